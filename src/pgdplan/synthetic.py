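"""Seeded synthetic landscapes, taxa, and genetic samples.

The generator emulates the statistical structure the pipeline assumes about
its real inputs, so every stage is testable without external data:

* climate — smooth latitudinal temperature and longitudinal precipitation
  gradients plus seeded, spatially autocorrelated noise (Gaussian-smoothed
  white noise), producing banded life zones;
* dividers — seeded Voronoi partitions standing in for biogeographic
  provinces, watersheds and similar historical-isolation cartography;
* land cover — a seven-class mosaic with agricultural classes, plus
  per-administrative-unit crop yields scattered around the 3 t/ha
  intensity boundary;
* taxa — suitability surfaces built as kernel mixtures anchored in a random
  subset of proxy zones (so ranges straddle several zones), presence points
  sampled proportional to suitability, IUCN categories drawn from the
  empirical category frequencies of the assessed inventory;
* genetics — admixture-style membership vectors drawn from a Dirichlet
  centered on the sample's home-proxy cluster with concentration alpha
  (alpha -> infinity: pure membership; alpha = 1: unstructured).

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridError, GridSpec, LabelGrid, ValueGrid
from .lifezones import ClimateStack, LifeZoneMap
from .pgd import DividerSet, PGDMap

__all__ = ["SimConfig", "SyntheticLandscape", "simulate_landscape",
           "simulate_taxa", "simulate_genetics", "uniform_assignment"]

#: Empirical IUCN category frequencies of the 224-taxon assessed inventory
#: (CR 7, EN 47, VU 16, NT 9, LC 125, DD 20).
IUCN_FREQUENCIES = {
    "CR": 7 / 224,
    "EN": 47 / 224,
    "VU": 16 / 224,
    "NT": 9 / 224,
    "LC": 125 / 224,
    "DD": 20 / 224,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1000.0  # 1 km cells, matching the analysis resolution
    crs_id: str = "EPSG:3395"  # World Mercator

    # climate: annual-mean range across the latitudinal gradient (degC),
    # seasonal half-amplitude, precipitation range (mm/yr), noise levels
    temp_north: float = 8.0
    temp_south: float = 26.0
    seasonal_amplitude: float = 6.0
    precip_west: float = 400.0
    precip_east: float = 2200.0
    temp_noise_sd: float = 1.0
    precip_noise_sd: float = 150.0
    noise_sigma_cells: float = 4.0  # autocorrelation length of the noise

    # dividers and administrative units (Voronoi cells each)
    dividers: tuple[tuple[str, int], ...] = (("provinces", 3), ("watersheds", 4))
    n_admin_units: int = 12

    # land cover / yields
    n_landcover: int = 7
    yield_low: float = 1.5
    yield_high: float = 4.5

    # taxa
    n_taxa: int = 10
    n_ssi_taxa: int = 2  # taxa without a distribution model, points only
    occurrences_per_taxon: int = 30  # > 20, the modeling minimum
    ssi_occurrences: int = 5
    range_pgd_min: int = 1
    range_pgd_max: int = 4
    kernel_scale_cells: float = 8.0
    suitability_noise: float = 0.1

    # genetics
    n_samples: int = 500
    alpha: float = 20.0  # Dirichlet concentration on the home cluster

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise GridError("alpha must be > 0")
        if self.n_taxa < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise GridError("counts must be >= 1")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_x=0.0,
            origin_y=self.n_rows * self.cell_size,
            cell_size=self.cell_size,
            crs_id=self.crs_id,
        )


@dataclass
class SyntheticLandscape:
    climate: ClimateStack
    divider_grids: dict[str, LabelGrid]
    landcover: LabelGrid
    admin_units: LabelGrid
    yields: pd.Series  # t/ha per administrative unit


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, sd: float
) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sigma <= 0 or sd == 0:
        return sd * white
    sm = gaussian_filter(white, sigma=sigma, mode="reflect")
    s = sm.std()
    return sd * sm / s if s > 0 else sm


def _voronoi_labels(
    rng: np.random.Generator, spec: GridSpec, n_classes: int
) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
    seeds_r = rng.uniform(0, spec.n_rows, n_classes)
    seeds_c = rng.uniform(0, spec.n_cols, n_classes)
    d2 = (rr[None] - seeds_r[:, None, None]) ** 2 + (cc[None] - seeds_c[:, None, None]) ** 2
    return d2.argmin(axis=0).astype(np.int32) + 1


def simulate_landscape(config: SimConfig) -> SyntheticLandscape:
    """Generate the climate stack, dividers, land cover and yield table."""
    spec = config.spec
    shape = spec.shape
    rows = np.arange(spec.n_rows)[:, None] / max(spec.n_rows - 1, 1)
    cols = np.arange(spec.n_cols)[None, :] / max(spec.n_cols - 1, 1)

    annual_mean = config.temp_north + (config.temp_south - config.temp_north) * rows
    annual_mean = annual_mean + _smooth_noise(
        _rng(config, 1), shape, config.noise_sigma_cells, config.temp_noise_sd
    )
    months = []
    for mth in range(12):
        seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (mth - 6) / 12)
        months.append(
            ValueGrid(spec=spec, values=np.broadcast_to(annual_mean + seasonal, shape).copy())
        )

    precip = config.precip_west + (config.precip_east - config.precip_west) * cols
    precip = precip + _smooth_noise(
        _rng(config, 2), shape, config.noise_sigma_cells, config.precip_noise_sd
    )
    precip = np.clip(np.broadcast_to(precip, shape), 1.0, None)
    precipitation = ValueGrid(spec=spec, values=precip.copy())

    divider_grids = {
        name: LabelGrid(spec=spec, labels=_voronoi_labels(_rng(config, 10 + i), spec, k))
        for i, (name, k) in enumerate(config.dividers)
    }
    admin = LabelGrid(
        spec=spec, labels=_voronoi_labels(_rng(config, 30), spec, config.n_admin_units)
    )

    # land cover: per-class smooth random fields, class = argmax
    rng_lc = _rng(config, 40)
    fields = np.stack(
        [
            gaussian_filter(rng_lc.standard_normal(shape), config.noise_sigma_cells)
            for _ in range(config.n_landcover)
        ]
    )
    landcover = LabelGrid(spec=spec, labels=fields.argmax(axis=0).astype(np.int32) + 1)

    rng_y = _rng(config, 50)
    yields = pd.Series(
        rng_y.uniform(config.yield_low, config.yield_high, config.n_admin_units),
        index=np.arange(1, config.n_admin_units + 1),
        name="yield_t_ha",
    )
    climate = ClimateStack(monthly_temperature=months, annual_precipitation=precipitation)
    return SyntheticLandscape(
        climate=climate,
        divider_grids=divider_grids,
        landcover=landcover,
        admin_units=admin,
        yields=yields,
    )


def uniform_assignment(
    lifezones: LifeZoneMap, divider_names: Sequence[str]
) -> dict[int, list[str]]:
    """Assign the same ordered divider list to every life zone present."""
    return {int(z): list(divider_names) for z in lifezones.zones.label_set()}


def _pgd_centroids(pgd: PGDMap) -> dict[int, tuple[float, float]]:
    out = {}
    for g in pgd.zones.label_set():
        r, c = np.nonzero(pgd.zones.labels == int(g))
        out[int(g)] = (float(r.mean()), float(c.mean()))
    return out


def simulate_taxa(
    config: SimConfig, pgd: PGDMap
) -> tuple[dict[str, ValueGrid], dict[str, pd.DataFrame], list]:
    """Generate suitability surfaces, presence points and taxon records.

    Each modeled taxon's suitability is a Gaussian-kernel mixture centered
    at the centroids of a random subset of PGDs and masked to those PGDs
    (its range is contained in its home proxies); presences are sampled
    without replacement proportional to suitability.  The last
    ``n_ssi_taxa`` taxa get no model, only a handful of occurrences.
    """
    from .features import TaxonRecord  # local import to avoid cycle

    spec = pgd.zones.spec
    shape = spec.shape
    rng = _rng(config, 100)
    centroids = _pgd_centroids(pgd)
    pgd_ids = sorted(centroids)
    rr, cc = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]

    cats = list(IUCN_FREQUENCIES)
    probs = np.array(list(IUCN_FREQUENCIES.values()))
    suitability: dict[str, ValueGrid] = {}
    presences: dict[str, pd.DataFrame] = {}
    records = []
    n_modeled = config.n_taxa - config.n_ssi_taxa
    if n_modeled < 1:
        raise GridError("need at least one modeled taxon")
    for t in range(config.n_taxa):
        taxon = f"taxon{t + 1:03d}"
        modeled = t < n_modeled
        k = int(rng.integers(config.range_pgd_min, config.range_pgd_max + 1))
        k = min(k, len(pgd_ids))
        # range zones drawn proportional to area (large proxies host more
        # ranges); grow the range until it can hold the occurrence sample
        areas = np.array([(pgd.zones.labels == g).sum() for g in pgd_ids], float)
        home = sorted(
            rng.choice(pgd_ids, size=k, replace=False, p=areas / areas.sum()).tolist()
        )
        needed = (
            config.occurrences_per_taxon if t < n_modeled else config.ssi_occurrences
        )
        while (
            np.isin(pgd.zones.labels, home).sum() < needed
            and len(home) < len(pgd_ids)
        ):
            rest = [g for g in pgd_ids if g not in home]
            p_rest = areas[[pgd_ids.index(g) for g in rest]]
            home = sorted(home + [int(rng.choice(rest, p=p_rest / p_rest.sum()))])
        prefs = {1: 1.0, 2: 1.0}
        for cls in range(3, 8):
            prefs[cls] = float(rng.choice([1.0, 0.5, 0.1], p=[0.2, 0.3, 0.5]))
        iucn = str(rng.choice(cats, p=probs))
        records.append(
            TaxonRecord(taxon_id=taxon, iucn=iucn, habitat_prefs=prefs, has_sdm=modeled)
        )
        support = np.isin(pgd.zones.labels, home)
        if modeled:
            surf = np.zeros(shape)
            for g in home:
                r0, c0 = centroids[g]
                surf += np.exp(
                    -((rr - r0) ** 2 + (cc - c0) ** 2)
                    / (2 * config.kernel_scale_cells**2)
                )
            noise = rng.uniform(0, config.suitability_noise, shape)
            surf = (surf / surf.max() + noise) * support
            suitability[taxon] = ValueGrid(spec=spec, values=surf)
            n_occ = config.occurrences_per_taxon
        else:
            surf = support.astype(np.float64)
            n_occ = config.ssi_occurrences
        positive = np.flatnonzero(surf.ravel() > 0)
        if n_occ > positive.size:
            raise GridError(
                f"{taxon}: {n_occ} presences requested but only "
                f"{positive.size} positive-suitability cells"
            )
        p = surf.ravel()[positive]
        chosen = rng.choice(positive, size=n_occ, replace=False, p=p / p.sum())
        prow, pcol = np.unravel_index(chosen, shape)
        presences[taxon] = pd.DataFrame(
            {
                "id": [f"{taxon}_occ{i}" for i in range(n_occ)],
                "x": spec.origin_x + (pcol + 0.5) * spec.cell_size,
                "y": spec.origin_y - (prow + 0.5) * spec.cell_size,
                "row": prow,
                "col": pcol,
            }
        )
    return suitability, presences, records


def simulate_genetics(
    config: SimConfig,
    pgd: PGDMap,
    sdm: ValueGrid,
    clusters_per_pgd: Optional[Mapping[int, int]] = None,
    alpha: Optional[float] = None,
) -> pd.DataFrame:
    """Place genetic samples on a taxon's range with admixture structure.

    Samples sit at the centers of random SDM-positive cells; each sample's
    membership vector is a Dirichlet draw with concentration ``alpha`` on
    its home proxy's cluster and 1 elsewhere.  By default every proxy
    overlapping the SDM gets its own cluster.
    """
    spec = pgd.zones.spec
    alpha = config.alpha if alpha is None else alpha
    occ = np.flatnonzero((sdm.filled(0.0) > 0).ravel() & (pgd.zones.labels.ravel() > 0))
    if occ.size == 0:
        raise GridError("SDM has no positive cells on the proxy partition")
    overlapping = sorted(int(g) for g in np.unique(pgd.zones.labels.ravel()[occ]))
    if clusters_per_pgd is None:
        clusters_per_pgd = {g: i for i, g in enumerate(overlapping)}
    missing = [g for g in overlapping if g not in clusters_per_pgd]
    if missing:
        raise GridError(f"clusters_per_pgd missing proxies: {missing}")
    n_clusters = max(clusters_per_pgd.values()) + 1

    rng = _rng(config, 200)
    cells = rng.choice(occ, size=config.n_samples, replace=True)
    prow, pcol = np.unravel_index(cells, spec.shape)
    home_pgd = pgd.zones.labels.ravel()[cells]
    mem = np.empty((config.n_samples, n_clusters))
    for i in range(config.n_samples):
        conc = np.ones(n_clusters)
        conc[clusters_per_pgd[int(home_pgd[i])]] = alpha
        mem[i] = rng.dirichlet(conc)
    df = pd.DataFrame(
        {
            "id": [f"sample{i}" for i in range(config.n_samples)],
            "x": spec.origin_x + (pcol + 0.5) * spec.cell_size,
            "y": spec.origin_y - (prow + 0.5) * spec.cell_size,
            "home_pgd": home_pgd,
        }
    )
    for kdx in range(n_clusters):
        df[f"q{kdx}"] = mem[:, kdx]
    return df
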