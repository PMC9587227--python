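"""Conservation-feature assembly.

Builds the layer stacks the prioritization consumes: binarized species
distribution models (SDM), their intersections with the proxies of genetic
differentiation (PGD), per-taxon habitat-condition layers derived from land
cover and expert preference scores, IUCN-category weights, and the five
scenario configurations used to compare how intraspecific variation is
represented.

Feature layers are stored sparsely (flat cell indices + values on the
shared grid) because the full SDM x PGD cross can run to thousands of
mostly-empty layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import GridError, GridSpec, LabelGrid, ValueGrid, check_alignment
from .lifezones import LifeZoneMap
from .pgd import PGDMap

__all__ = [
    "IUCN_WEIGHTS",
    "LANDCOVER_CATEGORIES",
    "TaxonRecord",
    "FeatureLayer",
    "FeatureSet",
    "binarize_sdm",
    "intersect_features",
    "intensity_split",
    "habitat_condition",
    "assign_weights",
    "build_scenario",
    "read_taxon_table",
]

#: Conservation weight per IUCN Red List category.
IUCN_WEIGHTS = {
    "CR": 1.0,
    "EN": 1.0,
    "VU": 0.8,
    "NT": 0.5,
    "DD": 0.3,
    "LC": 0.2,
    "NE": 0.1,
}

#: The seven aggregated land-cover categories, keyed by raster class label.
LANDCOVER_CATEGORIES = {
    1: "primary vegetation",
    2: "secondary vegetation",
    3: "less intensive rainfed/moisture agriculture",
    4: "intensive rainfed/moisture agriculture",
    5: "irrigated agriculture",
    6: "induced/cultivated grasslands and forests",
    7: "urban",
}

#: Classes 3 and 4 are the rainfed/moisture agriculture pair that the
#: intensity split reassigns; an input map may carry them as one merged
#: class 3 before splitting.
RAINFED_CLASSES = (3, 4)

_VALID_PREF_SCORES = (0.1, 0.5, 1.0)


@dataclass
class TaxonRecord:
    """Metadata for one crop-wild-relative taxon."""

    taxon_id: str
    iucn: str = "NE"
    weight: Optional[float] = None
    habitat_prefs: Optional[Mapping[int, float]] = None
    has_sdm: bool = True

    def __post_init__(self) -> None:
        if self.iucn not in IUCN_WEIGHTS:
            raise GridError(
                f"unknown IUCN category {self.iucn!r} for taxon {self.taxon_id}"
            )
        if self.habitat_prefs is not None:
            missing = set(LANDCOVER_CATEGORIES) - set(self.habitat_prefs)
            if missing:
                raise GridError(
                    f"taxon {self.taxon_id}: habitat prefs missing categories {sorted(missing)}"
                )
            bad = [v for v in self.habitat_prefs.values() if v not in _VALID_PREF_SCORES]
            if bad:
                raise GridError(
                    f"taxon {self.taxon_id}: preference scores must be in {_VALID_PREF_SCORES}"
                )


@dataclass
class FeatureLayer:
    """One conservation feature: sparse values on the shared grid.

    ``pgd_id`` is 0 for whole-range or non-taxon features.  ``kind`` is
    ``"raster"`` for SDM-derived layers and ``"points"`` for occurrence
    (SSI) features.  ``condition`` optionally names the taxon whose habitat
    layer multiplies this feature during ranking; never set for point
    features.
    """

    feature_id: str
    taxon_id: str
    pgd_id: int
    kind: str
    cells: np.ndarray  # flat indices into the grid
    values: np.ndarray  # positive values, same length as cells
    weight: float = 1.0
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.cells.shape != self.values.shape:
            raise GridError(f"feature {self.feature_id}: cells/values length mismatch")
        if (self.values < 0).any():
            raise GridError(f"feature {self.feature_id}: negative values")
        if self.kind not in ("raster", "points"):
            raise GridError(f"feature {self.feature_id}: kind must be raster|points")
        if self.kind == "points" and self.condition is not None:
            raise GridError(
                f"feature {self.feature_id}: point features cannot link a condition"
            )

    @property
    def n_cells(self) -> int:
        return int((self.values > 0).sum())

    def total(self) -> float:
        return float(self.values.sum())

    def to_grid(self, spec: GridSpec) -> ValueGrid:
        flat = np.zeros(spec.n_rows * spec.n_cols)
        flat[self.cells] = self.values
        return ValueGrid(spec=spec, values=flat.reshape(spec.shape))


@dataclass
class FeatureSet:
    """Ordered feature layers on one grid, tagged with the scenario name."""

    spec: GridSpec
    layers: list[FeatureLayer]
    scenario: str = ""
    planning_units: Optional[PGDMap] = None  # only for the ADMU scenario

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.layers]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GridError(f"duplicate feature ids: {dupes}")

    def __len__(self) -> int:
        return len(self.layers)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.layers],
                "taxon": [f.taxon_id for f in self.layers],
                "pgd": [f.pgd_id for f in self.layers],
                "weight": [f.weight for f in self.layers],
                "kind": [f.kind for f in self.layers],
                "n_cells": [f.n_cells for f in self.layers],
            }
        )


# ---------------------------------------------------------------------------
# SDM binarization


def binarize_sdm(
    suitability: ValueGrid,
    presence_cells: Sequence[tuple[int, int]],
    rule: str = "p10",
) -> tuple[ValueGrid, float]:
    """Binarize a continuous suitability raster at a presence-based threshold.

    ``rule="p10"`` uses the ten-percentile training threshold: the k-th
    smallest presence suitability with ``k = ceil(0.1 n)``.  ``rule="mtp"``
    uses the minimum training presence.  Cells with suitability >= threshold
    become 1, all other data cells 0; nodata is preserved.
    """
    if rule not in ("p10", "mtp"):
        raise GridError(f"rule must be 'p10' or 'mtp', got {rule!r}")
    vals = suitability.filled(np.nan)
    pres = np.array(
        [vals[r, c] for r, c in presence_cells], dtype=np.float64
    )
    pres = pres[~np.isnan(pres)]
    if pres.size == 0:
        raise GridError("all presence cells fall on nodata")
    if rule == "mtp":
        threshold = float(pres.min())
    else:
        k = int(np.ceil(0.1 * pres.size))
        threshold = float(np.sort(pres)[k - 1])
    binary = np.where(np.isnan(vals), suitability.spec.nodata,
                      (vals >= threshold).astype(np.float64))
    return ValueGrid(spec=suitability.spec, values=binary), threshold


# ---------------------------------------------------------------------------
# SDM x PGD intersection


def intersect_features(
    sdm_layers: Mapping[str, ValueGrid], pgd: PGDMap
) -> tuple[FeatureSet, int, int]:
    """Cross binary SDMs with the PGD partition into per-population features.

    Every (taxon, PGD) pair is a candidate layer; pairs whose intersection
    is empty are dropped.  Returns ``(feature_set, candidate_count,
    kept_count)`` where ``candidate_count = n_taxa x n_pgd``.  Per taxon the
    union of kept layers equals its SDM restricted to the land mask.
    """
    taxa = list(sdm_layers)
    if len(taxa) != len(set(taxa)):
        raise GridError("duplicate taxon ids")
    check_alignment([pgd.zones, *sdm_layers.values()])
    spec = pgd.zones.spec
    pgd_flat = pgd.zones.labels.ravel()
    pgd_ids = pgd.zones.label_set()
    candidate_count = len(taxa) * len(pgd_ids)
    layers: list[FeatureLayer] = []
    for taxon in taxa:
        sdm = sdm_layers[taxon]
        occ = (sdm.filled(0.0) > 0).ravel()
        cells = np.flatnonzero(occ & (pgd_flat > 0))
        labels_here = pgd_flat[cells]
        for g in pgd_ids:
            g = int(g)
            sub = cells[labels_here == g]
            if sub.size == 0:
                continue
            layers.append(
                FeatureLayer(
                    feature_id=f"{taxon}@pgd{g}",
                    taxon_id=taxon,
                    pgd_id=g,
                    kind="raster",
                    cells=sub,
                    values=np.ones(sub.size),
                )
            )
    fs = FeatureSet(spec=spec, layers=layers, scenario="SDMxPGD")
    return fs, candidate_count, len(layers)


# ---------------------------------------------------------------------------
# Habitat condition


def intensity_split(
    landcover: LabelGrid,
    admin_units: LabelGrid,
    yields: Mapping[int, float] | pd.Series,
    threshold: float = 3.0,
) -> LabelGrid:
    """Split rainfed/moisture agriculture into intensity classes by unit yield.

    Agricultural cells (classes 3 and 4) are relabeled class 3 ("less
    intensive") where their administrative unit's average yield is <= the
    threshold (default 3 t/ha, boundary inclusive) and class 4 ("intensive")
    otherwise.  All other classes pass through unchanged.
    """
    check_alignment([landcover, admin_units])
    yields = dict(pd.Series(yields))
    agri = np.isin(landcover.labels, RAINFED_CLASSES)
    units_here = np.unique(admin_units.labels[agri])
    units_here = units_here[units_here > 0]
    missing = [int(u) for u in units_here if u not in yields]
    if missing:
        raise GridError(f"no yield for administrative units with agriculture: {missing}")
    out = landcover.labels.copy()
    for u in units_here:
        in_unit = agri & (admin_units.labels == u)
        out[in_unit] = 3 if yields[int(u)] <= threshold else 4
    return LabelGrid(spec=landcover.spec, labels=out)


def habitat_condition(landcover: LabelGrid, taxon: TaxonRecord) -> ValueGrid:
    """Per-cell habitat preference score (1 / 0.5 / 0.1) for one taxon."""
    if taxon.habitat_prefs is None:
        raise GridError(f"taxon {taxon.taxon_id} has no habitat preferences")
    labels = landcover.labels
    present = np.unique(labels[labels > 0])
    unknown = [int(c) for c in present if c not in LANDCOVER_CATEGORIES]
    if unknown:
        raise GridError(f"land-cover classes outside the seven categories: {unknown}")
    spec = landcover.spec
    out = np.full(spec.shape, spec.nodata)
    for cls in present:
        out[labels == cls] = taxon.habitat_prefs[int(cls)]
    return ValueGrid(spec=spec, values=out)


# ---------------------------------------------------------------------------
# Weights and scenarios


def assign_weights(
    taxa: Sequence[TaxonRecord], ssi_ids: Sequence[str] = ()
) -> list[TaxonRecord]:
    """Fill taxon weights from IUCN categories; SSI taxa always weigh 1.

    An explicitly set weight (including 0, which excludes the feature from
    ranking while keeping it for evaluation) is preserved.
    """
    ssi = set(ssi_ids)
    out = []
    for t in taxa:
        if t.taxon_id in ssi:
            w = 1.0
        elif t.weight is not None:
            w = t.weight
        else:
            w = IUCN_WEIGHTS[t.iucn]
        out.append(
            TaxonRecord(
                taxon_id=t.taxon_id,
                iucn=t.iucn,
                weight=w,
                habitat_prefs=t.habitat_prefs,
                has_sdm=t.has_sdm,
            )
        )
    return out


def read_taxon_table(path) -> list[TaxonRecord]:
    """Read taxon metadata CSV (columns: taxon_id, iucn[, weight, has_sdm,
    pref_1..pref_7])."""
    df = pd.read_csv(path)
    records = []
    pref_cols = [f"pref_{c}" for c in LANDCOVER_CATEGORIES]
    for _, row in df.iterrows():
        prefs = None
        if all(c in df.columns for c in pref_cols):
            prefs = {c: float(row[f"pref_{c}"]) for c in LANDCOVER_CATEGORIES}
        weight = float(row["weight"]) if "weight" in df.columns and pd.notna(row.get("weight")) else None
        records.append(
            TaxonRecord(
                taxon_id=str(row["taxon_id"]),
                iucn=str(row["iucn"]),
                weight=weight,
                habitat_prefs=prefs,
                has_sdm=bool(row["has_sdm"]) if "has_sdm" in df.columns else True,
            )
        )
    return records


def _zone_layers(label_grid: LabelGrid, prefix: str) -> list[FeatureLayer]:
    flat = label_grid.labels.ravel()
    layers = []
    for z in label_grid.label_set():
        z = int(z)
        cells = np.flatnonzero(flat == z)
        layers.append(
            FeatureLayer(
                feature_id=f"{prefix}{z}",
                taxon_id="",
                pgd_id=z if prefix == "pgd" else 0,
                kind="raster",
                cells=cells,
                values=np.ones(cells.size),
            )
        )
    return layers


def _sdm_layers(
    sdm_layers: Mapping[str, ValueGrid],
    weights: Mapping[str, float],
    conditions: Mapping[str, str],
) -> list[FeatureLayer]:
    out = []
    for taxon, sdm in sdm_layers.items():
        occ = np.flatnonzero(sdm.filled(0.0).ravel() > 0)
        out.append(
            FeatureLayer(
                feature_id=taxon,
                taxon_id=taxon,
                pgd_id=0,
                kind="raster",
                cells=occ,
                values=np.ones(occ.size),
                weight=weights.get(taxon, 1.0),
                condition=conditions.get(taxon),
            )
        )
    return out


def build_scenario(
    tag: str,
    sdm_layers: Mapping[str, ValueGrid],
    pgd: Optional[PGDMap] = None,
    lifezones: Optional[LifeZoneMap] = None,
    ssi_points: Optional[Mapping[str, Sequence[int]]] = None,
    weights: Optional[Mapping[str, float]] = None,
    conditions: Optional[Mapping[str, str]] = None,
) -> FeatureSet:
    """Assemble one of the five scenario feature stacks.

    * ``SDM`` — one whole-range layer per taxon.
    * ``SDM+LZ`` — taxon layers plus one binary feature per life zone.
    * ``SDM+PGD`` — taxon layers plus one binary feature per PGD.
    * ``SDMxPGD`` — each taxon split into per-PGD features (empty dropped).
    * ``ADMU`` — taxon layers, with the PGD map attached as planning-unit
      strata for the administrative-unit ranking mode.

    ``ssi_points`` maps SSI taxon ids to occurrence flat-cell lists; SSI
    point features are appended in any scenario, weighted 1, never linked
    to a condition layer.  ``weights`` defaults to uniform 1 (the scenario
    comparison default); pass IUCN-derived weights for the final analysis.
    """
    weights = dict(weights or {})
    conditions = dict(conditions or {})
    if tag in ("SDM+PGD", "SDMxPGD", "ADMU") and pgd is None:
        raise GridError(f"scenario {tag} requires a PGD map")
    if tag == "SDM+LZ" and lifezones is None:
        raise GridError("scenario SDM+LZ requires a life-zone map")

    if tag == "SDMxPGD":
        fs, _, _ = intersect_features(sdm_layers, pgd)
        layers = fs.layers
        for lyr in layers:
            lyr.weight = weights.get(lyr.taxon_id, 1.0)
            lyr.condition = conditions.get(lyr.taxon_id)
        spec = fs.spec
        units = None
    else:
        spec = next(iter(sdm_layers.values())).spec
        layers = _sdm_layers(sdm_layers, weights, conditions)
        units = None
        if tag == "SDM":
            pass
        elif tag == "SDM+LZ":
            check_alignment([lifezones.zones, *sdm_layers.values()])
            layers += _zone_layers(lifezones.zones, "lz")
        elif tag == "SDM+PGD":
            check_alignment([pgd.zones, *sdm_layers.values()])
            layers += _zone_layers(pgd.zones, "pgd")
        elif tag == "ADMU":
            check_alignment([pgd.zones, *sdm_layers.values()])
            units = pgd
        else:
            raise GridError(f"unknown scenario tag {tag!r}")

    for taxon, cells in (ssi_points or {}).items():
        cells = np.asarray(sorted(set(int(c) for c in cells)), dtype=np.int64)
        layers.append(
            FeatureLayer(
                feature_id=f"ssi:{taxon}",
                taxon_id=taxon,
                pgd_id=0,
                kind="points",
                cells=cells,
                values=np.ones(cells.size),
                weight=1.0,
            )
        )
    return FeatureSet(spec=spec, layers=layers, scenario=tag, planning_units=units)
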