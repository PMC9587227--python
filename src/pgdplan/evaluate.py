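"""Evaluation of prioritization solutions.

Representation curves (retained proportion of each feature as a function of
the top landscape fraction), per-taxon mean representation of its
genetic-differentiation proxies, per-proxy representation at an area
threshold, overlay statistics against arbitrary masks, and the validation
workflow that compares proxy zones with empirical genetic-cluster
memberships (buffered sample-to-proxy assignment plus an adjusted Rand
index on the dominant-cluster contingency table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import GridError, LabelGrid, ValueGrid, check_alignment, points_to_cells
from .features import FeatureSet
from .pgd import PGDMap
from .prioritize import PriorityRankMap, top_fraction

__all__ = [
    "RepresentationCurves",
    "representation_curves",
    "taxon_mean_pgd_representation",
    "pgd_area_representation",
    "overlay_stats",
    "assign_samples_to_pgd",
    "cluster_zone_crosstab",
    "adjusted_rand_index",
]


@dataclass
class RepresentationCurves:
    """Retained proportion per feature at every removal step.

    ``fractions`` has length N+1 (0, 1/N, ..., 1: the top landscape
    fraction); ``proportions`` is (n_features, N+1) with
    ``proportions[j, k]`` = share of feature j's total retained in the top
    k/N of the landscape.  Features whose landscape total is zero are
    listed in ``undefined`` and carry NaN rows rather than silent zeros.
    """

    feature_ids: list[str]
    fractions: np.ndarray
    proportions: np.ndarray
    undefined: list[str]

    def at(self, f: float) -> pd.Series:
        """Retained proportion of every feature at top fraction ``f``."""
        n = len(self.fractions) - 1
        k = int(round(f * n))
        return pd.Series(self.proportions[:, k], index=self.feature_ids, name=f)

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        cols = {"fraction": self.fractions[::stride]}
        for j, fid in enumerate(self.feature_ids):
            cols[fid] = self.proportions[j, ::stride]
        return pd.DataFrame(cols)


def representation_curves(
    rank: PriorityRankMap,
    features: FeatureSet,
    conditions: Optional[Mapping[str, ValueGrid]] = None,
    use_conditions: bool = False,
) -> RepresentationCurves:
    """Compute every feature's representation curve from the removal order.

    rep_j(f) = (sum of v'_j over the top-f cells) / (sum over the whole
    landscape).  Pass the habitat-condition layers with
    ``use_conditions=True`` to evaluate on the same effective values the
    ranking used; the default evaluates binary occupancy (area retained).
    """
    spec = features.spec
    order = rank.removal_order()  # first removed ... last removed
    n = order.size
    kept_order = order[::-1]  # top-1 cell first
    pos_in_top = np.full(spec.n_rows * spec.n_cols, -1, dtype=np.int64)
    pos_in_top[kept_order] = np.arange(n)

    ids, props, undefined = [], [], []
    for lyr in features.layers:
        vals = lyr.values.astype(np.float64)
        if use_conditions and lyr.condition is not None:
            if conditions is None or lyr.condition not in conditions:
                raise GridError(f"missing condition layer {lyr.condition!r}")
            vals = vals * conditions[lyr.condition].filled(0.0).ravel()[lyr.cells]
        total = vals.sum()
        ids.append(lyr.feature_id)
        curve = np.full(n + 1, np.nan)
        if total <= 0:
            undefined.append(lyr.feature_id)
            props.append(curve)
            continue
        acc = np.zeros(n)
        inside = pos_in_top[lyr.cells]
        ok = inside >= 0
        np.add.at(acc, inside[ok], vals[ok])
        curve[0] = 0.0
        curve[1:] = np.cumsum(acc) / total
        props.append(curve)
    fractions = np.arange(n + 1) / n
    return RepresentationCurves(
        feature_ids=ids,
        fractions=fractions,
        proportions=np.asarray(props),
        undefined=undefined,
    )


def taxon_mean_pgd_representation(
    curves: RepresentationCurves,
    features: FeatureSet,
    f: float,
    iucn: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Mean retained proportion over each taxon's per-proxy layers at ``f``.

    The mean is unweighted over the taxon's non-empty zone layers
    (``pgd_id > 0``); taxa with a single layer return that layer's value;
    taxa with no zone layers are excluded (listed in ``df.attrs['excluded']``).
    Optionally joins each taxon's IUCN category for grouped summaries.
    """
    rep = curves.at(f)
    per_taxon: dict[str, list[float]] = {}
    for lyr in features.layers:
        if lyr.pgd_id <= 0 or not lyr.taxon_id:
            continue
        r = rep[lyr.feature_id]
        if np.isnan(r):
            continue
        per_taxon.setdefault(lyr.taxon_id, []).append(float(r))
    all_taxa = {lyr.taxon_id for lyr in features.layers if lyr.taxon_id}
    excluded = sorted(all_taxa - set(per_taxon))
    df = pd.DataFrame(
        {
            "taxon": list(per_taxon),
            "mean_pgd_representation": [float(np.mean(v)) for v in per_taxon.values()],
            "n_layers": [len(v) for v in per_taxon.values()],
        }
    )
    if iucn is not None:
        df["iucn"] = df["taxon"].map(dict(iucn))
    df.attrs["excluded"] = excluded
    df.attrs["fraction"] = f
    return df


def pgd_area_representation(
    mask: LabelGrid, sdm: ValueGrid, pgd: PGDMap
) -> pd.DataFrame:
    """Retained share of each proxy's overlap with a taxon's binary range.

    For every PGD g overlapping the SDM:
    ``|SDM & g & mask| / |SDM & g|``; proxies with empty SDM overlap are
    omitted.
    """
    check_alignment([mask, sdm, pgd.zones])
    occ = sdm.filled(0.0) > 0
    sel = mask.labels > 0
    labels = pgd.zones.labels
    rows = []
    for g in pgd.zones.label_set():
        g = int(g)
        inter = occ & (labels == g)
        n = int(inter.sum())
        if n == 0:
            continue
        kept = int((inter & sel).sum())
        rows.append({"pgd_id": g, "n_cells": n, "n_retained": kept,
                     "proportion": kept / n})
    return pd.DataFrame(rows, columns=["pgd_id", "n_cells", "n_retained", "proportion"])


def overlay_stats(mask: LabelGrid, layers: Mapping[str, LabelGrid]) -> pd.DataFrame:
    """Share of the mask covered by each named binary layer."""
    check_alignment([mask, *layers.values()])
    sel = mask.labels > 0
    denom = int(sel.sum())
    if denom == 0:
        raise GridError("empty mask")
    rows = []
    for name, layer in layers.items():
        inter = int((sel & (layer.labels > 0)).sum())
        rows.append({"layer": name, "n_overlap": inter, "n_mask": denom,
                     "proportion": inter / denom})
    return pd.DataFrame(rows, columns=["layer", "n_overlap", "n_mask", "proportion"])


def assign_samples_to_pgd(
    samples: pd.DataFrame, pgd: PGDMap, radius: float
) -> pd.DataFrame:
    """Assign each genetic sample to the proxy most frequent around it.

    A sample takes the PGD label most frequent among cells whose centers
    lie within ``radius`` map units of the point (5 km in the validation
    workflow); ties go to the smallest label, an all-nodata neighborhood
    leaves the sample unassigned (``pgd_id = 0``).  ``radius = 0``
    degenerates to the containing cell's label.
    """
    if radius < 0:
        raise GridError("radius must be >= 0")
    spec = pgd.zones.spec
    x = samples["x"].to_numpy(dtype=np.float64)
    y = samples["y"].to_numpy(dtype=np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise GridError("non-finite sample coordinates")
    cx, cy = spec.cell_centers()
    labels = pgd.zones.labels
    reach = max(int(np.ceil(radius / spec.cell_size)) + 1, 1)
    assigned = np.zeros(len(samples), dtype=np.int64)
    rows, cols, inside = points_to_cells(x, y, spec)
    for i in range(len(samples)):
        if radius == 0:
            if inside[i]:
                assigned[i] = int(labels[rows[i], cols[i]])
            continue
        # search window around the point regardless of containment
        cc = np.floor((x[i] - spec.origin_x) / spec.cell_size).astype(int)
        rr = np.floor((spec.origin_y - y[i]) / spec.cell_size).astype(int)
        r_lo, r_hi = max(rr - reach, 0), min(rr + reach + 1, spec.n_rows)
        c_lo, c_hi = max(cc - reach, 0), min(cc + reach + 1, spec.n_cols)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        sub = labels[r_lo:r_hi, c_lo:c_hi]
        d2 = (cx[r_lo:r_hi, c_lo:c_hi] - x[i]) ** 2 + (
            cy[r_lo:r_hi, c_lo:c_hi] - y[i]
        ) ** 2
        near = sub[(d2 <= radius**2) & (sub > 0)]
        if near.size:
            vals, counts = np.unique(near, return_counts=True)
            assigned[i] = int(vals[np.argmax(counts)])  # unique is sorted: ties -> smallest id
    out = samples.copy()
    out["pgd_id"] = assigned
    return out


def adjusted_rand_index(table: np.ndarray) -> float:
    """Adjusted Rand index from a contingency table (standard closed form)."""
    t = np.asarray(table, dtype=np.float64)
    n = t.sum()
    if n < 2:
        return 0.0
    comb2 = lambda x: x * (x - 1) / 2.0  # noqa: E731
    sum_ij = comb2(t).sum()
    a = comb2(t.sum(axis=1)).sum()
    b = comb2(t.sum(axis=0)).sum()
    expected = a * b / comb2(n)
    max_index = (a + b) / 2.0
    if max_index == expected:
        # both partitions trivial (one cluster, or all singletons): identical
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_zone_crosstab(
    samples: pd.DataFrame, membership_cols: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, float]:
    """Contingency table of dominant genetic cluster x assigned proxy, + ARI.

    The dominant cluster is the argmax of the membership vector (ties to
    the smallest cluster index).  Samples without an assigned proxy
    (``pgd_id == 0``) are excluded; their count is reported in
    ``table.attrs['n_unassigned']``.
    """
    if membership_cols is None:
        membership_cols = [c for c in samples.columns if str(c).startswith("q")]
    if not membership_cols:
        raise GridError("no membership columns found")
    mem = samples[list(membership_cols)].to_numpy(dtype=np.float64)
    if (mem < 0).any():
        raise GridError("negative membership proportions")
    if not np.allclose(mem.sum(axis=1), 1.0, atol=1e-6):
        raise GridError("membership vectors must sum to 1")
    dominant = mem.argmax(axis=1)  # argmax ties -> smallest index
    assigned = samples["pgd_id"].to_numpy()
    keep = assigned > 0
    table = pd.crosstab(
        pd.Series(dominant[keep], name="cluster"),
        pd.Series(assigned[keep], name="pgd"),
    )
    table.attrs["n_unassigned"] = int((~keep).sum())
    ari = adjusted_rand_index(table.to_numpy())
    return table, ari
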