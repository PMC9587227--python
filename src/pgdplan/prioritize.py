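"""Hierarchical landscape ranking by greedy core-area cell removal.

The ranking repeatedly discards the cell whose loss hurts the worst-off
conservation feature the least.  With retained set S, feature totals
``Q_j(S)`` over effective values ``v'_j(i) = v_j(i) * condition_i`` and
weights ``w_j``, the marginal loss of cell i is

    delta_i = max_j  w_j * v'_j(i) / Q_j(S)

and the cell minimizing delta_i is removed (core-area rule: a cell is only
as expendable as its most irreplaceable feature allows).  Removal order
defines the hierarchical rank: the last cell standing has rank 1.  Features
with weight 0 never enter delta (they are evaluated but do not steer the
solution); features already fully lost (Q_j = 0) are skipped.

Cell cost is uniform (1 per cell) and no connectivity penalty is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .grids import GridError, GridSpec, LabelGrid, ValueGrid
from .features import FeatureSet
from .pgd import PGDMap

__all__ = ["RankConfig", "PriorityRankMap", "caz_rank", "admu_rank", "top_fraction"]


@dataclass(frozen=True)
class RankConfig:
    """Run options for the greedy ranking.

    warp : cells removed per delta recomputation batch (1 = exact greedy).
    tie_break : "lowest-index" (deterministic) or "seeded-random".
    seed : RNG seed for the random tie-break.
    use_conditions : multiply feature values by their linked habitat layer.
    edge_only : restrict candidate cells to the eroding edge of the
        remaining area (an approximation device; off by default).
    """

    warp: int = 1
    tie_break: str = "lowest-index"
    seed: int = 0
    use_conditions: bool = True
    edge_only: bool = False

    def __post_init__(self) -> None:
        if self.warp < 1:
            raise GridError("warp must be >= 1")
        if self.tie_break not in ("lowest-index", "seeded-random"):
            raise GridError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class PriorityRankMap:
    """Per-cell priority rank in (0, 1] plus the removal log.

    ``rank.values`` holds, for each land cell, the fraction of land cells
    removed at or before that cell's removal — a permutation of
    {1/N, ..., 1}.  Higher rank = retained longer = higher priority.
    ``removal_log`` columns: step, row, col, delta.
    """

    rank: ValueGrid
    removal_log: pd.DataFrame

    @property
    def n_land(self) -> int:
        return int(self.rank.data_mask.sum())

    def removal_order(self) -> np.ndarray:
        """Flat cell indices in removal order (first removed first)."""
        log = self.removal_log
        return (log["row"].to_numpy() * self.rank.spec.n_cols + log["col"].to_numpy())


def _effective_matrix(
    features: FeatureSet,
    conditions: Optional[Mapping[str, ValueGrid]],
    land: np.ndarray,
    use_conditions: bool,
    allow_empty: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (feature x land-cell) matrix of effective values v'_j plus the
    weight vector, for positively weighted features only."""
    n_flat = features.spec.n_rows * features.spec.n_cols
    pos = np.full(n_flat, -1, dtype=np.int64)
    pos[land] = np.arange(land.size)
    rows = []
    weights = []
    for lyr in features.layers:
        if lyr.weight == 0:
            continue
        vec = np.zeros(land.size)
        on_land = pos[lyr.cells] >= 0 if lyr.cells.size else np.array([], bool)
        vec[pos[lyr.cells[on_land]]] = lyr.values[on_land]
        if use_conditions and lyr.condition is not None:
            if conditions is None or lyr.condition not in conditions:
                raise GridError(
                    f"feature {lyr.feature_id} links condition {lyr.condition!r} "
                    "but no such layer was supplied"
                )
            cond = conditions[lyr.condition].filled(0.0).ravel()[land]
            vec = vec * cond
        rows.append(vec)
        weights.append(lyr.weight)
    if not rows:
        raise GridError("no feature with positive weight")
    m = np.asarray(rows)
    if not allow_empty and not (m.sum(axis=1) > 0).any():
        raise GridError("all features are empty on the land mask")
    return m, np.asarray(weights, dtype=np.float64)


def _edge_mask(remaining_grid: np.ndarray) -> np.ndarray:
    """Cells of the remaining area with a removed/outside 4-neighbor."""
    r = remaining_grid
    pad = np.pad(r, 1, constant_values=False)
    interior = (
        pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    )
    return r & ~interior


def caz_rank(
    features: FeatureSet,
    conditions: Optional[Mapping[str, ValueGrid]] = None,
    config: RankConfig = RankConfig(),
    land_mask: Optional[np.ndarray] = None,
    _allow_empty: bool = False,
) -> PriorityRankMap:
    """Rank all land cells by iterative greedy core-area removal.

    ``land_mask`` is a boolean grid of rankable cells; by default it is the
    union of all feature supports.  Within each batch of ``config.warp``
    cells, delta is computed once and the batch removed in ascending
    (delta, tie-key) order; warp 1 is the exact greedy rule.
    """
    spec = features.spec
    n_flat = spec.n_rows * spec.n_cols
    if land_mask is None:
        land_mask = np.zeros(n_flat, dtype=bool)
        for lyr in features.layers:
            land_mask[lyr.cells[lyr.values > 0]] = True
        land_mask = land_mask.reshape(spec.shape)
    land = np.flatnonzero(np.asarray(land_mask).ravel())
    if land.size == 0:
        raise GridError("empty land mask")

    m, w = _effective_matrix(
        features, conditions, land, config.use_conditions, allow_empty=_allow_empty
    )
    n_feat, n_land = m.shape

    if config.tie_break == "seeded-random":
        tie_key = np.random.default_rng(config.seed).permutation(n_land)
    else:
        tie_key = np.arange(n_land)

    remaining = np.ones(n_land, dtype=bool)
    order = np.empty(n_land, dtype=np.int64)  # positions into `land`
    deltas = np.empty(n_land)
    step = 0
    while remaining.any():
        idx = np.flatnonzero(remaining)
        # recompute totals from scratch: incremental subtraction would leave
        # float residue that makes nearly-exhausted features dominate delta
        q = m[:, idx].sum(axis=1)
        if config.edge_only:
            grid_remaining = np.zeros(n_flat, dtype=bool)
            grid_remaining[land[idx]] = True
            edge = _edge_mask(grid_remaining.reshape(spec.shape)).ravel()[land[idx]]
            if edge.any():
                idx = idx[edge]
        active = q > 0
        if active.any():
            # delta_i = max_j w_j * v'_j(i) / Q_j over features with Q_j > 0;
            # evaluated as (w * v) / Q to match a plain scalar transcription
            scaled = (w[active, None] * m[np.ix_(active, idx)]) / q[active, None]
            delta = scaled.max(axis=0)
        else:
            delta = np.zeros(idx.size)
        take = min(config.warp, idx.size)
        cand = np.lexsort((tie_key[idx], delta))[:take]
        chosen = idx[cand]
        order[step : step + take] = chosen
        deltas[step : step + take] = delta[cand]
        step += take
        remaining[chosen] = False

    n = n_land
    rank_flat = np.full(n_flat, spec.nodata)
    rank_flat[land[order]] = (np.arange(n) + 1) / n
    rows, cols = np.unravel_index(land[order], spec.shape)
    log = pd.DataFrame(
        {"step": np.arange(1, n + 1), "row": rows, "col": cols, "delta": deltas}
    )
    return PriorityRankMap(
        rank=ValueGrid(spec=spec, values=rank_flat.reshape(spec.shape)),
        removal_log=log,
    )


def admu_rank(
    features: FeatureSet,
    units: Optional[PGDMap] = None,
    conditions: Optional[Mapping[str, ValueGrid]] = None,
    config: RankConfig = RankConfig(),
) -> PriorityRankMap:
    """Rank with each planning unit (PGD) treated independently.

    The greedy ranking runs inside every unit separately; a cell's global
    position is its within-unit rank quantile, so at any top fraction f
    each unit contributes about f of its own area (up to one-cell
    quantization).  Quantile ties across units are broken by unit id.
    """
    if units is None:
        units = features.planning_units
    if units is None:
        raise GridError("ADMU ranking requires planning units")
    spec = features.spec
    n_flat = spec.n_rows * spec.n_cols
    unit_flat = units.zones.labels.ravel()

    quantile = np.full(n_flat, np.nan)
    unit_of = np.full(n_flat, 0, dtype=np.int64)
    delta_of = np.full(n_flat, np.nan)
    skipped = []
    for uid in units.zones.label_set():
        uid = int(uid)
        mask = unit_flat == uid
        if not mask.any():
            skipped.append(uid)
            continue
        # a unit no feature reaches still gets ranked (delta 0, tie order)
        sub = caz_rank(
            features,
            conditions=conditions,
            config=config,
            land_mask=mask.reshape(spec.shape),
            _allow_empty=True,
        )
        cells = sub.removal_order()
        n_u = cells.size
        quantile[cells] = (np.arange(n_u) + 1) / n_u
        unit_of[cells] = uid
        delta_of[cells] = sub.removal_log["delta"].to_numpy()

    land = np.flatnonzero(~np.isnan(quantile))
    n = land.size
    if n == 0:
        raise GridError("no land cells in any planning unit")
    global_order = land[np.lexsort((unit_of[land], quantile[land]))]
    rank_flat = np.full(n_flat, spec.nodata)
    rank_flat[global_order] = (np.arange(n) + 1) / n
    rows, cols = np.unravel_index(global_order, spec.shape)
    log = pd.DataFrame(
        {
            "step": np.arange(1, n + 1),
            "row": rows,
            "col": cols,
            "delta": delta_of[global_order],
        }
    )
    if skipped:
        log.attrs["skipped_units"] = skipped
    return PriorityRankMap(
        rank=ValueGrid(spec=spec, values=rank_flat.reshape(spec.shape)),
        removal_log=log,
    )


def top_fraction(rank: PriorityRankMap, f: float) -> LabelGrid:
    """Binary mask (label 1) of the top fraction ``f`` of the landscape.

    Selects the ``round(f * N)`` highest-ranked land cells — the cells with
    rank > 1 - f up to one-cell rounding — so masks at increasing f nest.
    """
    if not 0.0 <= f <= 1.0:
        raise GridError(f"fraction must be in [0, 1], got {f}")
    spec = rank.rank.spec
    land = rank.rank.data_mask.ravel()
    vals = rank.rank.values.ravel()
    n = int(land.sum())
    k = int(round(f * n))
    out = np.zeros(spec.n_rows * spec.n_cols, dtype=np.int32)
    if k > 0:
        # ranks are a permutation of {1/N..1}: top k cells have rank > (n-k)/n
        out[land & (vals > (n - k) / n * (1 + 1e-12))] = 1
    return LabelGrid(spec=spec, labels=out.reshape(spec.shape))
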