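"""End-to-end convenience pipeline on synthetic or pre-built inputs.

Glues the stages together in the order the analysis runs them:
climate -> life zones -> proxy subdivision -> SDM binarization -> feature
assembly -> greedy ranking -> evaluation.  Each stage remains usable on
its own; this module only removes boilerplate for studies and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .evaluate import (
    RepresentationCurves,
    pgd_area_representation,
    representation_curves,
    taxon_mean_pgd_representation,
)
from .features import (
    FeatureSet,
    assign_weights,
    binarize_sdm,
    build_scenario,
    habitat_condition,
    intensity_split,
)
from .grids import LabelGrid, ValueGrid
from .lifezones import LifeZoneMap, classify_lifezones
from .pgd import DividerSet, PGDMap, subdivide_lifezones
from .prioritize import PriorityRankMap, RankConfig, admu_rank, caz_rank, top_fraction
from .synthetic import SimConfig, simulate_landscape, simulate_taxa, uniform_assignment

__all__ = ["StudyResult", "run_synthetic_study", "scenario_pgd_representation"]


@dataclass
class StudyResult:
    """All intermediate and final products of one synthetic study run."""

    config: SimConfig
    lifezones: LifeZoneMap
    pgd: PGDMap
    binary_sdm: dict[str, ValueGrid]
    thresholds: dict[str, float]
    features: FeatureSet
    conditions: dict[str, ValueGrid]
    rank: PriorityRankMap
    curves: RepresentationCurves
    taxon_records: list
    candidate_count: int = 0
    kept_count: int = 0

    def taxon_summary(self, f: float = 0.2) -> pd.DataFrame:
        iucn = {t.taxon_id: t.iucn for t in self.taxon_records}
        return taxon_mean_pgd_representation(self.curves, self.features, f, iucn=iucn)

    def mask_at(self, f: float = 0.2) -> LabelGrid:
        return top_fraction(self.rank, f)


def run_synthetic_study(
    config: SimConfig,
    scenario: str = "SDMxPGD",
    rank_config: Optional[RankConfig] = None,
    use_iucn_weights: bool = False,
    use_conditions: bool = False,
    binarize_rule: str = "p10",
) -> StudyResult:
    """Simulate a landscape and run the full prioritization pipeline on it.

    ``use_iucn_weights`` and ``use_conditions`` default off (the scenario-
    comparison configuration); turn both on for the final-analysis style
    run with extinction-risk weights and habitat-condition layers.
    """
    if rank_config is None:
        rank_config = RankConfig(warp=1, use_conditions=use_conditions)
    land = simulate_landscape(config)
    lifezones = classify_lifezones(land.climate)
    dividers = DividerSet(
        dividers=land.divider_grids,
        assignment=uniform_assignment(lifezones, list(land.divider_grids)),
    )
    pgd = subdivide_lifezones(lifezones, dividers)
    suitability, presences, records = simulate_taxa(config, pgd)
    records = assign_weights(
        records, ssi_ids=[t.taxon_id for t in records if not t.has_sdm]
    )

    binary: dict[str, ValueGrid] = {}
    thresholds: dict[str, float] = {}
    for taxon, suit in suitability.items():
        cells = list(zip(presences[taxon]["row"], presences[taxon]["col"]))
        binary[taxon], thresholds[taxon] = binarize_sdm(suit, cells, rule=binarize_rule)

    landcover = intensity_split(land.landcover, land.admin_units, land.yields)
    conditions = {}
    if use_conditions:
        by_id = {t.taxon_id: t for t in records}
        for taxon in binary:
            conditions[taxon] = habitat_condition(landcover, by_id[taxon])

    weights = (
        {t.taxon_id: t.weight for t in records}
        if use_iucn_weights
        else {t.taxon_id: 1.0 for t in records}
    )
    spec = pgd.zones.spec
    ssi_points = {
        t.taxon_id: (
            presences[t.taxon_id]["row"].to_numpy() * spec.n_cols
            + presences[t.taxon_id]["col"].to_numpy()
        )
        for t in records
        if not t.has_sdm
    }
    features = build_scenario(
        scenario,
        binary,
        pgd=pgd,
        lifezones=lifezones,
        ssi_points=ssi_points,
        weights=weights,
        conditions={t: t for t in binary} if use_conditions else None,
    )
    candidate = kept = 0
    if scenario == "SDMxPGD":
        candidate = len(binary) * pgd.n_pgd
        kept = sum(1 for lyr in features.layers if lyr.kind == "raster")

    land_mask = pgd.zones.data_mask
    if scenario == "ADMU":
        rank = admu_rank(features, units=pgd, conditions=conditions, config=rank_config)
    else:
        rank = caz_rank(
            features, conditions=conditions, config=rank_config, land_mask=land_mask
        )
    curves = representation_curves(rank, features)
    return StudyResult(
        config=config,
        lifezones=lifezones,
        pgd=pgd,
        binary_sdm=binary,
        thresholds=thresholds,
        features=features,
        conditions=conditions,
        rank=rank,
        curves=curves,
        taxon_records=records,
        candidate_count=candidate,
        kept_count=kept,
    )


def scenario_pgd_representation(result: StudyResult, f: float = 0.2) -> pd.DataFrame:
    """Pooled per-(taxon, proxy) retained proportions at top fraction ``f``.

    For every modeled taxon, the share of each proxy's overlap with the
    taxon's binary range that falls inside the top-``f`` mask — the
    quantity the scenario comparison judges scenarios by.
    """
    mask = result.mask_at(f)
    frames = []
    for taxon, sdm in result.binary_sdm.items():
        df = pgd_area_representation(mask, sdm, result.pgd)
        df.insert(0, "taxon", taxon)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
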