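"""Feature assembly: binarization, intersections, conditions, weights, scenarios."""

import numpy as np
import pandas as pd
import pytest

from pgdplan.grids import GridError, GridSpec, LabelGrid, ValueGrid
from pgdplan.lifezones import LifeZoneMap
from pgdplan.pgd import PGDMap
from pgdplan.features import (
    IUCN_WEIGHTS,
    TaxonRecord,
    assign_weights,
    binarize_sdm,
    build_scenario,
    habitat_condition,
    intensity_split,
    intersect_features,
    read_taxon_table,
)


def make_pgd(labels, spec=None):
    labels = np.asarray(labels)
    if spec is None:
        spec = GridSpec(labels.shape[0], labels.shape[1], 0.0,
                        labels.shape[0] * 1000.0, 1000.0)
    ids = sorted(set(labels.ravel()) - {0})
    prov = pd.DataFrame({
        "pgd_id": ids, "lifezone_id": 1, "divider_combo": "",
        "n_cells": [int((labels == i).sum()) for i in ids],
    })
    return PGDMap(zones=LabelGrid(spec=spec, labels=labels), provenance=prov)


class TestBinarize:
    def sorting_oracle(self, pres, rule):
        s = sorted(pres)
        if rule == "mtp":
            return s[0]
        k = int(np.ceil(0.1 * len(s)))
        return s[k - 1]

    def test_p10_twenty_presences(self):
        spec = GridSpec(4, 5, 0.0, 4000.0, 1000.0)
        suits = np.arange(0.05, 1.01, 0.05).reshape(4, 5)
        grid = ValueGrid(spec=spec, values=suits)
        cells = [(r, c) for r in range(4) for c in range(5)]
        binary, thr = binarize_sdm(grid, cells, rule="p10")
        assert thr == pytest.approx(self.sorting_oracle(suits.ravel(), "p10"))
        assert thr == pytest.approx(0.10)  # k = ceil(0.1*20) = 2
        assert binary.values.sum() == (suits >= thr).sum()

    def test_identical_suitabilities_same_threshold_both_rules(self):
        spec = GridSpec(2, 2, 0.0, 2000.0, 1000.0)
        grid = ValueGrid(spec=spec, values=np.full((2, 2), 0.4))
        for rule in ("p10", "mtp"):
            _, thr = binarize_sdm(grid, [(0, 0), (1, 1)], rule=rule)
            assert thr == 0.4

    def test_mtp_threshold_and_map(self):
        spec = GridSpec(1, 4, 0.0, 1000.0, 1000.0)
        grid = ValueGrid(spec=spec, values=np.array([[0.1, 0.3, 0.7, 0.9]]))
        binary, thr = binarize_sdm(grid, [(0, 1), (0, 2)], rule="mtp")
        assert thr == 0.3
        np.testing.assert_array_equal(binary.values, [[0, 1, 1, 1]])

    def test_monotonicity_p10_at_least_mtp(self):
        rng = np.random.default_rng(9)
        spec = GridSpec(10, 10, 0.0, 10000.0, 1000.0)
        for _ in range(25):
            vals = rng.uniform(0, 1, (10, 10))
            grid = ValueGrid(spec=spec, values=vals)
            n = int(rng.integers(1, 40))
            cells = [tuple(x) for x in rng.integers(0, 10, (n, 2))]
            _, t_mtp = binarize_sdm(grid, cells, rule="mtp")
            _, t_p10 = binarize_sdm(grid, cells, rule="p10")
            assert t_p10 >= t_mtp

    def test_all_presences_on_nodata_rejected(self):
        spec = GridSpec(2, 2, 0.0, 2000.0, 1000.0)
        vals = np.full((2, 2), spec.nodata)
        with pytest.raises(GridError):
            binarize_sdm(ValueGrid(spec=spec, values=vals), [(0, 0)])


class TestIntersect:
    def test_single_sdm_single_pgd_identity(self):
        pgd = make_pgd(np.ones((3, 3), int))
        sdm = ValueGrid(spec=pgd.zones.spec, values=np.ones((3, 3)))
        fs, cand, kept = intersect_features({"t1": sdm}, pgd)
        assert (cand, kept) == (1, 1)
        assert fs.layers[0].n_cells == 9

    def test_partial_overlap_counts(self):
        # 3 PGDs as columns; SDM "a" covers everything, "b" misses column 2
        pgd = make_pgd([[1, 2, 3]] * 3)
        spec = pgd.zones.spec
        a = ValueGrid(spec=spec, values=np.ones((3, 3)))
        bvals = np.ones((3, 3)); bvals[:, 2] = 0
        b = ValueGrid(spec=spec, values=bvals)
        fs, cand, kept = intersect_features({"a": a, "b": b}, pgd)
        assert (cand, kept) == (6, 5)
        # union conservation per taxon: kept layers tile the SDM land overlap
        for taxon, sdm in (("a", a), ("b", b)):
            total = sum(l.n_cells for l in fs.layers if l.taxon_id == taxon)
            assert total == int((sdm.values > 0).sum())

    def test_duplicate_taxon_ids_rejected(self):
        pgd = make_pgd(np.ones((2, 2), int))
        sdm = ValueGrid(spec=pgd.zones.spec, values=np.ones((2, 2)))
        class TwoSame(dict):
            def __iter__(self):
                return iter(["x", "x"])
        with pytest.raises(GridError, match="duplicate"):
            intersect_features(TwoSame({"x": sdm}), pgd)


class TestIntensitySplit:
    def setup_method(self):
        self.spec = GridSpec(2, 3, 0.0, 2000.0, 1000.0)
        # land cover: rainfed agriculture (3) everywhere except one urban cell
        lc = np.full((2, 3), 3); lc[1, 2] = 7
        self.landcover = LabelGrid(spec=self.spec, labels=lc)
        self.units = LabelGrid(spec=self.spec, labels=[[1, 1, 2], [1, 2, 2]])

    def test_boundary_yield_inclusive(self):
        out = intensity_split(self.landcover, self.units, {1: 3.0, 2: 3.2})
        assert out.labels[0, 0] == 3  # yield exactly 3.0 -> less intensive
        assert out.labels[0, 2] == 4  # 3.2 -> intensive
        assert out.labels[1, 2] == 7  # non-agricultural untouched

    def test_rule_application_both_sides(self):
        out = intensity_split(self.landcover, self.units, {1: 2.5, 2: 3.2})
        assert (out.labels[self.units.labels == 1][:2] == 3).all()
        assert out.labels[0, 2] == 4

    def test_no_agriculture_identity(self):
        lc = LabelGrid(spec=self.spec, labels=np.full((2, 3), 1))
        out = intensity_split(lc, self.units, {})
        np.testing.assert_array_equal(out.labels, lc.labels)

    def test_missing_yield_lists_units(self):
        with pytest.raises(GridError, match="2"):
            intensity_split(self.landcover, self.units, {1: 2.0})


class TestHabitatCondition:
    def test_constant_prefs_identity_condition(self):
        spec = GridSpec(2, 2, 0.0, 2000.0, 1000.0)
        lc = LabelGrid(spec=spec, labels=[[1, 2], [3, 7]])
        t = TaxonRecord("t", habitat_prefs={c: 1.0 for c in range(1, 8)})
        np.testing.assert_array_equal(habitat_condition(lc, t).values, 1.0)

    def test_classwise_lookup(self):
        spec = GridSpec(1, 3, 0.0, 1000.0, 1000.0)
        lc = LabelGrid(spec=spec, labels=[[1, 5, 7]])
        prefs = {1: 1.0, 2: 1.0, 3: 0.5, 4: 0.5, 5: 0.1, 6: 0.5, 7: 0.1}
        cond = habitat_condition(lc, TaxonRecord("t", habitat_prefs=prefs))
        np.testing.assert_array_equal(cond.values, [[1.0, 0.1, 0.1]])
        # condition layers only take scores in {0.1, 0.5, 1}
        assert set(np.unique(cond.values)) <= {0.1, 0.5, 1.0}

    def test_unknown_class_rejected(self):
        spec = GridSpec(1, 1, 0.0, 1000.0, 1000.0)
        lc = LabelGrid(spec=spec, labels=[[9]])
        t = TaxonRecord("t", habitat_prefs={c: 1.0 for c in range(1, 8)})
        with pytest.raises(GridError, match="9"):
            habitat_condition(lc, t)


class TestWeights:
    def test_category_map(self):
        recs = assign_weights([TaxonRecord("a", iucn="EN"), TaxonRecord("b", iucn="VU"),
                               TaxonRecord("c", iucn="NE")])
        assert [r.weight for r in recs] == [1.0, 0.8, 0.1]

    def test_ssi_always_one(self):
        recs = assign_weights([TaxonRecord("a", iucn="LC")], ssi_ids=["a"])
        assert recs[0].weight == 1.0

    def test_explicit_zero_preserved(self):
        recs = assign_weights([TaxonRecord("a", iucn="CR", weight=0.0)])
        assert recs[0].weight == 0.0

    def test_unknown_category_rejected(self):
        with pytest.raises(GridError):
            TaxonRecord("a", iucn="XX")


class TestScenarios:
    def setup_method(self):
        self.pgd = make_pgd([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])
        self.spec = self.pgd.zones.spec
        self.sdms = {
            f"t{i}": ValueGrid(spec=self.spec, values=np.ones((4, 4)))
            for i in range(1, 6)
        }
        legend = pd.DataFrame({"zone_id": [1], "belt": [0], "humidity": [0], "name": ["x"]})
        self.lz = LifeZoneMap(
            zones=LabelGrid(spec=self.spec, labels=np.ones((4, 4), int)), legend=legend
        )

    def test_sdm_tag_counts(self):
        assert len(build_scenario("SDM", self.sdms)) == 5

    def test_sdm_plus_pgd_counts(self):
        assert len(build_scenario("SDM+PGD", self.sdms, pgd=self.pgd)) == 9

    def test_sdm_plus_lz_counts(self):
        assert len(build_scenario("SDM+LZ", self.sdms, lifezones=self.lz)) == 6

    def test_cross_counts_full_overlap(self):
        fs = build_scenario("SDMxPGD", self.sdms, pgd=self.pgd)
        assert len(fs) == 20

    def test_admu_attaches_units(self):
        fs = build_scenario("ADMU", self.sdms, pgd=self.pgd)
        assert fs.planning_units is self.pgd
        assert len(fs) == 5

    def test_missing_pgd_rejected(self):
        with pytest.raises(GridError):
            build_scenario("SDMxPGD", self.sdms)

    def test_ssi_points_appended_without_condition(self):
        fs = build_scenario("SDM", self.sdms, ssi_points={"rare": [0, 5, 5, 9]})
        ssi = [l for l in fs.layers if l.kind == "points"]
        assert len(ssi) == 1
        assert ssi[0].weight == 1.0 and ssi[0].condition is None
        assert ssi[0].n_cells == 3  # duplicates collapse


def test_taxon_table_round_trip(tmp_path):
    df = pd.DataFrame({
        "taxon_id": ["a", "b"], "iucn": ["CR", "LC"], "has_sdm": [True, False],
        **{f"pref_{c}": [1.0, 0.5] for c in range(1, 8)},
    })
    path = tmp_path / "taxa.csv"
    df.to_csv(path, index=False)
    recs = read_taxon_table(path)
    assert [r.iucn for r in recs] == ["CR", "LC"]
    assert recs[1].has_sdm is False
    assert recs[0].habitat_prefs[3] == 1.0
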