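"""Representation curves, per-proxy representation, overlays, genetic validation."""

import numpy as np
import pandas as pd
import pytest

from pgdplan.grids import GridError, GridSpec, LabelGrid, ValueGrid
from pgdplan.pgd import PGDMap
from pgdplan.prioritize import RankConfig, caz_rank, top_fraction
from pgdplan.evaluate import (
    adjusted_rand_index,
    assign_samples_to_pgd,
    cluster_zone_crosstab,
    overlay_stats,
    pgd_area_representation,
    representation_curves,
    taxon_mean_pgd_representation,
)

from conftest import make_feature_set


def make_pgd(labels, spec=None):
    labels = np.asarray(labels)
    if spec is None:
        spec = GridSpec(labels.shape[0], labels.shape[1], 0.0,
                        labels.shape[0] * 1000.0, 1000.0)
    ids = sorted(set(labels.ravel()) - {0})
    prov = pd.DataFrame({"pgd_id": ids, "lifezone_id": 1, "divider_combo": "",
                         "n_cells": [int((labels == i).sum()) for i in ids]})
    return PGDMap(zones=LabelGrid(spec=spec, labels=labels), provenance=prov)


class TestCurves:
    def test_worked_example_rep_at_half(self, worked_2x2, spec2):
        fs, _ = worked_2x2
        rank = caz_rank(fs, land_mask=np.ones((2, 2), bool))
        curves = representation_curves(rank, fs)
        # retained {cell1, cell4}: feature A keeps 3 of 4
        assert curves.at(0.5)["A"] == pytest.approx(3 / 4)

    def test_endpoints_and_monotonicity(self, spec3):
        rng = np.random.default_rng(1)
        fs = make_feature_set(spec3, rng.uniform(0, 1, (3, 9)))
        rank = caz_rank(fs, land_mask=np.ones((3, 3), bool))
        curves = representation_curves(rank, fs)
        for row in curves.proportions:
            assert row[0] == 0.0
            assert row[-1] == pytest.approx(1.0)
            assert (np.diff(row) >= -1e-12).all()

    def test_uniform_feature_diagonal(self, spec3):
        fs = make_feature_set(spec3, [np.ones(9)])
        rank = caz_rank(fs, land_mask=np.ones((3, 3), bool))
        curves = representation_curves(rank, fs)
        np.testing.assert_allclose(curves.proportions[0], np.arange(10) / 9)

    def test_zero_total_feature_reported_undefined(self, spec3):
        from pgdplan.features import FeatureLayer, FeatureSet
        layers = [
            FeatureLayer("good", "good", 0, "raster", np.arange(9),
                         np.ones(9)),
            FeatureLayer("empty", "empty", 0, "raster", np.array([], int),
                         np.array([])),
        ]
        fs = FeatureSet(spec=spec3, layers=layers)
        rank = caz_rank(fs, land_mask=np.ones((3, 3), bool))
        curves = representation_curves(rank, fs)
        assert curves.undefined == ["empty"]
        assert np.isnan(curves.at(0.5)["empty"])


class TestTaxonMeans:
    def make_curves_fs(self, spec3, layer_spec):
        from pgdplan.features import FeatureLayer, FeatureSet
        layers = [
            FeatureLayer(fid, taxon, pgd, "raster", np.asarray(cells, int),
                         np.ones(len(cells)))
            for fid, taxon, pgd, cells in layer_spec
        ]
        fs = FeatureSet(spec=spec3, layers=layers)
        rank = caz_rank(fs, land_mask=np.ones((3, 3), bool))
        return representation_curves(rank, fs), fs

    def test_single_layer_returns_its_value(self, spec3):
        curves, fs = self.make_curves_fs(spec3, [("t@1", "t", 1, range(9))])
        df = taxon_mean_pgd_representation(curves, fs, 1.0)
        assert df.loc[df.taxon == "t", "mean_pgd_representation"].item() == 1.0

    def test_arithmetic_mean_of_two_layers(self, spec2):
        from pgdplan.features import FeatureLayer, FeatureSet
        layers = [
            FeatureLayer("t@1", "t", 1, "raster", np.array([0, 1]), np.ones(2)),
            FeatureLayer("t@2", "t", 2, "raster", np.array([2, 3]), np.ones(2)),
        ]
        fs = FeatureSet(spec=spec2, layers=layers)
        rank = caz_rank(fs, land_mask=np.ones((2, 2), bool))
        curves = representation_curves(rank, fs)
        f = 0.5
        df = taxon_mean_pgd_representation(curves, fs, f)
        expect = np.mean([curves.at(f)["t@1"], curves.at(f)["t@2"]])
        assert df["mean_pgd_representation"].item() == pytest.approx(expect)

    def test_consistency_with_mask_counting_oracle(self, spec3):
        rng = np.random.default_rng(3)
        layer_spec = []
        for t in range(5):
            for g in (1, 2):
                cells = rng.choice(9, size=rng.integers(1, 6), replace=False)
                layer_spec.append((f"t{t}@{g}", f"t{t}", g, cells))
        curves, fs = self.make_curves_fs(spec3, layer_spec)
        rank = caz_rank(fs, land_mask=np.ones((3, 3), bool))
        f = 1 / 3
        mask = top_fraction(rank, f).labels.ravel() > 0
        df = taxon_mean_pgd_representation(curves, fs, f).set_index("taxon")
        for t in range(5):
            reps = []
            for lyr in fs.layers:
                if lyr.taxon_id == f"t{t}":
                    reps.append(mask[lyr.cells].sum() / lyr.cells.size)
            assert df.loc[f"t{t}", "mean_pgd_representation"] == pytest.approx(
                np.mean(reps)
            )

    def test_taxon_without_layers_excluded(self, spec3):
        curves, fs = self.make_curves_fs(
            spec3, [("a@1", "a", 1, range(9)), ("b", "b", 0, range(4))]
        )
        df = taxon_mean_pgd_representation(curves, fs, 0.5)
        assert "b" not in set(df["taxon"])
        assert df.attrs["excluded"] == ["b"]


class TestPgdRepresentation:
    def test_full_mask_all_ones(self):
        pgd = make_pgd([[1, 1], [2, 2]])
        spec = pgd.zones.spec
        sdm = ValueGrid(spec=spec, values=np.ones((2, 2)))
        mask = LabelGrid(spec=spec, labels=np.ones((2, 2), int))
        df = pgd_area_representation(mask, sdm, pgd)
        assert (df["proportion"] == 1.0).all()

    def test_cell_counting_oracle(self):
        pgd = make_pgd([[1, 1, 1, 2], [1, 2, 2, 2]])
        spec = pgd.zones.spec
        sdm_vals = np.array([[1, 1, 1, 1], [1, 0, 0, 1]], float)
        sdm = ValueGrid(spec=spec, values=sdm_vals)
        mask = LabelGrid(spec=spec, labels=np.array([[1, 1, 0, 1], [0, 0, 0, 1]]))
        df = pgd_area_representation(mask, sdm, pgd).set_index("pgd_id")
        # SDM&g1 = 4 cells, 2 retained; SDM&g2 = 2 cells, 2 retained
        assert df.loc[1, "proportion"] == pytest.approx(2 / 4)
        assert df.loc[2, "proportion"] == pytest.approx(2 / 2)

    def test_disjoint_mask_all_zero(self):
        pgd = make_pgd([[1, 2]])
        spec = pgd.zones.spec
        sdm = ValueGrid(spec=spec, values=np.array([[1.0, 0.0]]))
        mask = LabelGrid(spec=spec, labels=np.array([[0, 1]]))
        df = pgd_area_representation(mask, sdm, pgd)
        assert (df["proportion"] == 0).all()
        assert set(df["pgd_id"]) == {1}  # empty-overlap proxy omitted


class TestOverlay:
    def test_superset_subset_and_fraction(self):
        spec = GridSpec(2, 5, 0.0, 2.0, 1.0)
        mask = LabelGrid(spec=spec, labels=np.ones((2, 5), int))
        superset = LabelGrid(spec=spec, labels=np.ones((2, 5), int))
        disjoint = LabelGrid(spec=spec, labels=np.zeros((2, 5), int))
        three = np.zeros((2, 5), int); three.ravel()[:3] = 1
        partial = LabelGrid(spec=spec, labels=three)
        df = overlay_stats(mask, {"all": superset, "none": disjoint, "part": partial})
        out = df.set_index("layer")["proportion"]
        assert out["all"] == 1.0 and out["none"] == 0.0
        assert out["part"] == pytest.approx(0.3)

    def test_empty_mask_rejected(self):
        spec = GridSpec(1, 1, 0.0, 1.0, 1.0)
        empty = LabelGrid(spec=spec, labels=np.zeros((1, 1), int))
        with pytest.raises(GridError):
            overlay_stats(empty, {"x": empty})


class TestSampleAssignment:
    def grid_pgd(self):
        # 6x6, zone 7 left half, zone 9 right half
        labels = np.full((6, 6), 7)
        labels[:, 3:] = 9
        return make_pgd(labels)

    def test_deep_sample_gets_its_zone(self):
        pgd = self.grid_pgd()
        s = pd.DataFrame({"id": ["a"], "x": [500.0], "y": [5500.0]})
        out = assign_samples_to_pgd(s, pgd, radius=0.0)
        assert out["pgd_id"].item() == 7

    def test_boundary_majority_counting_oracle(self):
        pgd = self.grid_pgd()
        spec = pgd.zones.spec
        # point near the 7|9 boundary; count cell centers within the radius
        x, y = 3100.0, 3000.0
        radius = 1600.0
        cx, cy = spec.cell_centers()
        d2 = (cx - x) ** 2 + (cy - y) ** 2
        near = pgd.zones.labels[d2 <= radius**2]
        counts = pd.Series(near[near > 0]).value_counts()
        s = pd.DataFrame({"id": ["a"], "x": [x], "y": [y]})
        out = assign_samples_to_pgd(s, pgd, radius=radius)
        assert out["pgd_id"].item() == counts.idxmax()

    def test_tie_goes_to_smallest_id(self):
        labels = np.zeros((2, 2), int)
        labels[:, 0] = 3
        labels[:, 1] = 8  # 2 cells each within the buffer
        pgd = make_pgd(labels)
        s = pd.DataFrame({"id": ["a"], "x": [1000.0], "y": [1000.0]})
        out = assign_samples_to_pgd(s, pgd, radius=3000.0)
        assert out["pgd_id"].item() == 3

    def test_all_nodata_neighborhood_unassigned(self):
        labels = np.zeros((3, 3), int)
        labels[0, 0] = 2
        pgd = make_pgd(labels)
        s = pd.DataFrame({"id": ["a"], "x": [2500.0], "y": [500.0]})
        out = assign_samples_to_pgd(s, pgd, radius=500.0)
        assert out["pgd_id"].item() == 0

    def test_nonfinite_coordinates_rejected(self):
        pgd = self.grid_pgd()
        s = pd.DataFrame({"id": ["a"], "x": [np.inf], "y": [0.0]})
        with pytest.raises(GridError):
            assign_samples_to_pgd(s, pgd, radius=0.0)


class TestCrosstab:
    def samples(self, dominant, pgd_ids, k=4):
        mem = np.full((len(dominant), k), 0.01)
        for i, d in enumerate(dominant):
            mem[i, d] = 1 - 0.01 * (k - 1)
        df = pd.DataFrame({"id": [f"s{i}" for i in range(len(dominant))],
                           "pgd_id": pgd_ids})
        for j in range(k):
            df[f"q{j}"] = mem[:, j]
        return df

    def test_identical_partitions_ari_one(self):
        df = self.samples([0, 0, 1, 1, 2, 2], [1, 1, 2, 2, 3, 3])
        table, ari = cluster_zone_crosstab(df)
        assert table.to_numpy().sum() == 6
        assert ari == pytest.approx(1.0)

    def test_degenerate_single_cluster_ari_zero(self):
        df = self.samples([0] * 6, [1, 1, 2, 2, 3, 3])
        _, ari = cluster_zone_crosstab(df)
        assert ari == pytest.approx(0.0)

    def test_ari_matches_sklearn_pair_counting(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 5, 60)
            table = pd.crosstab(a, b).to_numpy()
            assert adjusted_rand_index(table) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_unassigned_excluded_and_counted(self):
        df = self.samples([0, 0, 1], [1, 0, 2])
        table, _ = cluster_zone_crosstab(df)
        assert table.to_numpy().sum() == 2
        assert table.attrs["n_unassigned"] == 1

    def test_bad_memberships_rejected(self):
        df = self.samples([0, 1], [1, 2])
        df["q0"] = 5.0
        with pytest.raises(GridError):
            cluster_zone_crosstab(df)
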