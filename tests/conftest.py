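"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pgdplan.grids import GridSpec, LabelGrid, ValueGrid
from pgdplan.features import FeatureLayer, FeatureSet


@pytest.fixture
def spec3():
    return GridSpec(n_rows=3, n_cols=3, origin_x=0.0, origin_y=3000.0,
                    cell_size=1000.0, crs_id="EPSG:3395")


@pytest.fixture
def spec2():
    return GridSpec(n_rows=2, n_cols=2, origin_x=0.0, origin_y=2.0,
                    cell_size=1.0, crs_id="test")


def make_feature_set(spec: GridSpec, dense_layers, weights=None, ids=None) -> FeatureSet:
    """Build a FeatureSet from dense per-cell value arrays (row-major flat)."""
    layers = []
    for j, vals in enumerate(dense_layers):
        vals = np.asarray(vals, dtype=float).ravel()
        cells = np.flatnonzero(vals > 0)
        layers.append(
            FeatureLayer(
                feature_id=(ids[j] if ids else f"f{j}"),
                taxon_id=(ids[j] if ids else f"f{j}"),
                pgd_id=0,
                kind="raster",
                cells=cells,
                values=vals[cells],
                weight=1.0 if weights is None else float(weights[j]),
            )
        )
    return FeatureSet(spec=spec, layers=layers)


def caz_oracle_order(values: np.ndarray, weights: np.ndarray) -> list[int]:
    """Brute-force greedy core-area removal, recomputing delta each step.

    ``values``: (n_features, n_cells) non-negative; positive weights only.
    Returns flat cell positions in removal order; ties to the lowest index.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_feat, n = values.shape
    remaining = np.ones(n, dtype=bool)
    order: list[int] = []
    while remaining.any():
        idx = np.flatnonzero(remaining)
        q = values[:, idx].sum(axis=1)
        best_d, best_i = None, None
        for i in idx:
            d = 0.0
            for j in range(n_feat):
                if q[j] > 0:
                    d = max(d, weights[j] * values[j, i] / q[j])
            if best_d is None or d < best_d:
                best_d, best_i = d, int(i)
        order.append(best_i)
        remaining[best_i] = False
    return order


@pytest.fixture
def worked_2x2(spec2):
    """The 4-cell two-feature instance whose removal order is known by hand."""
    a = [3.0, 1.0, 0.0, 0.0]
    b = [0.0, 0.0, 2.0, 2.0]
    fs = make_feature_set(spec2, [a, b], ids=["A", "B"])
    return fs, np.array([a, b])
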