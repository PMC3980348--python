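"""Modality normalization, weighting, fusion bookkeeping, weight grid."""

import numpy as np
import pytest
from scipy import stats

from srvs import (
    ModalityMatrix,
    SRVSConfig,
    build_design,
    fuse,
    gen_white_noise,
    normalize_columns,
    srvs_select,
    weight_grid,
)


def _mat(values, tag="m1", prefix="v"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ModalityMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        variable_ids=[f"{prefix}{j}" for j in range(p)],
        modality_tag=tag,
    )


# ---------------------------------------------------------------------------
# normalize_columns


def test_three_four_five_triangle():
    m = normalize_columns(_mat([[3.0], [4.0]]), center=False)
    np.testing.assert_allclose(m.values[:, 0], [0.6, 0.8])


def test_zero_column_flagged_unselectable():
    m = normalize_columns(_mat([[0.0, 1.0], [0.0, 2.0]]), center=False)
    assert m.unselectable.tolist() == [True, False]
    assert np.all(m.values[:, 0] == 0.0)


def test_constant_column_zero_after_centering():
    m = normalize_columns(_mat([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]]), center=True)
    assert m.unselectable.tolist() == [True, False]


def test_random_matrix_unit_norms(rng):
    m = normalize_columns(_mat(rng.standard_normal((20, 50))))
    np.testing.assert_allclose(np.linalg.norm(m.values, axis=0), 1.0, atol=1e-12)


def test_non_finite_rejected():
    with pytest.raises(ValueError):
        _mat([[np.nan], [1.0]])


# ---------------------------------------------------------------------------
# fuse


def test_duplicated_modality_blocks_identical(rng):
    vals = rng.standard_normal((10, 6))
    d = fuse(_mat(vals, "a"), _mat(vals, "b", prefix="w"), alpha1=0.5)
    np.testing.assert_array_equal(d.matrix[:, :6], d.matrix[:, 6:])


def test_column_map_bookkeeping(rng):
    d = fuse(
        _mat(rng.standard_normal((5, 3)), "geno"),
        _mat(rng.standard_normal((5, 2)), "img", prefix="w"),
        alpha1=0.4,
    )
    assert d.n_columns == 5
    assert d.column_map[3] == ("img", "w0")
    assert d.column_map[0] == ("geno", "v0")
    assert d.block_slices["img"] == slice(3, 5)


def test_block_norms_equal_weights(rng):
    d = fuse(
        _mat(rng.standard_normal((20, 8)), "a"),
        _mat(rng.standard_normal((20, 5)), "b", prefix="w"),
        alpha1=0.46,
    )
    norms = np.linalg.norm(d.matrix, axis=0)
    np.testing.assert_allclose(norms[:8], 0.46, atol=1e-12)
    np.testing.assert_allclose(norms[8:], 0.54, atol=1e-12)


def test_split_roundtrip_recovers_unit_blocks(rng):
    m1 = _mat(rng.standard_normal((12, 4)), "a")
    m2 = _mat(rng.standard_normal((12, 3)), "b", prefix="w")
    d = fuse(m1, m2, alpha1=0.3)
    blocks = d.split()
    np.testing.assert_allclose(np.linalg.norm(blocks["a"], axis=0), 1.0, atol=1e-12)
    np.testing.assert_allclose(np.linalg.norm(blocks["b"], axis=0), 1.0, atol=1e-12)
    # weights rescale blocks but never reorder columns
    d2 = fuse(m1, m2, alpha1=0.6)
    np.testing.assert_allclose(d2.split()["a"], blocks["a"], atol=1e-12)


def test_transform_rows_maps_training_rows_exactly(rng):
    m1 = _mat(rng.standard_normal((9, 4)), "a")
    m2 = _mat(rng.standard_normal((9, 3)), "b", prefix="w")
    d = fuse(m1, m2, alpha1=0.35)
    got = d.transform_rows({"a": m1.values[2], "b": m2.values[2]})
    np.testing.assert_allclose(got[0], d.matrix[2], atol=1e-12)


def test_fusion_preconditions(rng):
    m1 = _mat(rng.standard_normal((5, 2)), "a")
    m2 = _mat(rng.standard_normal((5, 2)), "b", prefix="w")
    with pytest.raises(ValueError):
        fuse(m1, m2, alpha1=1.2)
    m3 = ModalityMatrix(
        values=rng.standard_normal((5, 2)),
        sample_ids=["x0", "x1", "x2", "x3", "x4"],
        variable_ids=["w0", "w1"],
        modality_tag="b",
    )
    with pytest.raises(ValueError):
        fuse(m1, m3, alpha1=0.5)


# ---------------------------------------------------------------------------
# weight grid


def test_reported_grid_has_sixteen_trials():
    grid = weight_grid(0.3, 0.6, 0.02)
    assert len(grid) == 16
    assert grid[0] == 0.3
    assert grid[-1] == 0.6
    assert all(b > a for a, b in zip(grid, grid[1:]))
    # exact decimal arithmetic: no floating-point accumulation artifacts
    assert 0.42 in grid and 0.46 in grid


def test_degenerate_grid():
    assert weight_grid(0.5, 0.5, 0.02) == [0.5]


def test_grid_span_must_be_multiple_of_step():
    with pytest.raises(ValueError):
        weight_grid(0.3, 0.6, 0.07)
    with pytest.raises(ValueError):
        weight_grid(0.6, 0.3, 0.02)
    with pytest.raises(ValueError):
        weight_grid(0.3, 0.6, -0.02)


# ---------------------------------------------------------------------------
# exchangeability of duplicated modalities


def test_duplicated_modalities_selected_symmetrically():
    """With modality 2 an exact copy of modality 1 and equal weights, the
    selector must not systematically favor either block: the per-seed
    difference in selected counts has no consistent sign (sign test)."""
    diffs = []
    for s in range(20):
        ds = gen_white_noise(10, 10, 60, seed=800 + s)
        twin = ModalityMatrix(
            values=ds.modality1.values.copy(),
            sample_ids=list(ds.modality1.sample_ids),
            variable_ids=[f"copy_{v}" for v in ds.modality1.variable_ids],
            modality_tag="copy",
        )
        d = fuse(ds.modality1, twin, alpha1=0.5)
        res = srvs_select(
            d, ds.phenotype, SRVSConfig(window_size=30, seed=900 + s, max_steps=40)
        )
        p1 = ds.modality1.n_variables
        diffs.append(int((res.support < p1).sum()) - int((res.support >= p1).sum()))
    signs = [d for d in diffs if d != 0]
    assert signs, "degenerate: all differences zero"
    n_pos = sum(d > 0 for d in signs)
    p = stats.binomtest(n_pos, len(signs), 0.5).pvalue
    assert p > 0.05
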