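"""Window planning and the windowed accumulation loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from srvs import SRVSConfig, SRVSSelector, build_design, gen_planted, omp_solve, plan_windows, srvs_select
from srvs.core import _prepare_target, lars_solve


# ---------------------------------------------------------------------------
# plan_windows


def test_single_full_window():
    plan = plan_windows(6, 6, np.random.default_rng(0))
    assert len(plan.windows) == 1
    assert sorted(plan.windows[0].tolist()) == list(range(6))


def test_partition_arithmetic():
    plan = plan_windows(10, 4, np.random.default_rng(0))
    assert [w.size for w in plan.windows] == [4, 4, 2]
    flat = np.concatenate(plan.windows)
    assert sorted(flat.tolist()) == list(range(10))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p=st.integers(min_value=1, max_value=500),
    k=st.integers(min_value=1, max_value=500),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_windows_partition_all_columns(p, k, seed):
    """Every pass visits each column exactly once, in blocks of size k
    (last block possibly smaller)."""
    if k > p:
        with pytest.raises(ValueError):
            plan_windows(p, k, np.random.default_rng(seed))
        return
    plan = plan_windows(p, k, np.random.default_rng(seed))
    sizes = [w.size for w in plan.windows]
    assert all(s == k for s in sizes[:-1])
    assert 1 <= sizes[-1] <= k
    assert sorted(np.concatenate(plan.windows).tolist()) == list(range(p))


def test_different_seeds_different_permutations():
    a = plan_windows(1000, 100, np.random.default_rng(1))
    b = plan_windows(1000, 100, np.random.default_rng(2))
    assert len(a.windows) == len(b.windows) == 10
    assert not np.array_equal(a.pass_permutation, b.pass_permutation)


def test_bad_window_sizes_rejected():
    with pytest.raises(ValueError):
        plan_windows(5, 0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        plan_windows(5, 6, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# config


def test_config_validation():
    with pytest.raises(ValueError):
        SRVSConfig(norm_order=2)
    with pytest.raises(ValueError):
        SRVSConfig(omp_residual_frac=1.5)
    with pytest.raises(ValueError):
        SRVSConfig(convergence_tol=0.0)
    cfg = SRVSConfig(window_size=0.05)
    assert cfg.resolve_k(1000) == 50
    assert SRVSConfig(window_size=1.0).resolve_k(7) == 7
    assert SRVSConfig(window_size=3).resolve_k(7) == 3
    with pytest.raises(ValueError):
        SRVSConfig(window_size=10).resolve_k(7)
    with pytest.raises(ValueError):
        SRVSConfig(window_size=2, max_steps=2, min_passes=1).resolve_max_steps(10, 2)


# ---------------------------------------------------------------------------
# srvs_select


def test_deterministic_given_seed(tiny_planted):
    design = build_design(tiny_planted.modality1)
    cfg = SRVSConfig(window_size=20, seed=9)
    a = srvs_select(design, tiny_planted.phenotype, cfg)
    b = srvs_select(design, tiny_planted.phenotype, cfg)
    assert np.array_equal(a.delta, b.delta)
    assert np.array_equal(a.change_history, b.change_history)
    c = srvs_select(design, tiny_planted.phenotype, SRVSConfig(window_size=20, seed=10))
    assert not np.array_equal(a.delta, c.delta)


def test_full_window_reduces_to_plain_omp(tiny_planted):
    """k = p: every step solves the identical full-design problem, so the
    average is constant, convergence hits at step 2 with zero change, and
    delta equals the single OMP solution (support <= n)."""
    design = build_design(tiny_planted.modality1)
    p = design.n_columns
    res = srvs_select(design, tiny_planted.phenotype, SRVSConfig(window_size=p, seed=0))
    assert res.converged
    assert res.steps == 2
    assert res.change_history[0] == pytest.approx(0.0, abs=1e-6)
    y = _prepare_target(tiny_planted.phenotype.values)
    full = omp_solve(design.matrix, y, max_atoms=design.n_samples, residual_eps=0.3)
    dense = np.zeros(p)
    dense[full.atom_indices] = full.coefficients
    np.testing.assert_allclose(res.delta, dense, atol=1e-10)
    assert res.support.size <= design.n_samples


def test_zero_design_selects_nothing(tiny_planted):
    X = np.zeros((30, 40))
    res = srvs_select(X, tiny_planted.phenotype.values, SRVSConfig(window_size=10, seed=0))
    assert res.support.size == 0
    assert np.all(res.delta == 0)
    assert res.converged  # the all-zero average is trivially stable


def test_dimension_mismatch_raises(tiny_planted):
    design = build_design(tiny_planted.modality1)
    with pytest.raises(ValueError):
        srvs_select(design, np.ones(7), SRVSConfig(window_size=10))


def test_constant_phenotype_rejected():
    X = np.random.default_rng(0).standard_normal((10, 20))
    with pytest.raises(ValueError):
        srvs_select(X, np.ones(10), SRVSConfig(window_size=5))


def test_change_history_starts_at_step_two(tiny_planted):
    design = build_design(tiny_planted.modality1)
    res = srvs_select(design, tiny_planted.phenotype, SRVSConfig(window_size=25, seed=3))
    assert res.change_history.size == res.steps - 1
    assert np.isfinite(res.change_history).all()


def test_support_bound_after_one_pass(tiny_planted):
    design = build_design(tiny_planted.modality1)
    n, p, k = design.n_samples, design.n_columns, 25
    n_windows = -(-p // k)
    res = srvs_select(
        design,
        tiny_planted.phenotype,
        SRVSConfig(window_size=k, seed=5, max_steps=n_windows, min_passes=1),
    )
    assert res.steps == n_windows
    assert res.support.size <= n_windows * min(n, k)


def test_loop_matches_naive_reimplementation(tiny_planted):
    """Oracle check of the whole accumulation loop: a direct, dense
    re-implementation (explicit delta_l / l differencing, no incremental
    norm bookkeeping) run on the same seed gives bit-comparable results."""
    design = build_design(tiny_planted.modality1)
    X, p = design.matrix, design.n_columns
    cfg = SRVSConfig(window_size=30, seed=77, max_steps=12, min_passes=1)
    res = srvs_select(design, tiny_planted.phenotype, cfg)

    y = _prepare_target(tiny_planted.phenotype.values)
    rng = np.random.default_rng(77)
    acc = np.zeros(p)
    l = 0
    prev_avg = None
    changes = []
    done = False
    n_pass = 0
    while not done:
        plan = plan_windows(p, 30, rng)
        for win in plan.windows:
            l += 1
            sol = omp_solve(X[:, win], y, max_atoms=min(30, 30), residual_eps=0.3)
            acc[win[sol.atom_indices]] += sol.coefficients
            avg = acc / l
            if l >= 2:
                changes.append(np.linalg.norm(avg - prev_avg))
            prev_avg = avg.copy()
            if l >= 2 and n_pass >= 1 and changes[-1] <= cfg.convergence_tol:
                done = True
                break
            if l >= 12:
                done = True
                break
        n_pass += 1

    assert res.steps == l
    np.testing.assert_allclose(res.delta, acc / l, atol=1e-12)
    np.testing.assert_allclose(res.change_history, changes, atol=1e-9)


def test_l1_homotopy_variant_recovers_exact_sparse():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((30, 12))
    X /= np.linalg.norm(X, axis=0)
    beta = np.zeros(12)
    beta[[2, 7]] = [1.5, -2.0]
    y = X @ beta
    sol = lars_solve(X, y, max_atoms=5, residual_eps=1e-6)
    assert set(sol.atom_indices.tolist()) == {2, 7}
    dense = np.zeros(12)
    dense[sol.atom_indices] = sol.coefficients
    np.testing.assert_allclose(dense, beta, atol=1e-4)


# ---------------------------------------------------------------------------
# estimator surface


def test_selector_is_sklearn_compatible(tiny_planted):
    sel = SRVSSelector(window_size=25, n_top=5, random_state=1)
    assert clone(sel).get_params() == sel.get_params()
    X = tiny_planted.modality1.values
    y = tiny_planted.phenotype.values
    sel.fit(X, y)
    assert sel.delta_.shape == (X.shape[1],)
    mask = sel.get_support()
    assert mask.sum() == 5
    reduced = sel.transform(X)
    assert reduced.shape == (X.shape[0], 5)
    truth = set(tiny_planted.truth["column_index"].tolist())
    assert len(set(sel.support_indices_.tolist()) & truth) == 5


def test_selector_tau_rule(tiny_planted):
    sel = SRVSSelector(window_size=25, tau=0.95, random_state=1)
    sel.fit(tiny_planted.modality1.values, tiny_planted.phenotype.values)
    assert 0 < sel.get_support().sum() < tiny_planted.modality1.n_variables
    with pytest.raises(ValueError):
        SRVSSelector(n_top=3, tau=0.5).fit(
            tiny_planted.modality1.values, tiny_planted.phenotype.values
        )
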