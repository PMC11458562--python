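"""Sparse CCA core: residualization, L1 projection, solver, top-k selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from neuroscca.scca import (SparseCCA, groupwise_scca, l1_constrain,
                            residualize, scca_fit, soft_threshold, top_k_snps,
                            tune_tau)
from neuroscca.simulate import SimulationConfig, simulate_cohort

from conftest import make_genotypes


# ------------------------------------------------------------- residualize

def test_residualize_no_covariates_is_zscore(rng):
    Y = rng.standard_normal((50, 3)) * 4 + 2
    adj = residualize(Y, None)
    np.testing.assert_allclose(adj.values.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(adj.values.std(axis=0), 1, atol=1e-10)


def test_residuals_orthogonal_to_covariates(rng):
    C = rng.standard_normal((200, 4))
    Y = rng.standard_normal((200, 5)) + C @ rng.standard_normal((4, 5))
    adj = residualize(Y, C)
    dots = np.abs(C.T @ adj.values) / 200
    assert dots.max() < 1e-10


def test_residualize_degenerate_column_flagged(rng):
    C = rng.standard_normal((100, 2))
    Y = np.column_stack([C @ [1.0, -2.0], rng.standard_normal(100)])
    with pytest.warns(UserWarning, match="degenerate"):
        adj = residualize(Y, C, roi_labels=["lin", "ok"])
    assert adj.degenerate == ["lin"]
    np.testing.assert_allclose(adj.values[:, 0], 0.0)


def test_residualize_collinear_covariates_rejected(rng):
    C = rng.standard_normal((100, 2))
    C = np.column_stack([C, C[:, 0] * 2.0])
    with pytest.raises(ValueError, match="collinear"):
        residualize(rng.standard_normal((100, 3)), C)


# ----------------------------------------------------------- soft threshold

@pytest.mark.parametrize("a, c, expected", [
    ([3.0, -0.5], 1.0, [2.0, 0.0]),
    ([3.0, -0.5], 0.0, [3.0, -0.5]),
    ([3.0, -0.5], 5.0, [0.0, 0.0]),
])
def test_soft_threshold(a, c, expected):
    np.testing.assert_allclose(soft_threshold(np.array(a), c), expected)


# ------------------------------------------------------------ l1 constraint

def test_l1_constrain_inactive_budget_returns_unit_vector(rng):
    w = rng.standard_normal(16)
    out = l1_constrain(w, np.sqrt(16))
    np.testing.assert_allclose(out, w / np.linalg.norm(w), atol=1e-12)


def test_l1_constrain_tau_one_is_one_sparse(rng):
    w = rng.standard_normal(20)
    out = l1_constrain(w, 1.0)
    k = np.argmax(np.abs(w))
    assert np.count_nonzero(out) == 1
    assert out[k] == pytest.approx(np.sign(w[k]))


def _grid_oracle(w, tau):
    """Independent route: two-stage fine grid over the soft threshold."""
    def l1_at(d):
        s = soft_threshold(w, d)
        nrm = np.linalg.norm(s)
        return np.abs(s).sum() / nrm if nrm > 0 else 0.0

    lo, hi = 0.0, np.abs(w).max() * 0.9999
    for _ in range(2):  # coarse pass then local refinement
        grid = np.linspace(lo, hi, 4001)
        feas = [d for d in grid if l1_at(d) <= tau + 1e-9]
        d_star = feas[0]
        idx = np.searchsorted(grid, d_star)
        lo, hi = grid[max(idx - 1, 0)], d_star
    s = soft_threshold(w, d_star)
    return s / np.linalg.norm(s)


def test_l1_constrain_matches_grid_oracle(rng):
    for _ in range(20):
        w = rng.standard_normal(rng.integers(5, 40))
        tau = float(rng.uniform(1.0, np.sqrt(len(w))))
        out = l1_constrain(w, tau)
        oracle = _grid_oracle(w, tau)
        assert abs(np.linalg.norm(out) - 1) < 1e-9
        assert np.abs(out).sum() <= tau + 1e-6
        assert abs(np.abs(out).sum() - np.abs(oracle).sum()) < 1e-3


@given(hnp.arrays(np.float64, st.integers(4, 30),
                  elements=st.floats(-5, 5, allow_nan=False)),
       st.floats(1.0, 5.0))
@settings(max_examples=80, derandomize=True, deadline=None)
def test_l1_constrain_invariants(w, tau):
    if np.linalg.norm(w) < 1e-9:
        return
    tau = min(tau, float(np.sqrt(len(w))))
    out = l1_constrain(w, tau)
    assert abs(np.linalg.norm(out) - 1.0) < 1e-8
    assert np.abs(out).sum() <= tau + 1e-5


def test_l1_constrain_zero_vector_rejected():
    with pytest.raises(ValueError):
        l1_constrain(np.zeros(5), 2.0)


# ------------------------------------------------------------------- solver

def _orthonormal_columns(rng, n, k):
    A = rng.standard_normal((n, k))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q * np.sqrt(n - 1)


def classical_cca_rho(X, Y):
    """Independent oracle: first canonical correlation via the generalized
    eigendecomposition of the CCA normal equations."""
    n = X.shape[0]
    Sxx, Syy = X.T @ X / (n - 1), Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    return float(np.sqrt(np.max(np.real(np.linalg.eigvals(M)))))


def test_scca_single_shared_column_is_exact(rng):
    x = rng.standard_normal(60)
    X = ((x - x.mean()) / x.std())[:, None]
    res = scca_fit(X, X.copy())
    assert res.rho == pytest.approx(1.0)
    assert abs(res.u[0]) == pytest.approx(1.0)
    assert res.v[0] * res.u[0] > 0


def test_scca_matches_classical_cca_on_orthonormal_design(rng):
    for _ in range(5):
        X = _orthonormal_columns(rng, 120, 8)
        Y = _orthonormal_columns(rng, 120, 5)
        res = scca_fit(X, Y)
        assert abs(abs(res.rho) - classical_cca_rho(X, Y)) < 1e-4


def test_scca_objective_monotone(rng):
    X = rng.standard_normal((80, 12))
    Y = rng.standard_normal((80, 6)) + 0.5 * X[:, :6]
    res = scca_fit(X, Y, tau1=2.0, tau2=1.5)
    trace = np.array(res.objective_trace)
    assert np.all(np.diff(trace) >= -1e-10)


def test_scca_constraints_hold(rng):
    X = rng.standard_normal((100, 15))
    Y = rng.standard_normal((100, 4))
    res = scca_fit(X, Y, tau1=2.5, tau2=1.2)
    assert abs(np.linalg.norm(res.u) - 1) < 1e-8
    assert abs(np.linalg.norm(res.v) - 1) < 1e-8
    assert np.abs(res.u).sum() <= 2.5 + 1e-6
    assert np.abs(res.v).sum() <= 1.2 + 1e-6
    xu, yv = X @ res.u, Y @ res.v
    assert res.rho == pytest.approx(np.corrcoef(xu, yv)[0, 1])


def test_scca_independent_data_not_significant(rng):
    hits = 0
    for rep in range(10):
        X = rng.standard_normal((400, 10))
        Y = rng.standard_normal((400, 5))
        rho = abs(scca_fit(X, Y).rho)
        null = [abs(scca_fit(X[rng.permutation(400)], Y).rho) for _ in range(30)]
        p = (1 + sum(r >= rho for r in null)) / 31
        hits += p > 0.05
    assert hits >= 8


def test_scca_bitwise_reproducible(rng):
    X = rng.standard_normal((60, 9))
    Y = rng.standard_normal((60, 4))
    r1 = scca_fit(X, Y, tau1=2.0, tau2=1.5)
    r2 = scca_fit(X, Y, tau1=2.0, tau2=1.5)
    assert np.array_equal(r1.u, r2.u) and np.array_equal(r1.v, r2.v)
    assert r1.rho == r2.rho
    k = np.argmax(np.abs(r1.u))
    assert r1.u[k] > 0  # sign convention


def test_scca_input_validation(rng):
    X = rng.standard_normal((50, 4))
    Y = rng.standard_normal((50, 3))
    with pytest.raises(ValueError, match="NaN"):
        Xn = X.copy(); Xn[0, 0] = np.nan
        scca_fit(Xn, Y)
    with pytest.raises(ValueError, match="tau1"):
        scca_fit(X, Y, tau1=0.5)
    with pytest.raises(ValueError, match="tau1"):
        scca_fit(X, Y, tau1=10.0)


def test_sparse_cca_estimator_api(rng):
    X = rng.standard_normal((50, 6))
    Y = rng.standard_normal((50, 3))
    est = SparseCCA(tau1=2.0)
    assert est.get_params()["tau1"] == 2.0
    est.set_params(tau2=1.5).fit(X, Y)
    xu, yv = est.transform(X, Y)
    assert xu.shape == (50,) and yv.shape == (50,)
    res = est.result()
    assert res.tau1 == 2.0 and res.tau2 == 1.5


# ----------------------------------------------------------------- tune_tau

def test_tune_tau_single_grid_point(rng):
    X = rng.standard_normal((60, 6))
    Y = rng.standard_normal((60, 3))
    assert tune_tau(X, Y, [(2.0, 1.5)], seed=1) == (2.0, 1.5)


def test_tune_tau_deterministic(rng):
    X = rng.standard_normal((80, 8))
    Y = rng.standard_normal((80, 4)) + 0.3 * X[:, :4]
    grid = [(1.5, 1.5), (2.5, 2.0), (np.sqrt(8), 2.0)]
    assert tune_tau(X, Y, grid, seed=3) == tune_tau(X, Y, grid, seed=3)


def test_tune_tau_prefers_sparse_for_sparse_signal():
    picked_sparse = 0
    for rep in range(10):
        rng = np.random.default_rng(rep)
        X = rng.standard_normal((150, 30))
        t = X[:, 0] - X[:, 1]   # 2-sparse signal
        Y = np.outer(t, [1.0, 0.5, 0.2]) + rng.standard_normal((150, 3)) * 2.0
        tau1, _ = tune_tau(X, Y, [(1.5, np.sqrt(3)), (3.0, np.sqrt(3)),
                                  (np.sqrt(30), np.sqrt(3))], seed=rep)
        picked_sparse += tau1 < np.sqrt(30)
    assert picked_sparse >= 8


# --------------------------------------------------------------- top_k_snps

def test_top_k_ranking_and_ties(rng):
    G = make_genotypes(rng.integers(0, 3, size=(10, 3)).astype(float),
                       ids=["a", "b", "c"])
    res = scca_fit(rng.standard_normal((30, 3)), rng.standard_normal((30, 2)))
    res.u = np.array([0.3, -0.5, 0.1])
    assert top_k_snps(res, G.snps, 2) == ["b", "a"]
    assert top_k_snps(res, G.snps, 3) == ["b", "a", "c"]


def test_top_k_fewer_nonzeros_warns(rng):
    G = make_genotypes(rng.integers(0, 3, size=(10, 4)).astype(float))
    res = scca_fit(rng.standard_normal((30, 4)), rng.standard_normal((30, 2)))
    res.u = np.array([0.0, 0.9, 0.0, 0.1])
    with pytest.warns(UserWarning, match="nonzero"):
        out = top_k_snps(res, G.snps, 3)
    assert out == ["snp1", "snp3"]


# ----------------------------------------------------------- groupwise scca

def _cohort(seed, **kw):
    kw.setdefault("n_causal", 6)
    cfg = SimulationConfig(n_samples=360, n_snps=60, seed=seed, **kw)
    return cfg, simulate_cohort(cfg)


def test_groupwise_identical_groups_agree(rng):
    cfg, (G, pheno, truth) = _cohort(21)
    # duplicate the cohort and label the copies as the two amyloid groups
    import pandas as pd
    from neuroscca.datatypes import GenotypeMatrix
    G2 = GenotypeMatrix(sample_ids=G.sample_ids + [s + "_b" for s in G.sample_ids],
                        snps=G.snps, dosages=np.vstack([G.dosages, G.dosages]))
    ph2 = pd.concat([pheno.assign(amyloid=0.0),
                     pheno.assign(amyloid=1.0,
                                  sample_id=pheno["sample_id"] + "_b")],
                    ignore_index=True)
    out = groupwise_scca(G2, ph2, tau1=3.0, tau2=2.0)
    np.testing.assert_allclose(out["neg"]["result"].u, out["pos"]["result"].u)
    assert out["neg"]["top_snps"] == out["pos"]["top_snps"]
    assert out["neg"]["result"].rho == pytest.approx(out["pos"]["result"].rho)


def test_groupwise_disjoint_signals_beat_pooled():
    wins = 0
    for rep in range(8):
        cfg, (G, pheno, truth) = _cohort(400 + rep, group_signal="disjoint",
                                         n_causal=3, canonical_strength=0.12)
        out = groupwise_scca(G, pheno)
        pooled = out["total"]["result"].rho
        wins += (out["neg"]["result"].rho > pooled) and \
                (out["pos"]["result"].rho > pooled)
    assert wins >= 5


def test_groupwise_small_group_rejected():
    cfg, (G, pheno, truth) = _cohort(23)
    pheno = pheno.copy()
    pheno.loc[pheno.index[:-4], "amyloid"] = 1.0   # leave 4 negatives
    with pytest.raises(ValueError, match="neg"):
        groupwise_scca(G, pheno)
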