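"""Rank-1 sparse canonical correlation analysis.

Solves

    max_{u,v}  u' X' Y v   s.t.  ||u||_2 = 1, ||v||_2 = 1,
                                 ||u||_1 <= tau1, ||v||_1 <= tau2

by alternating maximization in the penalized-matrix-decomposition style:
each half-step soft-thresholds the cross-product direction and rescales to
the unit sphere, with the threshold found by bisection so the L1 budget
binds exactly when active.  The objective is non-decreasing across
iterations and, with inactive L1 budgets on column-orthonormal data, the
solution coincides with classical CCA's first canonical pair.

``SparseCCA`` is a scikit-learn estimator (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so it
composes with pipelines and model selection; ``scca_fit`` and the other
module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .datatypes import GenotypeMatrix, ROI_COLUMNS, COVARIATE_COLUMNS

__all__ = [
    "AdjustedImagingMatrix", "SccaResult", "SparseCCA",
    "residualize", "soft_threshold", "l1_constrain",
    "scca_fit", "tune_tau", "top_k_snps", "groupwise_scca",
]


@dataclass
class AdjustedImagingMatrix:
    """Covariate-residualized, z-scored imaging features."""

    values: np.ndarray
    roi_labels: list[str]
    degenerate: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class SccaResult:
    """Fitted rank-1 canonical pair."""

    u: np.ndarray
    v: np.ndarray
    rho: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    tau1: float
    tau2: float


def residualize(Y_raw: np.ndarray, C: np.ndarray | None,
                roi_labels: list[str] | None = None) -> AdjustedImagingMatrix:
    """OLS-residualize each imaging column against [1, C], then z-score.

    An empty/None covariate block reduces to plain z-scoring.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    Y_raw = np.asarray(Y_raw, dtype=float)
    n, q = Y_raw.shape
    labels = roi_labels if roi_labels is not None else [f"roi{j}" for j in range(q)]
    if C is None or (hasattr(C, "shape") and np.size(C) == 0):
        design = np.ones((n, 1))
        cov_names = ["intercept"]
    else:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if n <= C.shape[1] + 1:
            raise ValueError("need n > number of covariates + 1")
        design = np.column_stack([np.ones(n), C])
        cov_names = ["intercept"] + [f"cov{j}" for j in range(C.shape[1])]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offenders via QR with column pivoting
        _, R, piv = sla.qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:].tolist())
        names = [cov_names[j] for j in bad]
        raise ValueError(f"covariate design is rank-deficient; collinear columns: {names}")

    beta, *_ = np.linalg.lstsq(design, Y_raw, rcond=None)
    resid = Y_raw - design @ beta
    sd = resid.std(axis=0)
    degenerate = [labels[j] for j in np.flatnonzero(sd < 1e-12)]
    if degenerate:
        warnings.warn(f"degenerate (all-residual-zero) imaging columns: {degenerate}")
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (resid - resid.mean(axis=0)) / sd_safe
    Z[:, sd < 1e-12] = 0.0
    return AdjustedImagingMatrix(values=Z, roi_labels=list(labels), degenerate=degenerate)


def soft_threshold(a: np.ndarray, c: float) -> np.ndarray:
    """Elementwise sign(a) * max(|a| - c, 0)."""
    if c < 0:
        raise ValueError("threshold must be non-negative")
    return np.sign(a) * np.maximum(np.abs(a) - c, 0.0)


def l1_constrain(w: np.ndarray, tau: float, tol: float = 1e-6) -> np.ndarray:
    """Project a direction onto {||x||_2 = 1, ||x||_1 <= tau}.

    Returns S(w, delta) / ||S(w, delta)||_2 with delta = 0 when the plain
    unit vector already meets the budget, otherwise delta found by bisection
    so the output's L1 norm equals tau within ``tol``.

    When the largest |w| entries tie exactly, the soft-threshold family
    cannot bind the budget (its L1/L2 ratio is constant across the tied
    block); the limit solution spreads weight equally over the floor(tau^2)
    largest entries, which is feasible and maximizes w'x within the family.
    """
    w = np.asarray(w, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("cannot L1-constrain the zero vector")
    if tau < 1.0:
        raise ValueError("tau must be >= 1 (unit L2 ball forces ||x||_1 >= 1)")
    u = w / norm
    if np.abs(u).sum() <= tau + tol:
        return u
    lo, hi = 0.0, np.abs(w).max()
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = soft_threshold(w, mid)
        ns = np.linalg.norm(s)
        l1 = np.abs(s).sum() / ns if ns > 0 else 0.0
        if l1 > tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, np.abs(w).max()) * 1e-6:
            break
    s = soft_threshold(w, hi)
    ns = np.linalg.norm(s)
    if ns == 0:  # tied maxima: degenerate limit of the threshold family
        m = max(1, int(np.floor(tau * tau)))
        idx = np.argsort(-np.abs(w), kind="stable")[:m]
        out = np.zeros_like(w)
        out[idx] = np.sign(w[idx]) / np.sqrt(m)
        return out
    return s / ns


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


class SparseCCA(BaseEstimator):
    """L1-constrained rank-1 CCA estimator.

    Parameters
    ----------
    tau1, tau2 : float or None
        L1 budgets for the X-side and Y-side weight vectors, each in
        [1, sqrt(dim)].  ``None`` means inactive (sqrt of the dimension).
    max_iter, tol : alternating-maximization controls; convergence is
        declared when the relative objective change drops below ``tol``.
    init : 'svd' (leading singular pair of X'Y, deterministic) or 'random'.
    random_state : seed for the random initialization.

    Fitted attributes: ``u_``, ``v_`` (unit-L2 weight vectors, sign fixed so
    the largest-|u| entry is positive), ``rho_`` (sample correlation of the
    projections), ``objective_trace_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, tau1: float | None = None, tau2: float | None = None,
                 max_iter: int = 200, tol: float = 1e-6,
                 init: str = "svd", random_state: int | None = None):
        self.tau1 = tau1
        self.tau2 = tau2
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SparseCCA":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching sample counts")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("NaN in input; impute before fitting")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        n, p = X.shape
        q = Y.shape[1]
        tau1 = float(np.sqrt(p)) if self.tau1 is None else float(self.tau1)
        tau2 = float(np.sqrt(q)) if self.tau2 is None else float(self.tau2)
        for tau, dim, name in ((tau1, p, "tau1"), (tau2, q, "tau2")):
            if not (1.0 <= tau <= np.sqrt(dim) + 1e-9):
                raise ValueError(f"{name} must lie in [1, sqrt(dim)] = [1, {np.sqrt(dim):.3f}]")

        C = X.T @ Y
        if self.init == "svd":
            # q is small; full SVD of the p x q cross-product is cheap
            _, _, Vt = np.linalg.svd(C, full_matrices=False)
            v = Vt[0]
        elif self.init == "random":
            rng = np.random.default_rng(self.random_state)
            v = rng.standard_normal(q)
        else:
            raise ValueError("init must be 'svd' or 'random'")
        v = v / np.linalg.norm(v)

        trace: list[float] = []
        obj_prev = -np.inf
        converged = False
        u = None
        for it in range(1, self.max_iter + 1):
            cu = C @ v
            if np.linalg.norm(cu) == 0:
                # X'Yv vanished (orthogonal start); restart from ones
                cu = C @ np.full(q, 1.0 / np.sqrt(q))
                if np.linalg.norm(cu) == 0:
                    u = np.zeros(p); u[0] = 1.0
                    trace.append(0.0)
                    break
            u = l1_constrain(cu, tau1)
            cv = C.T @ u
            if np.linalg.norm(cv) == 0:
                trace.append(0.0)
                break
            v = l1_constrain(cv, tau2)
            obj = float(u @ C @ v)
            trace.append(obj)
            if obj_prev > -np.inf and abs(obj - obj_prev) <= self.tol * max(1.0, abs(obj_prev)):
                converged = True
                break
            obj_prev = obj

        # deterministic sign convention: largest-|u| entry positive
        k = int(np.argmax(np.abs(u)))
        if u[k] < 0:
            u, v = -u, -v
        self.u_, self.v_ = u, v
        self.rho_ = _corr(X @ u, Y @ v)
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        self.tau1_, self.tau2_ = tau1, tau2
        return self

    def transform(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "u_")
        return np.asarray(X) @ self.u_, np.asarray(Y) @ self.v_

    def fit_transform(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.fit(X, Y).transform(X, Y)

    def result(self) -> SccaResult:
        check_is_fitted(self, "u_")
        return SccaResult(u=self.u_, v=self.v_, rho=self.rho_,
                          objective_trace=self.objective_trace_,
                          n_iter=self.n_iter_, converged=self.converged_,
                          tau1=self.tau1_, tau2=self.tau2_)


def scca_fit(X: np.ndarray, Y: np.ndarray | AdjustedImagingMatrix,
             tau1: float | None = None, tau2: float | None = None,
             max_iter: int = 200, tol: float = 1e-6,
             init: str = "svd", random_state: int | None = None) -> SccaResult:
    """Functional wrapper around :class:`SparseCCA`."""
    Ym = Y.values if isinstance(Y, AdjustedImagingMatrix) else Y
    est = SparseCCA(tau1=tau1, tau2=tau2, max_iter=max_iter, tol=tol,
                    init=init, random_state=random_state)
    return est.fit(X, Ym).result()


def tune_tau(X: np.ndarray, Y: np.ndarray,
             grid: list[tuple[float, float]],
             n_folds: int = 5, seed: int = 0) -> tuple[float, float]:
    """Pick (tau1, tau2) maximizing mean out-of-fold projection correlation.

    Ties break toward the smallest (sparsest) pair under (tau1, tau2) order.
    """
    if not grid:
        raise ValueError("empty tau grid")
    grid = sorted({(float(a), float(b)) for a, b in grid})
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tau1, tau2 in grid:
        fold_r = []
        for tr, te in kf.split(X):
            res = scca_fit(X[tr], Y[tr], tau1=tau1, tau2=tau2)
            fold_r.append(_corr(X[te] @ res.u, Y[te] @ res.v))
        scores.append(np.mean(fold_r))
    best = int(np.argmax(scores))  # argmax takes the first (sparsest) maximizer
    return grid[best]


def top_k_snps(result: SccaResult, snps: list, k: int) -> list[str]:
    """Top-k SNP IDs by descending |u|, ties by (chrom, pos, id).

    Only SNPs with nonzero weight are eligible; if fewer than ``k`` weights
    are nonzero the list is shorter and a warning is emitted.
    """
    p = len(result.u)
    if k > p:
        raise ValueError("k cannot exceed the number of SNPs")
    order = sorted(range(p),
                   key=lambda j: (-abs(result.u[j]), snps[j].chrom, snps[j].pos, snps[j].id))
    nonzero = [j for j in order if result.u[j] != 0.0]
    if len(nonzero) < k:
        warnings.warn(f"only {len(nonzero)} nonzero canonical weights; "
                      f"returning fewer than k={k} SNPs")
    return [snps[j].id for j in nonzero[:k]]


def groupwise_scca(G: GenotypeMatrix, pheno: pd.DataFrame,
                   group_col: str = "amyloid",
                   roi_cols: list[str] | None = None,
                   covar_cols: list[str] | None = None,
                   tau1: float | None = None, tau2: float | None = None,
                   top_k: int = 10, adjust_x: bool = False,
                   **fit_kwargs) -> dict[str, dict]:
    """Run residualize + SCCA per group (0/1 on ``group_col``) and pooled.

    Returns {"neg": {...}, "pos": {...}, "total": {...}} where each entry
    holds the SccaResult, the top-k SNP IDs, sample count and ROI loadings.
    Only the imaging side is covariate-adjusted unless ``adjust_x`` is set.
    """
    roi_cols = roi_cols or [c for c in ROI_COLUMNS if c in pheno.columns]
    covar_cols = covar_cols or [c for c in COVARIATE_COLUMNS if c in pheno.columns]
    if not roi_cols:
        raise ValueError("no ROI columns found in the phenotype table")

    groups = {"neg": pheno[group_col] == 0, "pos": pheno[group_col] == 1,
              "total": pd.Series(True, index=pheno.index)}
    out: dict[str, dict] = {}
    X_all = G.standardized()
    for name, mask in groups.items():
        idx = np.flatnonzero(mask.to_numpy())
        n_min = 3 * (len(covar_cols) + 1)
        if idx.size < n_min:
            raise ValueError(f"group {name!r} too small: {idx.size} < {n_min} samples")
        Yg = pheno.loc[mask, roi_cols].to_numpy(dtype=float)
        Cg = pheno.loc[mask, covar_cols].to_numpy(dtype=float) if covar_cols else None
        adj = residualize(Yg, Cg, roi_labels=roi_cols)
        Xg = X_all[idx]
        Xg = (Xg - Xg.mean(axis=0)) / np.where(Xg.std(axis=0) > 0, Xg.std(axis=0), 1.0)
        if adjust_x:
            Xg = residualize(Xg, Cg, roi_labels=G.snp_ids).values
        res = scca_fit(Xg, adj.values, tau1=tau1, tau2=tau2, **fit_kwargs)
        out[name] = {
            "result": res,
            "top_snps": top_k_snps(res, G.snps, min(top_k, G.n_snps)),
            "n": int(idx.size),
            "roi_loadings": dict(zip(roi_cols, res.v.tolist())),
        }
    return out
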