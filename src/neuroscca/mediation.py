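"""Per-SNP association and causal mediation through amyloid positivity.

Two analyses per selected SNP:

* logistic association with clinical diagnosis (CU vs DAT, aMCI excluded),
  adjusted for age, sex and education;
* potential-outcomes mediation of the SNP -> cortical-thickness effect with
  binary amyloid status as the mediator, adjusted for age, sex, education
  and ICV.  The estimator is the quasi-Bayesian two-model procedure: a
  logistic mediator model and a linear outcome model are fit by maximum
  likelihood, parameter vectors are drawn from their asymptotic sampling
  distributions, and the average causal mediation effect (ACME), average
  direct effect (ADE) and total effect are computed per draw by averaging
  simulated potential outcomes over the observed covariates.  With a linear
  no-interaction outcome model ACME + ADE = total holds exactly per draw.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .datatypes import GenotypeMatrix

__all__ = [
    "AssociationResult", "MediationResult",
    "logistic_association", "mediate", "mediation_screen",
]


@dataclass
class AssociationResult:
    snp_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    separation_flag: bool = False


@dataclass
class MediationResult:
    snp_id: str
    roi: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    total_p: float
    n_sim: int
    seed: int
    acme_mc_se: float
    ade_mc_se: float
    total_mc_se: float


def logistic_association(dosage: np.ndarray, diagnosis: np.ndarray,
                         covariates: np.ndarray, snp_id: str = "snp"
                         ) -> AssociationResult:
    """Additive-genotype logistic regression of AD case status.

    ``diagnosis`` is a string array; CU codes 0, DAT codes 1, anything else
    (aMCI) is excluded.  Wald OR, 95% CI and p for the dosage term.
    """
    diagnosis = np.asarray(diagnosis)
    keep = np.isin(diagnosis, ("CU", "DAT"))
    y = (diagnosis[keep] == "DAT").astype(float)
    if y.min() == y.max():
        raise ValueError("both CU and DAT must be present")
    d = np.asarray(dosage, dtype=float)[keep]
    if np.nanstd(d) == 0:
        raise ValueError(f"{snp_id}: monomorphic dosage, association undefined")
    C = np.asarray(covariates, dtype=float)[keep]
    if C.ndim == 1:
        C = C[:, None]
    ok = ~np.isnan(d)
    y, d, C = y[ok], d[ok], C[ok]
    Xd = sm.add_constant(np.column_stack([d, C]))

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit(disp=0)
        beta = fit.params[1]
        se = fit.bse[1]
        p = fit.pvalues[1]
        if not np.isfinite(se) or se > 50:
            raise np.linalg.LinAlgError("unstable fit")
    except Exception:
        # complete/quasi-separation: fall back to a ridge-penalized fit
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        beta = fit.params[1]
        se = np.nan
        p = np.nan
    ci = (np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)) if np.isfinite(se) \
        else (np.nan, np.nan)
    return AssociationResult(
        snp_id=snp_id, odds_ratio=float(np.exp(beta)),
        ci_low=float(ci[0]), ci_high=float(ci[1]), p_value=float(p),
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
        separation_flag=separation)


def _draw_params(fit, rng: np.random.Generator, n_sim: int) -> np.ndarray:
    cov = np.asarray(fit.cov_params())
    # guard tiny asymmetries
    cov = 0.5 * (cov + cov.T)
    return rng.multivariate_normal(np.asarray(fit.params), cov, size=n_sim,
                                   method="svd")


def mediate(dosage: np.ndarray, mediator: np.ndarray, outcome: np.ndarray,
            covariates: np.ndarray, n_sim: int = 1000, seed: int = 0,
            treat: float = 1.0, control: float = 0.0,
            mediator_model: str = "logit",
            snp_id: str = "snp", roi: str = "roi") -> MediationResult:
    """Quasi-Bayesian mediation with a binary (or degenerate linear) mediator.

    Treatment contrast is a dosage increment ``control -> treat`` (one
    alternate allele by default).  Percentile CIs over ``n_sim`` parameter
    draws; two-sided p = 2 min(P(draw <= 0), P(draw >= 0)) capped at 1.
    """
    d = np.asarray(dosage, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = ~(np.isnan(d) | np.isnan(m) | np.isnan(y) | np.isnan(C).any(axis=1))
    d, m, y, C = d[ok], m[ok], y[ok], C[ok]

    if mediator_model == "logit":
        if set(np.unique(m)) - {0.0, 1.0}:
            raise ValueError("mediator must be binary 0/1 for the logit model")
        if m.min() == m.max():
            raise ValueError("mediator must have both levels")
        for g in np.unique(d):
            mg = m[d == g]
            if mg.size and mg.min() == mg.max():
                warnings.warn(f"{snp_id}: mediator constant within dosage stratum {g:g}")

    Xm = sm.add_constant(np.column_stack([d, C]))
    Xy = sm.add_constant(np.column_stack([d, m, C]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if mediator_model == "logit":
                m_fit = sm.Logit(m, Xm).fit(disp=0)
            elif mediator_model == "linear":
                m_fit = sm.OLS(m, Xm).fit()
            else:
                raise ValueError("mediator_model must be 'logit' or 'linear'")
            y_fit = sm.OLS(y, Xy).fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"degenerate model fit for {snp_id}/{roi}: {exc}") from exc
    if not np.all(np.isfinite(m_fit.bse)) or not np.all(np.isfinite(y_fit.bse)):
        raise ValueError(f"degenerate model fit for {snp_id}/{roi}")

    rng = np.random.default_rng(seed)
    m_draws = _draw_params(m_fit, rng, n_sim)   # columns: const, d, C...
    y_draws = _draw_params(y_fit, rng, n_sim)   # columns: const, d, m, C...

    # mediator linear predictors at treat/control, per draw: n_sim x n
    def m_linpred(t: float) -> np.ndarray:
        X = np.column_stack([np.ones(d.size), np.full(d.size, t), C])
        return m_draws @ X.T

    if mediator_model == "logit":
        Em1 = expit(m_linpred(treat)).mean(axis=1)
        Em0 = expit(m_linpred(control)).mean(axis=1)
    else:
        Em1 = m_linpred(treat).mean(axis=1)
        Em0 = m_linpred(control).mean(axis=1)

    beta_t = y_draws[:, 1]
    beta_m = y_draws[:, 2]
    acme_draws = beta_m * (Em1 - Em0)
    ade_draws = beta_t * (treat - control)
    total_draws = acme_draws + ade_draws

    def summarize(draws: np.ndarray) -> tuple[float, tuple[float, float], float, float]:
        est = float(draws.mean())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        p = 2.0 * min((draws <= 0).mean(), (draws >= 0).mean())
        return est, (float(lo), float(hi)), float(min(1.0, p)), float(draws.std() / np.sqrt(n_sim))

    acme, acme_ci, acme_p, acme_se = summarize(acme_draws)
    ade, ade_ci, ade_p, ade_se = summarize(ade_draws)
    total, total_ci, total_p, total_se = summarize(total_draws)
    prop = acme / total if abs(total) > 1e-12 else float("nan")
    return MediationResult(
        snp_id=snp_id, roi=roi, acme=acme, ade=ade, total=total,
        prop_mediated=float(prop), acme_ci=acme_ci, ade_ci=ade_ci,
        total_ci=total_ci, acme_p=acme_p, ade_p=ade_p, total_p=total_p,
        n_sim=n_sim, seed=seed,
        acme_mc_se=acme_se, ade_mc_se=ade_se, total_mc_se=total_se)


def _pair_seed(global_seed: int, snp_id: str, roi: str) -> int:
    """Deterministic per-(SNP, ROI) seed, invariant to screen ordering."""
    h = zlib.crc32(f"{snp_id}|{roi}".encode())
    return int((global_seed * 2654435761 + h) % (2**31 - 1))


def mediation_screen(G: GenotypeMatrix, pheno: pd.DataFrame,
                     snp_ids: list[str], rois: list[str],
                     covar_cols: list[str] = ("age", "sex", "education", "icv"),
                     mediator_col: str = "amyloid",
                     n_sim: int = 1000, seed: int = 0,
                     treat: float = 1.0, control: float = 0.0
                     ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run ``mediate`` for every (SNP, ROI) pair.

    Returns a long-format table (one row per pair) and the direct/indirect
    effect matrices for heatmaps, with significance marks at unadjusted
    p < 0.05 plus Benjamini-Hochberg adjusted q columns in the long table.
    """
    from statsmodels.stats.multitest import multipletests

    missing = [s for s in snp_ids if s not in set(G.snp_ids)]
    if missing:
        raise KeyError(f"screen SNPs absent from genotype panel: {missing}")
    C = pheno[list(covar_cols)].to_numpy(dtype=float)
    m = pheno[mediator_col].to_numpy(dtype=float)

    rows = []
    for snp in snp_ids:
        dcol = G.dosages[:, G.snp_index(snp)]
        for roi in rois:
            res = mediate(dcol, m, pheno[roi].to_numpy(dtype=float), C,
                          n_sim=n_sim, seed=_pair_seed(seed, snp, roi),
                          treat=treat, control=control, snp_id=snp, roi=roi)
            rows.append({
                "snp": snp, "roi": roi, "acme": res.acme, "ade": res.ade,
                "total": res.total, "prop_mediated": res.prop_mediated,
                "acme_ci_low": res.acme_ci[0], "acme_ci_high": res.acme_ci[1],
                "ade_ci_low": res.ade_ci[0], "ade_ci_high": res.ade_ci[1],
                "acme_p": res.acme_p, "ade_p": res.ade_p, "total_p": res.total_p,
            })
    table = pd.DataFrame(rows)
    for col in ("acme_p", "ade_p"):
        table[col.replace("_p", "_q")] = multipletests(table[col], method="fdr_bh")[1]

    def pivot(col: str) -> pd.DataFrame:
        return table.pivot(index="snp", columns="roi", values=col) \
                    .reindex(index=snp_ids, columns=rois)

    matrices = {
        "direct": pivot("ade"),
        "indirect": pivot("acme"),
        "direct_sig": pivot("ade_p") < 0.05,
        "indirect_sig": pivot("acme_p") < 0.05,
    }
    return table, matrices
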