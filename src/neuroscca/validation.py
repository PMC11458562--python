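"""Predictive validation of the selected SNPs.

Elastic-net models predict global cortical thickness, MMSE and CDR-SB under
two study designs:

* cross-group: train in one amyloid group (repeated 5-fold CV, 10 repeats),
  test on the other group;
* within-group model comparison: model 1 = covariates only, model 2 =
  covariates + the top-10 SCCA SNPs, model 3 = covariates + 10 random
  panel SNPs (drawn excluding the top-10).

Model pairs are compared with the Hittner-May-Silver z test for two
dependent overlapping correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .datatypes import GenotypeMatrix

__all__ = [
    "ModelSpec", "PredictionReport",
    "fit_elastic_net_cv", "cross_group_validate", "model_comparison_suite",
    "compare_models", "hittner_test", "fisher_ci",
]

#: covariates entering model 1, per outcome ("if appropriate, ICV or
#: education": ICV for the anatomical outcome, education for cognition)
MODEL1_COVARS = {
    "global_thickness": ["age", "sex", "apoe4", "icv"],
    "mmse": ["age", "sex", "apoe4", "education"],
    "cdr_sb": ["age", "sex", "apoe4", "education"],
}

DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class ModelSpec:
    """Feature recipe for one prediction model."""

    label: str                      # "model1" | "model2" | "model3"
    covariates: list[str]
    snp_ids: list[str] = field(default_factory=list)


@dataclass
class PredictionReport:
    """Accumulates per-(design, model, outcome) results and predictions."""

    rows: list[dict] = field(default_factory=list)
    predictions: dict[tuple, np.ndarray] = field(default_factory=dict)
    observed: dict[tuple, np.ndarray] = field(default_factory=dict)

    def add(self, design: str, model: str, outcome: str, split: str,
            r: float, ci: tuple[float, float], n: int,
            preds: np.ndarray | None = None, y: np.ndarray | None = None) -> None:
        self.rows.append({"design": design, "model": model, "outcome": outcome,
                          "split": split, "r": r, "ci_low": ci[0], "ci_high": ci[1],
                          "n": n})
        if preds is not None:
            key = (design, model, outcome, split)
            self.predictions[key] = np.asarray(preds)
            self.observed[key] = np.asarray(y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["design", "model", "outcome",
                                                "split", "r", "ci_low", "ci_high", "n"])


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    r = float(np.clip(r, -0.999999, 0.999999))
    if n <= 3:
        return (-1.0, 1.0)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def _enet(seed: int, l1_ratios, n_alphas: int) -> make_pipeline:
    return make_pipeline(
        StandardScaler(),
        ElasticNetCV(l1_ratio=list(l1_ratios), alphas=n_alphas,
                     cv=5, random_state=seed, max_iter=5000),
    )


def fit_elastic_net_cv(features: np.ndarray, outcome: np.ndarray,
                       folds: int = 5, repeats: int = 10, seed: int = 0,
                       l1_ratios=DEFAULT_L1_RATIOS, n_alphas: int = 50):
    """Repeated k-fold CV elastic net.

    Per repeat, out-of-fold predictions are pooled and correlated with the
    observed outcome; ``cv_r`` is the mean over repeats.  Hyperparameters
    (mixing, strength) are chosen by a nested grid on the training folds.
    Returns (final model refit on all data, cv_r, per-repeat r list,
    mean out-of-fold predictions).
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if F.shape[0] < 25:
        raise ValueError("need at least 25 samples for repeated CV")
    if y.std() == 0:
        raise ValueError("constant outcome")
    if np.isnan(F).any() or np.isnan(y).any():
        raise ValueError("NaN in features/outcome; impute upstream")

    rep_r = []
    oof_sum = np.zeros_like(y)
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed * 1000 + rep)
        oof = np.empty_like(y)
        for tr, te in kf.split(F):
            model = _enet(seed * 1000 + rep, l1_ratios, n_alphas)
            model.fit(F[tr], y[tr])
            oof[te] = model.predict(F[te])
        rep_r.append(float(np.corrcoef(oof, y)[0, 1]) if oof.std() > 0 else 0.0)
        oof_sum += oof
    cv_r = float(np.mean(rep_r))
    final = _enet(seed, l1_ratios, n_alphas)
    final.fit(F, y)
    return final, cv_r, rep_r, oof_sum / repeats


def _features(G: GenotypeMatrix, pheno: pd.DataFrame, spec: ModelSpec,
              rows: np.ndarray) -> np.ndarray:
    cols = [pheno.loc[rows, c].to_numpy(dtype=float) for c in spec.covariates]
    F = np.column_stack(cols) if cols else np.empty((rows.sum(), 0))
    if spec.snp_ids:
        sub = G.select_snps(spec.snp_ids)
        F = np.column_stack([F, sub.imputed()[np.flatnonzero(rows)]]) if F.size \
            else sub.imputed()[np.flatnonzero(rows)]
    return F


def cross_group_validate(G: GenotypeMatrix, pheno: pd.DataFrame,
                         top10_neg: list[str], top10_pos: list[str],
                         outcomes: tuple[str, ...] = ("global_thickness",),
                         group_col: str = "amyloid",
                         include_covariates: bool = False,
                         folds: int = 5, repeats: int = 10, seed: int = 0,
                         l1_ratios=DEFAULT_L1_RATIOS, n_alphas: int = 50
                         ) -> PredictionReport:
    """The two cross-group designs.

    Design 1 trains in the amyloid-negative group with its top-10 SNPs
    (train r = repeated-CV r) and tests on every amyloid-positive sample;
    design 2 is the mirror image.  CIs are Fisher-z.

    Models use the SNPs alone by default: with covariates included, age and
    ICV predict thickness in every group and mask the group-specificity of
    the genetic signal that this comparison is designed to expose.
    """
    groups = pheno[group_col].to_numpy()
    if not ((groups == 0).any() and (groups == 1).any()):
        raise ValueError("both amyloid groups must be present")
    report = PredictionReport()
    designs = [("design1", 0, 1, top10_neg), ("design2", 1, 0, top10_pos)]
    for name, train_g, test_g, snps in designs:
        train_rows = groups == train_g
        test_rows = groups == test_g
        for outcome in outcomes:
            covars = MODEL1_COVARS.get(outcome, ["age", "sex", "apoe4", "icv"]) \
                if include_covariates else []
            spec = ModelSpec(label="top10", covariates=list(covars), snp_ids=list(snps))
            F_tr = _features(G, pheno, spec, train_rows)
            y_tr = pheno.loc[train_rows, outcome].to_numpy(dtype=float)
            model, cv_r, _, oof = fit_elastic_net_cv(
                F_tr, y_tr, folds=folds, repeats=repeats, seed=seed,
                l1_ratios=l1_ratios, n_alphas=n_alphas)
            report.add(name, "top10", outcome, "train", cv_r,
                       fisher_ci(cv_r, int(train_rows.sum())), int(train_rows.sum()),
                       preds=oof, y=y_tr)
            F_te = _features(G, pheno, spec, test_rows)
            y_te = pheno.loc[test_rows, outcome].to_numpy(dtype=float)
            pred = model.predict(F_te)
            r_te = float(np.corrcoef(pred, y_te)[0, 1]) if pred.std() > 0 else 0.0
            report.add(name, "top10", outcome, "test", r_te,
                       fisher_ci(r_te, int(test_rows.sum())), int(test_rows.sum()),
                       preds=pred, y=y_te)
    return report


def model_comparison_suite(G: GenotypeMatrix, pheno: pd.DataFrame,
                           group_mask: np.ndarray, top10: list[str],
                           panel_ids: list[str],
                           outcomes: tuple[str, ...] = ("global_thickness", "mmse", "cdr_sb"),
                           folds: int = 5, repeats: int = 10, seed: int = 0,
                           l1_ratios=DEFAULT_L1_RATIOS, n_alphas: int = 50
                           ) -> tuple[PredictionReport, pd.DataFrame]:
    """Models 1-3 within one group, plus Hittner comparisons.

    Model 3's random SNPs are drawn from the candidate panel excluding the
    top-10, seeded.  Comparisons (m1 vs m2, m2 vs m3) use the mean
    out-of-fold predictions on the same samples.
    """
    rng = np.random.default_rng(seed)
    pool = [s for s in panel_ids if s not in set(top10)]
    if len(pool) < len(top10):
        raise ValueError("candidate panel too small to draw random SNPs")
    random_snps = sorted(rng.choice(pool, size=len(top10), replace=False).tolist())

    report = PredictionReport()
    rows = np.asarray(group_mask, dtype=bool)
    comparisons = []
    for outcome in outcomes:
        covars = MODEL1_COVARS.get(outcome, ["age", "sex", "apoe4", "icv"])
        specs = [ModelSpec("model1", list(covars)),
                 ModelSpec("model2", list(covars), list(top10)),
                 ModelSpec("model3", list(covars), random_snps)]
        y = pheno.loc[rows, outcome].to_numpy(dtype=float)
        oofs = {}
        for spec in specs:
            F = _features(G, pheno, spec, rows)
            _, cv_r, _, oof = fit_elastic_net_cv(
                F, y, folds=folds, repeats=repeats, seed=seed,
                l1_ratios=l1_ratios, n_alphas=n_alphas)
            report.add("within", spec.label, outcome, "cv", cv_r,
                       fisher_ci(cv_r, int(rows.sum())), int(rows.sum()),
                       preds=oof, y=y)
            oofs[spec.label] = oof
        for a, b in (("model1", "model2"), ("model2", "model3")):
            z, p = compare_models_from_predictions(oofs[a], oofs[b], y)
            comparisons.append({"outcome": outcome, "model_a": a, "model_b": b,
                                "z": z, "p": p})
    return report, pd.DataFrame(comparisons)


def compare_models_from_predictions(pred_a: np.ndarray, pred_b: np.ndarray,
                                    y: np.ndarray) -> tuple[float, float]:
    """Hittner z/p for corr(pred_a, y) vs corr(pred_b, y) on shared samples."""
    pred_a, pred_b, y = (np.asarray(v, dtype=float) for v in (pred_a, pred_b, y))
    if not (pred_a.shape == pred_b.shape == y.shape):
        raise ValueError("predictions and outcome must share samples")
    r12 = float(np.corrcoef(pred_a, y)[0, 1])
    r13 = float(np.corrcoef(pred_b, y)[0, 1])
    r23 = float(np.corrcoef(pred_a, pred_b)[0, 1])
    return hittner_test(r12, r13, r23, len(y))


def compare_models(report: PredictionReport, model_a: str, model_b: str,
                   outcome: str, design: str = "within", split: str = "cv"
                   ) -> tuple[float, float]:
    """Hittner comparison of two stored models on the same outcome."""
    ka, kb = (design, model_a, outcome, split), (design, model_b, outcome, split)
    if ka not in report.predictions or kb not in report.predictions:
        raise KeyError("both models must have stored predictions for this outcome")
    ya, yb = report.observed[ka], report.observed[kb]
    if ya.shape != yb.shape or not np.allclose(ya, yb):
        raise ValueError("models were evaluated on different samples")
    return compare_models_from_predictions(report.predictions[ka],
                                           report.predictions[kb], ya)


def hittner_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Hittner-May-Silver test for two dependent overlapping correlations.

    Tests H0: rho12 = rho13 where variable 1 is shared.  Fisher-z transforms
    r12 and r13; the Dunn & Clark covariance term is evaluated at the
    backtransformed mean of z12 and z13:

        c = (r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2) / 2)
            / (1 - rbar^2)^2
        z = (z12 - z13) sqrt((n - 3) / (2 - 2 c))

    Returns (z, two-sided p from the standard normal).
    """
    for name, r in (("r12", r12), ("r13", r13)):
        if not (-1.0 < r < 1.0):
            raise ValueError(f"{name} must lie strictly inside (-1, 1); got {r}")
    if not (-1.0 <= r23 <= 1.0):
        raise ValueError(f"r23 must lie in [-1, 1]; got {r23}")
    if n < 10:
        raise ValueError("n must be >= 10")
    if r12 == r13:
        # identical correlations (e.g. a model compared with itself)
        return 0.0, 1.0
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlations are inconsistent (matrix not PSD)")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = np.tanh(0.5 * (z12 + z13))
    rb2 = rbar * rbar
    c = (r23 * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r23 * r23)) \
        / ((1.0 - rb2) ** 2)
    if c >= 1.0:
        raise ValueError("correlations too close to 1: the covariance term "
                         "degenerates (c >= 1)")
    z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), min(1.0, p)
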