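"""Sample- and marker-level genotype quality control.

Filter chain (applied in this order, each stage on the survivors of the
previous one):

  samples : call rate >= 95%, heterozygosity within +-5 SD of the mean,
            one member of every pair with PI_HAT >= 0.125 removed;
  markers : call rate >= 98%, MAF >= 1%, Hardy-Weinberg exact p >= 1e-6,
            imputation quality r^2 > 0.8 (when recorded).

Every removal is logged with its stage and the offending value, so counts
are exactly auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix

__all__ = [
    "QcThresholds", "QcReport",
    "call_rates", "heterozygosity_outliers", "ibd_pihat",
    "hwe_exact_test", "minor_allele_freq", "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    sample_call_rate_min: float = 0.95
    het_sd_mult: float = 5.0
    ibd_pihat_max: float = 0.125
    marker_call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    info_r2_min: float = 0.8
    het_one_sided: bool = False  # flag excess-heterozygosity only

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "marker_call_rate_min",
                     "maf_min", "hwe_p_min", "info_r2_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1] (got {v})")
        if self.het_sd_mult < 0 or not (0.0 <= self.ibd_pihat_max <= 1.0):
            raise ValueError("het_sd_mult must be >= 0 and ibd_pihat_max in [0,1]")


@dataclass
class QcReport:
    """Ordered log of removals; one record per removed entity."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, kind: str, entity_id: str,
            value: float | None, threshold: float | None) -> None:
        self.records.append({"stage": stage, "kind": kind, "id": entity_id,
                             "value": value, "threshold": threshold})

    def removed_ids(self, stage: str) -> list[str]:
        return [r["id"] for r in self.records if r["stage"] == stage]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r["stage"]] = out.get(r["stage"], 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = ["stage", "kind", "id", "value", "threshold"]
        return pd.DataFrame(self.records, columns=cols)


def call_rates(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-sample, per-marker) fractions of non-missing genotypes."""
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    obs = ~np.isnan(G.dosages)
    return obs.mean(axis=1), obs.mean(axis=0)


def heterozygosity_outliers(G: GenotypeMatrix, sd_mult: float = 5.0,
                            one_sided: bool = False) -> set[str]:
    """Samples whose heterozygous-call fraction deviates > sd_mult SD from the mean."""
    if G.n_samples < 2:
        raise ValueError("need >= 2 samples")
    het = (G.dosages == 1.0)
    obs = ~np.isnan(G.dosages)
    with np.errstate(invalid="ignore"):
        rate = het.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    mu, sd = rate.mean(), rate.std()
    if sd == 0:
        return set()
    z = (rate - mu) / sd
    flag = z > sd_mult if one_sided else np.abs(z) > sd_mult
    return {G.sample_ids[i] for i in np.flatnonzero(flag)}


def _ibs_counts(D: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise counts of IBS state 0/1/2 over jointly observed SNPs."""
    I = [((D == v) & obs).astype(float) for v in (0.0, 1.0, 2.0)]
    n0 = I[0] @ I[2].T
    n0 = n0 + n0.T  # |dosage diff| == 2
    n1 = I[0] @ I[1].T + I[1] @ I[2].T
    n1 = n1 + n1.T  # |dosage diff| == 1
    joint = obs.astype(float) @ obs.astype(float).T
    n2 = joint - n0 - n1
    return n0, n1, n2


def ibd_pihat(G: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments PI_HAT = P(IBD=2) + 0.5 P(IBD=1), PLINK-style.

    Expected IBS-given-IBD probabilities are evaluated at the sample allele
    frequencies (large-sample form, no finite-size correction) and summed
    over the SNPs jointly observed in each pair.
    """
    if G.n_samples < 2:
        raise ValueError("need >= 2 samples")
    freq = G.alt_allele_freq()
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if not poly.any():
        raise ValueError("no polymorphic markers: PI_HAT undefined")
    D = G.dosages[:, poly]
    p = freq[poly]
    q = 1.0 - p
    obs = ~np.isnan(D)

    n0, n1, n2 = _ibs_counts(np.nan_to_num(D, nan=-9.0), obs)

    # per-SNP P(IBS=i | IBD=j) under HWE
    e0_z0 = 2 * p**2 * q**2
    e1_z0 = 4 * p**3 * q + 4 * p * q**3
    e2_z0 = 1.0 - e0_z0 - e1_z0
    e1_z1 = 2 * p * q            # = 2 p^2 q + 2 p q^2
    e2_z1 = 1.0 - e1_z1

    M = obs.astype(float)

    def pairsum(f: np.ndarray) -> np.ndarray:
        return (M * f) @ M.T

    S0_z0, S1_z0, S2_z0 = pairsum(e0_z0), pairsum(e1_z0), pairsum(e2_z0)
    S1_z1, S2_z1 = pairsum(e1_z1), pairsum(e2_z1)
    joint = M @ M.T

    # raw moment estimates; only the final PI_HAT is clipped, since clipping
    # the per-state probabilities first biases unrelated pairs upward
    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = n0 / S0_z0
        P1 = (n1 - P0 * S1_z0) / S1_z1
        P2 = (n2 - P0 * S2_z0 - P1 * S2_z1) / joint
    P1 = np.nan_to_num(P1)
    P2 = np.nan_to_num(P2)
    pihat = np.clip(P2 + 0.5 * P1, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, no mid-p).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability.  Computed with the standard ratio
    recurrence, so it is exact for any sample size.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa         # minor-ish allele count
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # heterozygote count shares parity with the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)

    # log unnormalized conditional probabilities (log-space avoids overflow
    # at large sample sizes): log P(h) ~ -log(hom_r!) - log(h!) - log(hom_c!)
    # + h log 2, the shared n!/denominator terms cancel in the ratio
    hom_r = (rare - het_values) // 2
    hom_c = n - het_values - hom_r
    logp = (het_values * np.log(2.0)
            - gammaln(hom_r + 1) - gammaln(het_values + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    w = np.exp(logp)
    total = w.sum()
    p_obs = w[het_values == n_Aa][0] / total
    p_val = w[w / total <= p_obs * (1 + 1e-12)].sum() / total
    return float(min(1.0, p_val))


def minor_allele_freq(column: np.ndarray) -> float:
    """MAF of one dosage column; nan if every call is missing."""
    col = np.asarray(column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return float("nan")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def apply_qc(G: GenotypeMatrix, thresholds: QcThresholds | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full filter chain; returns the surviving matrix and report."""
    th = thresholds or QcThresholds()
    report = QcReport()
    cur = G

    # --- samples: call rate ---------------------------------------------
    s_rate, _ = call_rates(cur)
    drop = s_rate < th.sample_call_rate_min
    for i in np.flatnonzero(drop):
        report.add("sample_call_rate", "sample", cur.sample_ids[i],
                   float(s_rate[i]), th.sample_call_rate_min)
    if drop.any():
        cur = cur.subset_samples(~drop)
    if cur.n_samples == 0:
        raise ValueError("QC removed every sample at the call-rate stage")

    # --- samples: heterozygosity ------------------------------------------
    het_ids = heterozygosity_outliers(cur, th.het_sd_mult, th.het_one_sided) \
        if cur.n_samples >= 2 else set()
    for sid in sorted(het_ids):
        report.add("heterozygosity", "sample", sid, None, th.het_sd_mult)
    if het_ids:
        keep = np.array([sid not in het_ids for sid in cur.sample_ids])
        cur = cur.subset_samples(keep)
    if cur.n_samples == 0:
        raise ValueError("QC removed every sample at the heterozygosity stage")

    # --- samples: relatedness ---------------------------------------------
    if cur.n_samples >= 2 and th.ibd_pihat_max < 1.0:
        pihat = ibd_pihat(cur)
        s_rate, _ = call_rates(cur)
        removed: set[int] = set()
        ii, jj = np.nonzero(np.triu(pihat >= th.ibd_pihat_max, k=1))
        # deterministic order: by descending pihat then ids
        pairs = sorted(zip(ii, jj),
                       key=lambda ij: (-pihat[ij[0], ij[1]],
                                       cur.sample_ids[ij[0]], cur.sample_ids[ij[1]]))
        for i, j in pairs:
            if i in removed or j in removed:
                continue
            # drop the lower call rate; tie -> lexicographically smaller ID
            if (s_rate[i], cur.sample_ids[j]) < (s_rate[j], cur.sample_ids[i]):
                victim = i
            elif (s_rate[j], cur.sample_ids[i]) < (s_rate[i], cur.sample_ids[j]):
                victim = j
            else:
                victim = i if cur.sample_ids[i] < cur.sample_ids[j] else j
            removed.add(victim)
            report.add("ibd", "sample", cur.sample_ids[victim],
                       float(pihat[i, j]), th.ibd_pihat_max)
        if removed:
            keep = np.array([i not in removed for i in range(cur.n_samples)])
            cur = cur.subset_samples(keep)
    if cur.n_samples == 0:
        raise ValueError("QC removed every sample at the relatedness stage")

    # --- markers: call rate -------------------------------------------------
    _, m_rate = call_rates(cur)
    drop = m_rate < th.marker_call_rate_min
    for j in np.flatnonzero(drop):
        report.add("marker_call_rate", "marker", cur.snps[j].id,
                   float(m_rate[j]), th.marker_call_rate_min)
    if drop.any():
        cur = cur.subset_snps(~drop)
    if cur.n_snps == 0:
        raise ValueError("QC removed every marker at the call-rate stage")

    # --- markers: MAF ---------------------------------------------------------
    maf = np.array([minor_allele_freq(cur.dosages[:, j]) for j in range(cur.n_snps)])
    drop = np.isnan(maf) | (maf < th.maf_min)
    for j in np.flatnonzero(drop):
        report.add("maf", "marker", cur.snps[j].id,
                   None if np.isnan(maf[j]) else float(maf[j]), th.maf_min)
    if drop.any():
        cur = cur.subset_snps(~drop)
    if cur.n_snps == 0:
        raise ValueError("QC removed every marker at the MAF stage")

    # --- markers: HWE ------------------------------------------------------------
    drop = np.zeros(cur.n_snps, dtype=bool)
    hwe_p = np.ones(cur.n_snps)
    for j in range(cur.n_snps):
        col = cur.dosages[:, j]
        obs = col[~np.isnan(col)]
        counts = (int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
        if sum(counts) == 0:
            continue
        hwe_p[j] = hwe_exact_test(*counts)
        drop[j] = hwe_p[j] < th.hwe_p_min
    for j in np.flatnonzero(drop):
        report.add("hwe", "marker", cur.snps[j].id, float(hwe_p[j]), th.hwe_p_min)
    if drop.any():
        cur = cur.subset_snps(~drop)
    if cur.n_snps == 0:
        raise ValueError("QC removed every marker at the HWE stage")

    # --- markers: imputation quality ------------------------------------------------
    drop = np.array([rec.info_r2 is not None and rec.info_r2 <= th.info_r2_min
                     for rec in cur.snps])
    for j in np.flatnonzero(drop):
        report.add("info_r2", "marker", cur.snps[j].id,
                   float(cur.snps[j].info_r2), th.info_r2_min)
    if drop.any():
        cur = cur.subset_snps(~drop)
    if cur.n_snps == 0:
        raise ValueError("QC removed every marker at the imputation-quality stage")

    return cur, report
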