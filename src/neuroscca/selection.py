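"""Candidate-SNP selection: summary-statistic thresholding and LD clumping.

Reduces a post-QC panel to approximately uncorrelated index SNPs the way
PLINK's ``--clump`` does: iterate SNPs passing the p-value filter in
ascending p; each still-unassigned SNP becomes an index and absorbs the
unassigned SNPs within a physical window whose dosage r-squared with it
reaches the clump threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["CandidatePanel", "ld_r2", "filter_by_pvalue", "clump", "read_summary_stats"]


@dataclass
class CandidatePanel:
    """Ordered index SNPs plus the clump membership map."""

    index_ids: list[str]
    clumps: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_index(self) -> int:
        return len(self.index_ids)

    def members(self, index_id: str) -> list[str]:
        return self.clumps.get(index_id, [])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"index_snp": idx, "members": ",".join(self.clumps.get(idx, []))}
                for idx in self.index_ids]
        return pd.DataFrame(rows, columns=["index_snp", "members"])


def read_summary_stats(path) -> pd.DataFrame:
    """Read a `snp chrom pos p` TSV and validate it."""
    stats = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    missing = {"snp", "chrom", "pos", "p"} - set(stats.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    if stats["snp"].duplicated().any():
        raise ValueError("summary statistics contain duplicate SNP IDs")
    if not ((stats["p"] > 0) & (stats["p"] <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    return stats


def ld_r2(G: GenotypeMatrix, snp_i: str | int, snp_j: str | int) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD).

    Computed on the jointly non-missing samples; nan when either SNP is
    monomorphic on that overlap.
    """
    i = snp_i if isinstance(snp_i, (int, np.integer)) else G.snp_index(snp_i)
    j = snp_j if isinstance(snp_j, (int, np.integer)) else G.snp_index(snp_j)
    x, y = G.dosages[:, i], G.dosages[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def filter_by_pvalue(stats: pd.DataFrame, threshold: float,
                     panel_ids: set[str] | None = None) -> set[str]:
    """SNP IDs with p strictly below threshold, restricted to the panel."""
    if stats.empty:
        raise ValueError("empty summary statistics")
    passing = set(stats.loc[stats["p"] < threshold, "snp"])
    if panel_ids is not None:
        passing &= set(panel_ids)
    return passing


def clump(G: GenotypeMatrix, stats: pd.DataFrame,
          p_threshold: float = 1e-4, r2_threshold: float = 0.1,
          window_kb: float = 250.0) -> CandidatePanel:
    """Greedy PLINK-style clumping of the SNPs passing the p filter.

    Ties in p are broken by (chrom, pos, id) so the output is invariant to
    the input row order.
    """
    panel_ids = set(G.snp_ids)
    passing = filter_by_pvalue(stats, p_threshold, panel_ids)
    if not passing:
        return CandidatePanel(index_ids=[], clumps={})

    sub = stats[stats["snp"].isin(passing)].copy()
    meta = {rec.id: rec for rec in G.snps}
    sub["chrom"] = sub["snp"].map(lambda s: meta[s].chrom)
    sub["pos"] = sub["snp"].map(lambda s: meta[s].pos)
    sub = sub.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")

    window_bp = window_kb * 1000.0
    assigned: set[str] = set()
    index_ids: list[str] = []
    clumps: dict[str, list[str]] = {}
    rows = list(sub.itertuples())
    for row in rows:
        if row.snp in assigned:
            continue
        index_ids.append(row.snp)
        assigned.add(row.snp)
        members: list[str] = []
        for other in rows:
            if other.snp in assigned or other.chrom != row.chrom:
                continue
            if abs(other.pos - row.pos) > window_bp:
                continue
            r2 = ld_r2(G, row.snp, other.snp)
            if not np.isnan(r2) and r2 >= r2_threshold:
                members.append(other.snp)
                assigned.add(other.snp)
        clumps[row.snp] = members
    return CandidatePanel(index_ids=index_ids, clumps=clumps)
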