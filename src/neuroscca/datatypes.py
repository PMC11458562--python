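"""Core in-memory containers shared across the pipeline.

Genotypes are held as an additive dosage matrix (count of the ``a1``
allele, ``numpy.nan`` for missing calls) plus per-SNP metadata, mirroring
the information content of a PLINK1 fileset.  Phenotypes and covariates
live in a plain :class:`pandas.DataFrame` with one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SnpRecord", "GenotypeMatrix", "ROI_COLUMNS", "COVARIATE_COLUMNS"]

#: Cortical-thickness regions of interest: four lobes plus the cingulate per
#: hemisphere, and the hemispheric global means (12 measures in total).
ROI_COLUMNS = [
    "thk_frontal_l", "thk_frontal_r",
    "thk_temporal_l", "thk_temporal_r",
    "thk_parietal_l", "thk_parietal_r",
    "thk_occipital_l", "thk_occipital_r",
    "thk_cingulate_l", "thk_cingulate_r",
    "thk_global_l", "thk_global_r",
]

COVARIATE_COLUMNS = ["age", "sex", "education", "icv"]


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic marker.

    ``a1`` is the counted (dosage) allele, ``a2`` the other allele.
    ``info_r2`` is the post-imputation quality metric when available.
    """

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    info_r2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based (got {self.pos})")
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: alleles must differ (got {self.a1}/{self.a2})")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with per-SNP metadata.

    ``dosages`` is float with values in {0, 1, 2, nan}; nan marks a missing
    call.  Rows follow ``sample_ids``, columns follow ``snps``.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(f"dosage rows ({n}) != sample count ({len(self.sample_ids)})")
        if p != len(self.snps):
            raise ValueError(f"dosage columns ({p}) != SNP count ({len(self.snps)})")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must lie in {0, 1, 2} or be missing (nan)")

    def check_positions_sorted(self) -> None:
        """Require non-decreasing positions per chromosome (file-input contract).

        Enforced at the I/O boundary; in-memory subsets (e.g. a clumped panel
        ordered by p-value) may legitimately reorder columns.
        """
        last: dict[str, int] = {}
        for rec in self.snps:
            if rec.chrom in last and rec.pos < last[rec.chrom]:
                raise ValueError(
                    f"positions on chromosome {rec.chrom} are not non-decreasing near {rec.id}"
                )
            last[rec.chrom] = rec.pos

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [rec.id for rec in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    # -- subsetting ----------------------------------------------------

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            snps=list(self.snps),
            dosages=self.dosages[keep, :].copy(),
        )

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
        )

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Subset to the given SNP IDs, in the given order."""
        lookup = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [lookup[s] for s in snp_ids]
        return self.subset_snps(np.asarray(idx))

    # -- numeric views -------------------------------------------------

    def alt_allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        X = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        return X

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosages (monomorphic columns -> 0)."""
        X = self.imputed()
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd_safe
        Z[:, sd == 0] = 0.0
        return Z

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[replace(rec) for rec in self.snps],
            dosages=self.dosages.copy(),
        )
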