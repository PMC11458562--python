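"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: an amyloid-PET
stratified cohort (Abeta- / Abeta+), a panel of candidate SNPs with block
linkage disequilibrium, 12 lobar/global cortical-thickness measures carrying
a planted rank-1 canonical signal, covariate effects, and SNP -> amyloid ->
thickness mediation paths.  Companion GWAS summary statistics, SNP->gene
annotation and GMT gene sets are generated alongside so every downstream
stage is testable without external downloads.

Genotypes come from a Gaussian-copula threshold model: each sample carries
two independent latent standard-normal haplotype vectors with block-diagonal
AR(1) correlation across SNPs; an allele is present when the latent value
falls below Phi^-1(MAF).  Dosage is the sum over the two haplotypes, so
Hardy-Weinberg proportions hold exactly per SNP while within-block r^2 is
tunable through ``ld_rho``.

The planted canonical signal rescales the latent score X_std u_true to unit
sample variance, so the planted correlation between the SNP and imaging
projections has the closed form s / sqrt(s^2 + noise_sd^2) with
s = canonical_strength, independent of the LD structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .datatypes import GenotypeMatrix, SnpRecord, ROI_COLUMNS
from .plinkio import write_plink

__all__ = [
    "SimulationConfig", "SyntheticTruth",
    "simulate_genotypes", "simulate_cohort", "simulate_summary_stats",
    "write_fixture",
]

# Per-ROI baseline mean thickness (mm): frontal, temporal, parietal,
# occipital, cingulate, global x {L, R}.
_BASELINE_MM = np.array([2.45, 2.45, 2.75, 2.75, 2.30, 2.30,
                         2.10, 2.10, 2.60, 2.60, 2.45, 2.45])


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Cohort-level defaults mirror the demographic table of the emulated
    study: n=1125 with a 57.5% amyloid-positive fraction, age 70.2 (8.5)
    years, 58.5% female, APOE e4 count distribution ~ (0.564, 0.344, 0.092),
    and a 344-SNP candidate panel with 12 thickness ROIs.
    """

    n_samples: int = 1125
    n_snps: int = 344
    n_rois: int = 12
    ld_block_size: int = 8
    #: residual LD of a post-clumping panel (neighbour r^2 ~ 0.05); raise for
    #: clumping/QC tests that need strong LD
    ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 10
    #: calibrated so the planted canonical correlation, net of the amyloid
    #: path's variance along v_true, is 0.5 at the defaults
    canonical_strength: float = 0.0735
    path_a: float = 0.15     # per-causal-allele log-odds on amyloid (OR ~1.16)
    path_b: float = -0.05    # amyloid -> thickness (mm)
    path_c: float = 0.0      # direct per-allele SNP -> thickness (mm)
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "age": -0.010,       # mm per year
        "sex": 0.03,         # mm, female vs male
        "education": 0.0,    # mm per year of education
        "icv": 0.0002,       # mm per cm^3
    })
    noise_sd: float = 0.10   # mm
    target_ab_fraction: float = 0.575
    apoe_logor: float = 1.3  # per-e4-allele log-odds on amyloid positivity
    group_signal: str = "shared"   # "shared" | "disjoint"
    decoy_fraction: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1 or self.n_rois < 1:
            raise ValueError("n_samples, n_snps, n_rois must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0,1) (got {self.ld_rho})")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5] (got {self.maf_range})")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.group_signal not in ("shared", "disjoint"):
            raise ValueError("group_signal must be 'shared' or 'disjoint'")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        if self.canonical_strength < 0:
            raise ValueError("canonical_strength must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    ``u_true`` is the unit-L2 SNP-side canonical vector whose support is
    exactly ``causal_indices``; ``v_true`` the unit-L2 imaging-side vector.
    In "disjoint" mode the group-specific vectors and causal sets are also
    recorded (``causal_indices`` is then their union).
    """

    causal_indices: list[int]
    u_true: np.ndarray
    v_true: np.ndarray
    path_a: float
    path_b: float
    path_c: float
    causal_indices_neg: list[int] | None = None
    causal_indices_pos: list[int] | None = None
    u_true_neg: np.ndarray | None = None
    u_true_pos: np.ndarray | None = None

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        return json.dumps({k: conv(v) for k, v in asdict(self).items()}, indent=1)


def _block_ar1_latents(rng: np.random.Generator, n: int, p: int,
                       block: int, rho: float) -> np.ndarray:
    """n x p latent standard normals, AR(1) with parameter rho within blocks."""
    Z = rng.standard_normal((n, p))
    if rho == 0.0:
        return Z
    scale = np.sqrt(1.0 - rho * rho)
    for start in range(0, p, block):
        stop = min(start + block, p)
        for j in range(start + 1, stop):
            Z[:, j] = rho * Z[:, j - 1] + scale * Z[:, j]
    return Z


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a samples x SNPs dosage matrix under the Gaussian-copula LD model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_snps
    lo, hi = config.maf_range
    maf = lo + (hi - lo) * rng.random(p) if lo < hi else np.full(p, lo)
    cut = ndtri(maf)

    hap1 = _block_ar1_latents(rng, n, p, config.ld_block_size, config.ld_rho)
    hap2 = _block_ar1_latents(rng, n, p, config.ld_block_size, config.ld_rho)
    dosages = (hap1 < cut).astype(float) + (hap2 < cut).astype(float)

    if config.missing_rate > 0:
        dosages[rng.random((n, p)) < config.missing_rate] = np.nan

    # Metadata: blocks contiguous in position (1 kb spacing), 10 Mb gaps
    # between blocks (far beyond any clump window), cycling over autosomes.
    bases = "ACGT"
    snps = []
    for j in range(p):
        b = j // config.ld_block_size
        chrom = str((b % 22) + 1)
        a1, a2 = rng.choice(list(bases), size=2, replace=False)
        snps.append(SnpRecord(id=f"rs{100000 + j}", chrom=chrom, pos=1,
                              a1=str(a1), a2=str(a2), info_r2=None))
    snps = _relayout_positions(snps, config.ld_block_size)
    G = GenotypeMatrix(sample_ids=[f"S{i:05d}" for i in range(n)],
                       snps=snps, dosages=dosages)
    G.check_positions_sorted()
    return G


def _relayout_positions(snps: list[SnpRecord], block: int) -> list[SnpRecord]:
    """Assign positions so blocks are 1 kb-spaced runs separated by 10 Mb."""
    out: list[SnpRecord] = []
    next_start: dict[str, int] = {}
    for j, rec in enumerate(snps):
        offset = j % block
        if offset == 0:
            start = next_start.get(rec.chrom, 1_000_000)
            next_start[rec.chrom] = start + 10_000_000
            base = start
        pos = base + offset * 1000
        out.append(SnpRecord(id=rec.id, chrom=rec.chrom, pos=pos,
                             a1=rec.a1, a2=rec.a2, info_r2=rec.info_r2))
    return out


def _unit(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x)


def _pick_causal(rng: np.random.Generator, config: SimulationConfig,
                 k: int, exclude: set[int] = frozenset()) -> list[int]:
    """Pick k causal SNPs, at most one per LD block, excluding given indices."""
    n_blocks = (config.n_snps + config.ld_block_size - 1) // config.ld_block_size
    used_blocks = {i // config.ld_block_size for i in exclude}
    free_blocks = [b for b in range(n_blocks) if b not in used_blocks]
    if len(free_blocks) < k:
        raise ValueError("not enough LD blocks to place causal SNPs disjointly")
    blocks = rng.choice(free_blocks, size=k, replace=False)
    idx = []
    for b in blocks:
        lo = b * config.ld_block_size
        hi = min(lo + config.ld_block_size, config.n_snps)
        idx.append(int(rng.integers(lo, hi)))
    return sorted(idx)


def _sparse_unit(rng: np.random.Generator, p: int, support: list[int]) -> np.ndarray:
    # comparable per-SNP contributions with mild (+-25%) magnitude variation
    u = np.zeros(p)
    mags = 0.75 + 0.5 * rng.random(len(support))
    signs = rng.choice([-1.0, 1.0], size=len(support))
    u[support] = mags * signs
    return _unit(u)


def _standardize_score(t: np.ndarray) -> np.ndarray:
    sd = t.std()
    if sd == 0:
        return np.zeros_like(t)
    return (t - t.mean()) / sd


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection on the logistic intercept so mean(expit(lp + b)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(lp + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate genotypes, phenotype/covariate table and planted truth.

    The phenotype table has one row per sample with columns: sample_id,
    age, sex (1=female), education, icv (cm^3), apoe4 (0/1/2), amyloid
    (0/1), diagnosis (CU/aMCI/DAT), mmse, cdr_sb, global_thickness and the
    12 ROI thickness columns.
    """
    if config.n_rois != len(ROI_COLUMNS):
        roi_cols = [f"thk_roi{r:02d}" for r in range(config.n_rois)]
        baseline = np.resize(_BASELINE_MM, config.n_rois)
    else:
        roi_cols = list(ROI_COLUMNS)
        baseline = _BASELINE_MM.copy()

    rng = np.random.default_rng(config.seed)
    G = simulate_genotypes(config, rng=rng)
    n, p, q = config.n_samples, config.n_snps, config.n_rois
    X = G.standardized()

    # --- planted canonical structure -----------------------------------
    if config.group_signal == "disjoint":
        causal_neg = _pick_causal(rng, config, config.n_causal)
        causal_pos = _pick_causal(rng, config, config.n_causal, exclude=set(causal_neg))
        u_neg = _sparse_unit(rng, p, causal_neg)
        u_pos = _sparse_unit(rng, p, causal_pos)
        causal = sorted(set(causal_neg) | set(causal_pos))
        u_true = _unit(np.abs(u_neg) + np.abs(u_pos))
    else:
        causal = _pick_causal(rng, config, config.n_causal)
        u_true = _sparse_unit(rng, p, causal)
        causal_neg = causal_pos = None
        u_neg = u_pos = None
    # imaging loadings: same-sign atrophy pattern with the hemispheric
    # global means most prominent, then frontal and parietal cortex
    if q == len(ROI_COLUMNS):
        v_raw = np.array([0.80, 0.75,   # frontal L/R
                          0.50, 0.45,   # temporal
                          0.65, 0.60,   # parietal
                          0.25, 0.20,   # occipital
                          0.35, 0.30,   # cingulate
                          1.00, 0.95])  # global
    else:
        v_raw = 1.0 / np.sqrt(1.0 + np.arange(q))
    v_true = _unit(v_raw)

    # --- covariates -----------------------------------------------------
    age = rng.normal(70.2, 8.5, n)
    sex = (rng.random(n) < 0.585).astype(float)
    education = np.clip(rng.normal(11.8, 4.6, n), 0.0, 22.0)
    icv = rng.normal(1450.0, 130.0, n)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.564, 0.344, 0.092]).astype(float)

    # --- amyloid status (mediator) ---------------------------------------
    dos_imp = G.imputed()
    causal_dosage = dos_imp[:, causal].sum(axis=1)
    lp = (config.path_a * (causal_dosage - causal_dosage.mean())
          + config.apoe_logor * (apoe4 - apoe4.mean())
          - 0.01 * (age - age.mean()))
    lp += _calibrate_intercept(lp, config.target_ab_fraction)
    prob = expit(lp)
    amyloid = (rng.random(n) < prob).astype(float)
    if amyloid.min() == amyloid.max():
        raise ValueError("degenerate amyloid-status simulation: single class; "
                         "check path_a / target_ab_fraction")

    # --- thickness -------------------------------------------------------
    Y = np.tile(baseline, (n, 1))
    cov_values = {"age": age - 70.2, "sex": sex, "education": education - 11.8,
                  "icv": icv - 1450.0}
    for name, slope in config.covariate_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown covariate in covariate_effects: {name!r}")
        Y += slope * cov_values[name][:, None]

    if config.group_signal == "disjoint":
        t_neg = _standardize_score(X @ u_neg)
        t_pos = _standardize_score(X @ u_pos)
        score = np.where(amyloid == 0, t_neg, t_pos)
    else:
        score = _standardize_score(X @ u_true)
    Y += config.canonical_strength * np.outer(score, v_true)
    Y += config.path_b * amyloid[:, None]
    Y += config.path_c * causal_dosage[:, None]
    Y += rng.normal(0.0, config.noise_sd, (n, q))

    # --- cognition and diagnosis ----------------------------------------
    if q == len(ROI_COLUMNS):
        global_thk = Y[:, [roi_cols.index("thk_global_l"),
                           roi_cols.index("thk_global_r")]].mean(axis=1)
    else:
        global_thk = Y.mean(axis=1)
    gt_z = _standardize_score(global_thk)
    mmse = np.clip(np.round(24.0 + 3.0 * gt_z + rng.normal(0, 3.0, n)), 0, 30)
    cdr_sb = np.clip(np.round((2.9 - 1.5 * gt_z + rng.normal(0, 1.5, n)) * 2) / 2, 0, 18)

    severity = -gt_z + 1.2 * amyloid + rng.normal(0, 1.0, n)
    order = np.argsort(severity)
    diagnosis = np.empty(n, dtype=object)
    n_cu = int(round(n * 310 / 1125))
    n_mci = int(round(n * 368 / 1125))
    diagnosis[order[:n_cu]] = "CU"
    diagnosis[order[n_cu:n_cu + n_mci]] = "aMCI"
    diagnosis[order[n_cu + n_mci:]] = "DAT"

    pheno = pd.DataFrame({
        "sample_id": G.sample_ids,
        "age": age, "sex": sex, "education": education, "icv": icv,
        "apoe4": apoe4, "amyloid": amyloid, "diagnosis": diagnosis,
        "mmse": mmse, "cdr_sb": cdr_sb, "global_thickness": global_thk,
    })
    for j, col in enumerate(roi_cols):
        pheno[col] = Y[:, j]

    truth = SyntheticTruth(
        causal_indices=list(map(int, causal)), u_true=u_true, v_true=v_true,
        path_a=config.path_a, path_b=config.path_b, path_c=config.path_c,
        causal_indices_neg=list(map(int, causal_neg)) if causal_neg else None,
        causal_indices_pos=list(map(int, causal_pos)) if causal_pos else None,
        u_true_neg=u_neg, u_true_pos=u_pos,
    )
    return G, pheno, truth


def simulate_summary_stats(config: SimulationConfig, truth: SyntheticTruth,
                           G: GenotypeMatrix | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Companion GWAS summary statistics for the panel.

    Causal SNPs draw p-values log-uniform below 1e-4; a ``decoy_fraction``
    of non-causal SNPs do likewise; the rest are Uniform(1e-4, 1).
    Columns: snp, chrom, pos, p.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    p = config.n_snps
    causal = set(truth.causal_indices)
    non_causal = [j for j in range(p) if j not in causal]
    n_decoy = int(round(config.decoy_fraction * len(non_causal)))
    decoys = set(rng.choice(non_causal, size=n_decoy, replace=False).tolist()) \
        if n_decoy else set()

    pvals = np.empty(p)
    for j in range(p):
        if j in causal or j in decoys:
            pvals[j] = 10.0 ** rng.uniform(-8.0, np.log10(1e-4) - 0.05)
        else:
            pvals[j] = rng.uniform(1e-4, 1.0)

    if G is not None and G.n_snps == p:
        ids = G.snp_ids
        chrom = [rec.chrom for rec in G.snps]
        pos = [rec.pos for rec in G.snps]
    else:
        ids = [f"rs{100000 + j}" for j in range(p)]
        chrom = ["1"] * p
        pos = list(range(1, p + 1))
    return pd.DataFrame({"snp": ids, "chrom": chrom, "pos": pos, "p": pvals})


def _companion_annotation(G: GenotypeMatrix, block: int) -> pd.DataFrame:
    """Synthetic SNP->gene map: one gene symbol per LD block."""
    genes = [f"GENE{j // block:03d}" for j in range(G.n_snps)]
    return pd.DataFrame({"snp": G.snp_ids, "gene": genes})


def _companion_gmt(annotation: pd.DataFrame, truth: SyntheticTruth,
                   block: int, rng: np.random.Generator) -> list[str]:
    """Synthetic GMT: one set enriched for causal-SNP genes + random sets."""
    universe = sorted(annotation["gene"].unique())
    causal_genes = sorted({f"GENE{j // block:03d}" for j in truth.causal_indices})
    lines = ["CAUSAL_PATHWAY\tBP\t" + "\t".join(causal_genes)]
    for k in range(12):
        size = int(rng.integers(5, 16))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        ont = ["BP", "MF", "CC"][k % 3]
        lines.append(f"RANDOM_SET_{k:02d}\t{ont}\t" + "\t".join(sorted(members)))
    return lines


def write_fixture(cohort: tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth],
                  out_dir: str | os.PathLike,
                  config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write a complete on-disk fixture: PLINK bed/bim/fam, phenotype TSV,
    summary-stat TSV, SNP->gene annotation TSV, GMT gene sets, truth JSON.

    Returns the mapping of logical names to paths.  Round-tripping the
    PLINK files reproduces the dosage matrix exactly (including missing).
    """
    G, pheno, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / "genotypes"
    write_plink(G, prefix)

    paths = {
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "pheno": out / "phenotypes.tsv",
        "stats": out / "summary_stats.tsv",
        "annotation": out / "snp_gene.tsv",
        "gmt": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    pheno.to_csv(paths["pheno"], sep="\t", index=False)

    cfg = config or SimulationConfig(n_samples=G.n_samples, n_snps=G.n_snps)
    rng = np.random.default_rng(cfg.seed + 2)
    stats = simulate_summary_stats(cfg, truth, G=G, rng=np.random.default_rng(cfg.seed + 1))
    stats.to_csv(paths["stats"], sep="\t", index=False)

    annot = _companion_annotation(G, cfg.ld_block_size)
    annot.to_csv(paths["annotation"], sep="\t", index=False)
    paths["gmt"].write_text("\n".join(_companion_gmt(annot, truth, cfg.ld_block_size, rng)) + "\n")
    paths["truth"].write_text(truth.to_json())
    return paths
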