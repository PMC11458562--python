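# neuroscca

Sparse canonical correlation analysis (SCCA) for imaging genetics: linking a
panel of candidate SNPs to covariate-adjusted cortical-thickness measures in
an amyloid-stratified cohort, with predictive validation, causal mediation
and gene-set enrichment.

## The problem

Cortical atrophy in Alzheimer's disease has a complex genetic architecture,
and the variants that matter may differ between amyloid-negative (Aβ−) and
amyloid-positive (Aβ+) individuals. Given an *n × p* additive SNP dosage
matrix **X** and an *n × q* matrix **Y** of lobar and global mean
cortical-thickness measures (adjusted for age, sex, education and
intracranial volume), SCCA finds unit-norm weight vectors that expose the
strongest joint axis of variation:

```
min_{u,v}  −uᵀXᵀYv    s.t.  ‖u‖₂² = 1, ‖v‖₂² = 1, ‖u‖₁ ≤ τ₁, ‖v‖₁ ≤ τ₂
```

The L1 budgets zero out most SNP weights, so the nonzero entries of *u* name
a small set of variants whose dosage profile co-varies with the atrophy
pattern in *v*. The canonical correlation ρ = corr(Xu, Yv) measures the
strength of that axis. The analysis is run separately within each amyloid
group and on the pooled sample; the top-10 SNPs per group (by |u|) feed
three post-hoc analyses:

* **predictive validation** — elastic-net models of global thickness, MMSE
  and CDR-SB, trained in one amyloid group with repeated 5-fold CV and
  tested on the other, plus a covariates / covariates+top-10 /
  covariates+random-10 model comparison using the Hittner test for two
  dependent overlapping correlations;
* **mediation** — for each (SNP, ROI) pair, the quasi-Bayesian
  potential-outcomes decomposition of the SNP→thickness effect into a
  direct path and an indirect path through binary amyloid positivity
  (ACME / ADE / total);
* **enrichment** — Fisher-exact over-representation of the mapped genes in
  GO-style gene sets, with Benjamini–Hochberg q-values.

Everything upstream is included too: PLINK1 bed/bim/fam I/O, the full
genotype QC chain (sample call rate ≥ 95%, heterozygosity within ±5 SD,
PI_HAT < 0.125, marker call rate ≥ 98%, MAF ≥ 1%, HWE exact p ≥ 1e-6,
imputation r² > 0.8), GWAS p-value filtering (p < 1e-4) and greedy LD
clumping to an approximately uncorrelated candidate panel.

A synthetic cohort generator (`neuroscca.simulate`) produces complete,
seeded fixtures — genotypes with block LD, covariates, amyloid status, ROI
thickness carrying a planted rank-1 canonical signal, cognition scores,
companion summary statistics, SNP→gene annotation and GMT gene sets — so the
entire pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from neuroscca import SimulationConfig, simulate_cohort, groupwise_scca

cfg = SimulationConfig(n_samples=1125, n_snps=344, n_causal=10, seed=1)
G, pheno, truth = simulate_cohort(cfg)

out = groupwise_scca(G, pheno, tau1=np.sqrt(10), tau2=np.sqrt(12))
for grp in ("neg", "pos", "total"):
    r = out[grp]["result"]
    print(f"{grp:5s} n={out[grp]['n']:4d} rho={r.rho:.3f} "
          f"top3={out[grp]['top_snps'][:3]}")

top10 = out["total"]["top_snps"]
causal = {G.snps[j].id for j in truth.causal_indices}
print(f"recovered {len(set(top10) & causal)}/10 planted SNPs in the top 10")
```

prints

```
neg   n= 482 rho=0.625 top3=['rs100111', 'rs100071', 'rs100256']
pos   n= 643 rho=0.605 top3=['rs100111', 'rs100093', 'rs100071']
total n=1125 rho=0.539 top3=['rs100111', 'rs100164', 'rs100071']
recovered 8/10 planted SNPs in the top 10
```

The group-wise canonical correlations (≈0.5–0.6) measure how strongly the
selected SNP combination tracks the adjusted atrophy pattern in each
amyloid stratum, and the top-10 list recovers the planted causal variants.

The same workflow is available from a shell:

```bash
neuroscca demo --out demo_run --seed 1     # simulate + full pipeline
neuroscca qc --bfile demo_run/data/genotypes --out qc_out
neuroscca run --config my_analysis.yaml    # real data, per-stage config
```

`demo` writes per-stage TSVs (SCCA weights and loadings, validation r with
CIs, mediation effect matrices, enrichment tables) plus a manifest of seeds
and content hashes; rerunning with the same seed reproduces every output
byte for byte, and stages whose inputs are unchanged are skipped.

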