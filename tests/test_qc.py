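"""Genotype QC: call rates, heterozygosity, relatedness, HWE, filter chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroscca.qc import (QcThresholds, apply_qc, call_rates,
                          heterozygosity_outliers, hwe_exact_test, ibd_pihat,
                          minor_allele_freq)

from conftest import make_genotypes


# ---------------------------------------------------------------- call rates

def test_call_rates_basic():
    D = np.ones((3, 10))
    D[0, 0] = np.nan          # sample 0: 1 of 10 missing
    s, m = call_rates(make_genotypes(D))
    assert s[0] == pytest.approx(0.9)
    D2 = np.ones((3, 10))
    D2[:, 9] = np.nan         # marker 9 fully missing
    _, m = call_rates(make_genotypes(D2))
    assert m[9] == 0.0
    full = make_genotypes(np.ones((3, 4)))
    s, m = call_rates(full)
    assert np.all(s == 1.0) and np.all(m == 1.0)


def test_call_rates_empty_matrix_rejected():
    with pytest.raises(ValueError):
        call_rates(make_genotypes(np.empty((0, 0))))


# ------------------------------------------------------------ heterozygosity

def test_het_outliers():
    # identical samples: zero variance -> nothing flagged
    D = np.tile([0, 1, 2, 0, 1], (10, 1)).astype(float)
    assert heterozygosity_outliers(make_genotypes(D), 5.0) == set()

    # one all-het sample among all-homozygous ones
    D = np.zeros((100, 20))
    D[7] = 1.0
    flagged = heterozygosity_outliers(make_genotypes(D), 5.0)
    assert flagged == {"s7"}


def test_het_flagging_monotone_in_sd_mult(rng):
    D = rng.integers(0, 3, size=(60, 50)).astype(float)
    G = make_genotypes(D)
    loose = heterozygosity_outliers(G, 3.0)
    tight = heterozygosity_outliers(G, 5.0)
    assert tight <= loose


# ------------------------------------------------------------------- PI_HAT

def _random_genotypes(rng, n, p):
    maf = rng.uniform(0.1, 0.5, p)
    return ((rng.random((n, p)) < maf).astype(float)
            + (rng.random((n, p)) < maf).astype(float))


def test_pihat_duplicate_pair_detected(rng):
    D = _random_genotypes(rng, 30, 800)
    D[1] = D[0]
    ph = ibd_pihat(make_genotypes(D))
    assert ph[0, 1] >= 0.95


def test_pihat_unrelated_near_zero(rng):
    D = _random_genotypes(rng, 40, 1000)
    ph = ibd_pihat(make_genotypes(D))
    off = ph[np.triu_indices(40, 1)]
    assert off.mean() < 0.05


def test_pihat_parent_offspring(rng):
    # child inherits one allele IBD from the parent per locus
    p_count = 1000
    maf = rng.uniform(0.2, 0.5, p_count)
    h = lambda: (rng.random(p_count) < maf).astype(float)
    parent_h1, parent_h2 = h(), h()
    transmit = rng.random(p_count) < 0.5
    child = np.where(transmit, parent_h1, parent_h2) + h()
    others = _random_genotypes(rng, 10, p_count)
    D = np.vstack([parent_h1 + parent_h2, child, others])
    ph = ibd_pihat(make_genotypes(D))
    assert abs(ph[0, 1] - 0.5) < 0.1


def test_pihat_symmetric_unit_diagonal(rng):
    D = _random_genotypes(rng, 15, 300)
    ph = ibd_pihat(make_genotypes(D))
    np.testing.assert_allclose(ph, ph.T)
    np.testing.assert_allclose(np.diag(ph), 1.0)


def test_pihat_monomorphic_panel_rejected():
    with pytest.raises(ValueError, match="polymorphic"):
        ibd_pihat(make_genotypes(np.zeros((5, 10))))


# ----------------------------------------------------------------------- HWE

def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent route: exact conditional probabilities via factorials."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h] = (math.factorial(n)
                    / (math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
                    * 2 ** h)
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(0, 0, 50) == 1.0
    assert hwe_exact_test(50, 0, 0) == 1.0


def test_hwe_two_sample_case_by_enumeration():
    # (1,0,1): attainable het counts {0, 2}; enumeration gives p = 1/3
    assert hwe_exact_test(1, 0, 1) == pytest.approx(1.0 / 3.0)
    assert hwe_exact_test(1, 0, 1) == pytest.approx(hwe_enumeration_oracle(1, 0, 1))


def test_hwe_matches_enumeration_small_totals():
    for n_AA in range(9):
        for n_Aa in range(9):
            for n_aa in range(9):
                if n_AA + n_Aa + n_aa == 0:
                    continue
                rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
                if n_Aa % 2 != rare % 2 or n_Aa > rare:
                    continue  # not an attainable configuration
                got = hwe_exact_test(n_AA, n_Aa, n_aa)
                want = hwe_enumeration_oracle(n_AA, n_Aa, n_aa)
                assert got == pytest.approx(want, abs=1e-12), (n_AA, n_Aa, n_aa)


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_hwe_p_in_unit_interval(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0:
        return
    p = hwe_exact_test(n_AA, n_Aa, n_aa)
    assert 0.0 < p <= 1.0


def test_hwe_invalid_counts_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ----------------------------------------------------------------------- MAF

@pytest.mark.parametrize("column, expected", [
    ([0, 1, 2, 2], 0.375),
    ([0, 0, 0], 0.0),
    ([1, 1, np.nan], 0.5),
])
def test_minor_allele_freq(column, expected):
    assert minor_allele_freq(np.array(column, dtype=float)) == pytest.approx(expected)


def test_maf_all_missing_is_nan():
    assert np.isnan(minor_allele_freq(np.array([np.nan, np.nan])))


# ---------------------------------------------------------------- apply_qc

def _clean_panel(rng, n=80, p=60):
    maf = rng.uniform(0.2, 0.5, p)
    return ((rng.random((n, p)) < maf).astype(float)
            + (rng.random((n, p)) < maf).astype(float))


def test_apply_qc_planted_violations_counted_exactly(rng):
    D = _clean_panel(rng)
    D[0, :20] = np.nan   # 3 samples under 95% call rate (20/60 missing)
    D[1, :20] = np.nan
    D[2, :20] = np.nan
    for j in range(50, 55):           # 5 markers with MAF < 1%
        D[:, j] = 0.0
        D[0, j] = 1.0 if j % 2 else 0.0  # MAF 1/160 or 0, both < 0.01
    G = make_genotypes(D)
    th = QcThresholds(ibd_pihat_max=1.0, het_sd_mult=50.0)  # isolate the two filters
    filtered, report = apply_qc(G, th)
    counts = report.counts()
    assert counts.get("sample_call_rate", 0) == 3
    assert counts.get("maf", 0) == 5
    assert filtered.n_samples == 77 and filtered.n_snps == 55


def test_apply_qc_extreme_thresholds_remove_nothing(rng):
    G = make_genotypes(_clean_panel(rng))
    th = QcThresholds(sample_call_rate_min=0.0, marker_call_rate_min=0.0,
                      maf_min=0.0, hwe_p_min=0.0, ibd_pihat_max=1.0,
                      het_sd_mult=1e6)
    filtered, report = apply_qc(G, th)
    assert report.records == []
    assert filtered.n_samples == G.n_samples and filtered.n_snps == G.n_snps


def test_apply_qc_idempotent(rng):
    D = _clean_panel(rng, n=100, p=80)
    D[0, :40] = np.nan
    D[:, 0] = 0.0
    G = make_genotypes(D)
    th = QcThresholds(ibd_pihat_max=0.9)
    once, rep1 = apply_qc(G, th)
    twice, rep2 = apply_qc(once, th)
    assert rep2.records == []
    assert twice.n_samples == once.n_samples and twice.n_snps == once.n_snps


def test_apply_qc_survivors_order_invariant_without_ibd(rng):
    # with independent per-entity criteria the surviving set is unique
    D = _clean_panel(rng, n=60, p=40)
    D[3, :15] = np.nan
    for j in range(35, 38):
        D[:, j] = 0.0
    G = make_genotypes(D)
    th = QcThresholds(ibd_pihat_max=1.0, het_sd_mult=1e6,
                      sample_call_rate_min=0.7, maf_min=0.01)
    f1, _ = apply_qc(G, th)
    # permute samples and markers, reapply, compare surviving ID sets
    perm_s = rng.permutation(60)
    perm_m = rng.permutation(40)
    Gp = G.subset_samples(perm_s).subset_snps(perm_m)
    f2, _ = apply_qc(Gp, th)
    assert set(f1.sample_ids) == set(f2.sample_ids)
    assert set(f1.snp_ids) == set(f2.snp_ids)


def test_apply_qc_ibd_drops_lower_call_rate_member(rng):
    D = _clean_panel(rng, n=20, p=500)
    D[5] = D[4]           # duplicate pair
    D[5, :50] = np.nan    # member 5 has the lower call rate
    G = make_genotypes(D)
    # duplicate-level threshold: unrelated-pair PI_HAT noise at p=500 markers
    # stays well below 0.45
    th = QcThresholds(sample_call_rate_min=0.5, ibd_pihat_max=0.45)
    filtered, report = apply_qc(G, th)
    ibd_removed = report.removed_ids("ibd")
    assert ibd_removed == ["s5"]
    assert "s4" in filtered.sample_ids


def test_apply_qc_all_removed_is_error(rng):
    D = np.full((4, 6), np.nan)
    D[:, 0] = 1.0  # keep matrix constructible
    with pytest.raises(ValueError):
        apply_qc(make_genotypes(D), QcThresholds())
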