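"""Heterozygosity, rarefied allelic richness, F_IS, HWE and LD screens."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from islepop import (
    GenotypeDataset, allelic_richness, f_is, heterozygosity, ho_he_ttest,
    hwe_test, ld_test,
)
from islepop.diversity import hwe_chisq_single

from conftest import random_dataset


def _single_pop(calls):
    calls = np.asarray(calls)
    return GenotypeDataset(
        [f"i{k}" for k in range(len(calls))], ["P"] * len(calls),
        [f"L{j + 1}" for j in range(calls.shape[1])], calls,
    )


# ---------------------------------------------------------------------------
# heterozygosity


def test_unbiased_expected_heterozygosity_hand_value():
    d = _single_pop([[[1, 2]], [[1, 2]]])  # pop {Aa, Aa}
    row = heterozygosity(d).per_locus.iloc[0]
    assert row["H_O"] == 1.0
    assert row["H_E"] == pytest.approx(4 / 3 * 0.5)


def test_monomorphic_locus_zero_heterozygosity():
    d = _single_pop([[[7, 7]], [[7, 7]], [[7, 7]]])
    row = heterozygosity(d).per_locus.iloc[0]
    assert row["H_O"] == 0.0 and row["H_E"] == 0.0


def test_he_unbiasedness_under_known_frequencies(rng):
    p = np.array([0.5, 0.3, 0.2])
    target = 1 - np.sum(p**2)
    vals = []
    for _ in range(400):
        genes = rng.choice(3, p=p, size=(8, 1, 2)) + 1
        vals.append(heterozygosity(_single_pop(genes)).per_locus["H_E"][0])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - target) < 4 * se


def test_ho_he_ttest_cases(rng):
    # identical H_O and H_E at every locus -> t = 0, p = 1
    d = _single_pop(rng.integers(1, 5, size=(40, 5, 2)))
    summ = heterozygosity(d)
    summ.per_locus["H_O"] = summ.per_locus["H_E"]
    t, p = ho_he_ttest(summ)
    assert t == 0.0 and p == 1.0
    # constant positive offset, zero variance -> degenerate p -> 0
    summ.per_locus["H_O"] = summ.per_locus["H_E"] - 0.1
    t, p = ho_he_ttest(summ)
    assert p == 0.0 and math.isinf(t)


def test_ho_he_ttest_matches_textbook_formula(rng):
    d = _single_pop(rng.integers(1, 6, size=(30, 6, 2)))
    summ = heterozygosity(d)
    t, p = ho_he_ttest(summ)
    diffs = (summ.per_locus["H_E"] - summ.per_locus["H_O"]).to_numpy()
    n = len(diffs)
    t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
    p_hand = 2 * stats.t.sf(abs(t_hand), n - 1)
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(p_hand)


def test_ho_he_ttest_requires_two_loci():
    d = _single_pop([[[1, 2]], [[1, 1]]])
    with pytest.raises(ValueError):
        ho_he_ttest(heterozygosity(d))


# ---------------------------------------------------------------------------
# allelic richness


def _exhaustive_ar(genes, g):
    subs = list(combinations(range(len(genes)), g))
    return sum(len(set(genes[list(s)])) for s in subs) / len(subs)


def test_ar_monomorphic_and_full_sample():
    d = _single_pop([[[3, 3]], [[3, 3]], [[3, 3]]])
    assert allelic_richness(d, 2).per_locus["AR"][0] == pytest.approx(1.0)
    d2 = _single_pop([[[1, 2]], [[3, 4]]])
    assert allelic_richness(d2, 4).per_locus["AR"][0] == pytest.approx(4.0)


def test_ar_equals_exhaustive_enumeration(rng):
    genes = rng.integers(1, 4, size=8)
    d = _single_pop(genes.reshape(4, 1, 2))
    for g in range(1, 9):
        got = allelic_richness(d, g).per_locus["AR"][0]
        assert got == pytest.approx(_exhaustive_ar(genes, g), abs=1e-12)


def test_ar_nondecreasing_in_g(rng):
    d = _single_pop(rng.integers(1, 6, size=(10, 2, 2)))
    ars = [allelic_richness(d, g).per_population["AR"][0]
           for g in range(2, 21)]
    assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))


def test_private_ar_zero_without_unique_alleles(rng):
    """At g equal to the full sample, shared alleles cannot be private.

    For g below the other population's full gene count, hypergeometric
    rarefaction gives a strictly positive expected private count even for
    shared alleles (a finite subsample can miss them), so the zero
    identity is checked at full sample size.
    """
    shared = rng.integers(1, 4, size=(6, 2, 2))
    d = GenotypeDataset(
        [f"i{k}" for k in range(12)], ["A"] * 6 + ["B"] * 6,
        ["L1", "L2"], np.concatenate([shared, shared]),
    )
    res = allelic_richness(d, 12, private=True)
    assert np.allclose(res.per_locus["private_AR"], 0.0)
    # and a genuinely unique allele is recovered at full g
    shared2 = shared.copy()
    shared2[0, 0, 0] = 9
    d2 = GenotypeDataset(
        [f"i{k}" for k in range(12)], ["A"] * 6 + ["B"] * 6,
        ["L1", "L2"], np.concatenate([shared2, shared]),
    )
    res2 = allelic_richness(d2, 12, private=True)
    a_l1 = res2.per_locus.query("population=='A' and locus=='L1'")
    assert a_l1["private_AR"].iloc[0] == pytest.approx(1.0)


def test_ar_g_too_large_raises(rng):
    d = _single_pop(rng.integers(1, 4, size=(4, 1, 2)))
    with pytest.raises(ValueError, match="gene copies"):
        allelic_richness(d, 9, adjust_g=False)


# ---------------------------------------------------------------------------
# F_IS


def test_fis_fully_homozygous_is_one():
    calls = np.array([[[1, 1], [2, 2]], [[3, 3], [4, 4]],
                      [[1, 1], [2, 2]], [[3, 3], [2, 2]]])
    res = f_is(_single_pop(calls), n_boot=49, seed=0)
    assert res["F_IS"][0] == pytest.approx(1.0)


def test_fis_null_under_hardy_weinberg(rng):
    genes = rng.choice(4, p=[0.4, 0.3, 0.2, 0.1], size=(300, 8, 2)) + 1
    res = f_is(_single_pop(genes), n_boot=199, seed=1)
    assert abs(res["F_IS"][0]) < 0.05
    assert res["ci_low"][0] <= 0 <= res["ci_high"][0]
    assert not res["significant"][0]


def test_fis_matches_anova_route(rng):
    """W&C f equals the nested-ANOVA variance-component estimate."""
    calls = rng.integers(1, 4, size=(12, 3, 2))
    d = _single_pop(calls)
    res = f_is(d, n_boot=1, seed=0)
    num = den = 0.0
    for li in range(3):
        g = calls[:, li, :]
        n = len(g)
        alleles = np.unique(g)
        if len(alleles) < 2:
            continue
        for a in alleles:
            x = (g == a).astype(float)        # (n, 2) indicators
            xbar_i = x.mean(axis=1)
            ssg = np.sum((x - xbar_i[:, None]) ** 2)
            ssi = 2 * np.sum((xbar_i - xbar_i.mean()) ** 2)
            msg = ssg / n
            msi = ssi / (n - 1)
            den += msi / 2 + msg / 2
            num += (msi - msg) / 2
    assert res["F_IS"][0] == pytest.approx(num / den)


# ---------------------------------------------------------------------------
# HWE


def test_hwe_exact_proportions_give_p_one():
    calls = ([[1, 1]] * 25) + ([[1, 2]] * 50) + ([[2, 2]] * 25)
    chi2, p, df = hwe_chisq_single(np.array(calls))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert df == 1


def test_hwe_all_heterozygotes_strongly_significant():
    chi2, p, df = hwe_chisq_single(np.array([[1, 2]] * 50))
    assert p < 1e-10


def test_hwe_three_alleles_matches_direct_summation(rng):
    g = rng.integers(1, 4, size=(40, 2))
    chi2, p, df = hwe_chisq_single(g)
    # independent direct summation over the 6 genotype classes
    n = len(g)
    alleles, counts = np.unique(g, return_counts=True)
    freq = dict(zip(alleles, counts / (2 * n)))
    gs = np.sort(g, axis=1)
    chi2_hand = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            obs = np.sum((gs[:, 0] == a) & (gs[:, 1] == b))
            exp = n * (freq[a] ** 2 if a == b else 2 * freq[a] * freq[b])
            chi2_hand += (obs - exp) ** 2 / exp
    assert df == 3
    assert chi2 == pytest.approx(chi2_hand)


def test_hwe_bonferroni_counts_performed_tests(rng):
    data = random_dataset(rng, n_per_pop=(20, 20), n_loci=3)
    out = hwe_test(data, alpha=0.05)
    n_tests = out["p"].notna().sum()
    assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / n_tests)


# ---------------------------------------------------------------------------
# LD


def test_ld_duplicated_locus_is_extreme(rng):
    g = rng.integers(1, 4, size=(30, 1, 2))
    calls = np.concatenate([g, g], axis=1)  # perfect duplicate
    d = _single_pop(calls)
    out = ld_test(d, n_perm=99, seed=3)
    assert out["p"][0] <= 0.05


def test_ld_monomorphic_pair_is_na(rng):
    calls = np.ones((10, 2, 2), dtype=int)
    calls[:, 0, :] = rng.integers(1, 4, size=(10, 2))
    d = _single_pop(calls)
    out = ld_test(d, n_perm=99, seed=0)
    assert np.isnan(out["p"][0])


def test_ld_requires_min_permutations(toy_dataset):
    with pytest.raises(ValueError):
        ld_test(toy_dataset, n_perm=10)
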