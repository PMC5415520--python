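"""Weir-Cockerham theta, G_ST, Jost's D, exact tests and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from islepop import (
    GenotypeDataset, allele_count_vs_diff, compute_differentiation,
    genotypic_exact_test,
)
from islepop.differentiation import (
    jost_d_locus, mc_fisher_pvalue, per_locus_estimate, theta_components,
)

from conftest import random_dataset


def _two_pop(calls_a, calls_b, n_loci=None):
    a, b = np.asarray(calls_a), np.asarray(calls_b)
    calls = np.concatenate([a, b])
    L = calls.shape[1]
    return GenotypeDataset(
        [f"i{k}" for k in range(len(calls))],
        ["A"] * len(a) + ["B"] * len(b),
        [f"L{j + 1}" for j in range(L)], calls,
    )


def test_all_statistics_one_on_fixed_divergent_pair():
    d = _two_pop(np.full((8, 3, 2), 1), np.full((8, 3, 2), 2))
    for stat in ("theta", "gst", "jostd"):
        res = compute_differentiation(d, stat, n_boot=0)
        assert res.get("A", "B") == pytest.approx(1.0)


def test_statistics_near_zero_on_panmictic_halves(rng):
    means = {s: [] for s in ("theta", "gst", "jostd")}
    for _ in range(150):
        pool = rng.choice(4, p=[0.4, 0.3, 0.2, 0.1], size=(40, 2)) + 1
        gs = [pool[:20], pool[20:]]
        for s in means:
            means[s].append(per_locus_estimate(gs, s))
    for s, vals in means.items():
        assert abs(np.nanmean(vals)) < 0.02, s


def test_jost_d_parametric_two_deme_value():
    """D = [(0.5 - 0.18)/(1 - 0.18)]*2 ~ 0.780 for freqs (.9,.1) vs (.1,.9).

    Samples are built with the exact parametric frequencies; the
    finite-sample corrections vanish as n grows.
    """
    n = 500
    a = np.concatenate([np.full(2 * int(0.9 * n), 1),
                        np.full(2 * n - 2 * int(0.9 * n), 2)])
    b = np.concatenate([np.full(2 * n - 2 * int(0.9 * n), 1),
                        np.full(2 * int(0.9 * n), 2)])
    d = jost_d_locus([a.reshape(-1, 2), b.reshape(-1, 2)])
    expected = (0.5 - 0.18) / (1 - 0.18) * 2
    assert d == pytest.approx(expected, abs=0.01)


def test_theta_matches_nested_anova_route(rng):
    """Multiallelic W&C theta equals the explicit sums-of-squares ANOVA."""
    calls_a = rng.integers(1, 5, size=(9, 1, 2))
    calls_b = rng.integers(1, 5, size=(13, 1, 2))
    gs = [calls_a[:, 0, :], calls_b[:, 0, :]]
    a_sum, abc_sum = theta_components(gs)

    n = np.array([len(g) for g in gs], dtype=float)
    r = 2
    ntot = n.sum()
    nc = (ntot - np.sum(n**2) / ntot) / (r - 1)
    num = den = 0.0
    for allele in np.unique(np.concatenate([g.ravel() for g in gs])):
        x = [(g == allele).astype(float) for g in gs]
        xbar_i = [xi.mean(axis=1) for xi in x]
        xbar_p = np.array([xb.mean() for xb in xbar_i])
        xbar = np.sum(n * xbar_p) / ntot
        ssg = sum(np.sum((xi - xb[:, None]) ** 2)
                  for xi, xb in zip(x, xbar_i))
        ssi = 2 * sum(np.sum((xb - xp) ** 2)
                      for xb, xp in zip(xbar_i, xbar_p))
        ssp = 2 * np.sum(n * (xbar_p - xbar) ** 2)
        msg = ssg / ntot
        msi = ssi / (ntot - r)
        msp = ssp / (r - 1)
        sc = msg
        sb = (msi - msg) / 2
        sa = (msp - msi) / (2 * nc)
        num += sa
        den += sa + sb + sc
    assert a_sum / abc_sum == pytest.approx(num / den)


def test_theta_invariances(rng):
    calls_a = rng.integers(1, 4, size=(10, 1, 2))
    calls_b = rng.integers(2, 6, size=(12, 1, 2))
    gs = [calls_a[:, 0, :], calls_b[:, 0, :]]
    t0 = per_locus_estimate(gs, "theta")
    # population order
    assert per_locus_estimate(gs[::-1], "theta") == pytest.approx(t0)
    # allele relabeling
    relabel = {a: 10 - a for a in range(1, 7)}
    gs2 = [np.vectorize(relabel.get)(g) for g in gs]
    assert per_locus_estimate(gs2, "theta") == pytest.approx(t0)


def test_multilocus_theta_equals_single_locus(rng):
    d = random_dataset(rng, n_per_pop=(10, 10), n_loci=1)
    res = compute_differentiation(d, "theta", n_boot=0)
    per_locus = res.per_locus_values("P1", "P2").iloc[0]
    assert res.get("P1", "P2") == pytest.approx(per_locus)


def test_bootstrap_ci_brackets_estimate(rng):
    d = random_dataset(rng, n_per_pop=(15, 15), n_loci=5)
    res = compute_differentiation(d, "theta", n_boot=99, seed=7)
    lo, hi = res.ci[frozenset(("P1", "P2"))]
    assert lo <= hi
    # percentile CI from individual resampling should usually bracket
    assert lo - 0.1 <= res.get("P1", "P2") <= hi + 0.1


def test_candidate_never_pooled_with_neutral(rng):
    d = random_dataset(rng, n_per_pop=(10, 10), n_loci=4, candidate="IGF1")
    res = compute_differentiation(d, "theta", n_boot=0)
    assert "IGF1" not in set(res.per_locus["locus"])


def test_mc_fisher_matches_hypergeometric(rng):
    table = np.array([[6, 2], [1, 7]])
    _, p_exact = stats.fisher_exact(table)
    p_mc = mc_fisher_pvalue(table[:, 0], table[:, 1], 4000, rng)
    se = np.sqrt(p_exact * (1 - p_exact) / 4000)
    assert abs(p_mc - p_exact) < 4 * se + 1e-3


def test_genotypic_exact_disjoint_supports(rng):
    d = _two_pop(np.full((10, 2, 2), 1), np.full((10, 2, 2), 3))
    out = genotypic_exact_test(d, n_mc=199, seed=0)
    assert out["p"][0] < 1e-3


def test_genotypic_exact_monomorphic_excluded(rng):
    calls_a = np.concatenate(
        [np.full((10, 1, 2), 1), rng.integers(1, 4, (10, 1, 2))], axis=1
    )
    calls_b = np.concatenate(
        [np.full((10, 1, 2), 1), rng.integers(1, 4, (10, 1, 2))], axis=1
    )
    d = _two_pop(calls_a, calls_b)
    out = genotypic_exact_test(d, n_mc=199, seed=0)
    assert out["n_loci"][0] == 1  # monomorphic L1 dropped


def test_allele_count_regression_recovers_linear_relation(rng):
    # loci with different allele numbers so the predictor varies
    blocks = [rng.integers(1, k, size=(24, 1, 2)) for k in (3, 4, 6, 8, 10, 12)]
    calls = np.concatenate(blocks, axis=1)
    d = GenotypeDataset(
        [f"i{j}" for j in range(24)], ["P1"] * 12 + ["P2"] * 12,
        [f"L{j + 1}" for j in range(6)], calls,
    )
    res = compute_differentiation(d, "theta", n_boot=0)
    table, fit = allele_count_vs_diff(d, res)
    # independent least-squares via normal equations
    x, y = table["mean_alleles"].to_numpy(), table["value"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit["slope"] == pytest.approx(beta[1])
    # constant statistic -> zero slope
    res.per_locus["value"] = 0.3
    _, fit0 = allele_count_vs_diff(d, res)
    assert fit0["slope"] == 0.0
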