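"""Coancestry N_eb, bottleneck heterozygosity excess, drift regression."""

import numpy as np
import pandas as pd
import pytest

from islepop import (
    GenotypeDataset, bottleneck_test, coancestry_neb, drift_regression,
    compute_differentiation, simulate_breeding_cohort,
)
from islepop.coalescent import equilibrium_het_given_k

from conftest import random_dataset


def _single_pop(calls):
    calls = np.asarray(calls)
    return GenotypeDataset(
        [f"i{k}" for k in range(len(calls))], ["P"] * len(calls),
        [f"L{j + 1}" for j in range(calls.shape[1])], calls,
    )


# ---------------------------------------------------------------------------
# coancestry N_eb


def test_clonal_population_minimal_neb():
    # identical heterozygous clones: between-individual gene identity 1/2,
    # within-individual 0, so f1 = 1/2 and N_eb = 1 breeder
    calls = np.tile(np.array([[[1, 2], [3, 4]]]), (6, 1, 1))
    res = coancestry_neb(_single_pop(calls))
    assert res.table["f1"][0] == pytest.approx(0.5)
    assert res.table["N_eb"][0] == pytest.approx(1.0)


def test_identity_sums_symmetric_in_locus_order(rng):
    calls = rng.integers(1, 5, size=(10, 4, 2))
    d1 = _single_pop(calls)
    d2 = _single_pop(calls[:, ::-1, :])
    t1 = coancestry_neb(d1).table
    t2 = coancestry_neb(d2).table
    assert t1["f1"][0] == pytest.approx(t2["f1"][0])


def test_neb_monotone_in_breeder_count(rng):
    med = {}
    for n_pairs in (5, 25):
        vals = []
        for r in range(40):
            ds = simulate_breeding_cohort(
                n_pairs, 30, n_loci=12, theta=8.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            vals.append(coancestry_neb(ds).table["N_eb"][0])
        med[n_pairs] = np.median(vals)
    assert med[5] < med[25]


def test_single_individual_population_is_na():
    calls = np.array([[[1, 2]]])
    res = coancestry_neb(_single_pop(calls))
    assert np.isnan(res.table["N_eb"][0])


# ---------------------------------------------------------------------------
# bottleneck test


def test_equilibrium_mean_het_monotone_in_allele_count(rng):
    means = []
    for k in (2, 4, 6):
        c = equilibrium_het_given_k(40, k, model="iam", n_iter=300, rng=rng)
        means.append(c.het.mean())
    assert means[0] < means[1] < means[2]


def test_bottleneck_monomorphic_only_gives_na():
    calls = np.ones((8, 5, 2), dtype=int)
    res = bottleneck_test(_single_pop(calls), model="smm", n_iter=100, seed=0)
    assert np.isnan(res.per_population["p_excess"][0])
    assert res.per_population["n_loci"][0] == 0


def test_bottleneck_few_loci_gives_na(rng):
    d = random_dataset(rng, n_per_pop=(10,), n_loci=2)
    res = bottleneck_test(d, model="smm", n_iter=100, seed=0)
    assert np.isnan(res.per_population["p_excess"][0])


def test_bottleneck_requires_min_iterations(toy_dataset):
    with pytest.raises(ValueError):
        bottleneck_test(toy_dataset, n_iter=10)


def test_bottleneck_output_shape(rng):
    d = random_dataset(rng, n_per_pop=(15,), n_loci=6)
    res = bottleneck_test(d, model="tpm", n_iter=100, seed=1)
    assert set(res.per_locus["locus"]) <= set(d.loci)
    assert ((res.per_locus["n_sim"] >= 100).all())
    p = res.per_population["p_excess"][0]
    assert 0 < p <= 1


# ---------------------------------------------------------------------------
# drift regression


def _pairwise_from_values(values):
    pops = sorted({p for pair in values for p in pair})
    from islepop.differentiation import PairwiseStatResult

    ests = {frozenset(k): v for k, v in values.items()}
    return PairwiseStatResult("theta", pops, ests, pd.DataFrame(
        columns=["pop1", "pop2", "locus", "value"]))


def test_drift_regression_perfectly_collinear():
    div = pd.DataFrame({"population": list("ABCD"),
                        "value": [0.2, 0.4, 0.6, 0.8]})
    values = {}
    for i, p1 in enumerate("ABCD"):
        for p2 in "ABCD"[i + 1:]:
            x = (div.value[div.population == p1].iloc[0]
                 + div.value[div.population == p2].iloc[0]) / 2
            values[(p1, p2)] = 1.0 - x  # exact negative line
    res = drift_regression({"theta": _pairwise_from_values(values)},
                           {"H_E": div})
    assert res["r2"][0] == pytest.approx(1.0)
    assert res["slope"][0] == pytest.approx(-1.0)


def test_drift_regression_constant_predictor_is_na():
    div = pd.DataFrame({"population": list("ABCD"), "value": [0.5] * 4})
    values = {(p1, p2): 0.1 for i, p1 in enumerate("ABCD")
              for p2 in "ABCD"[i + 1:]}
    res = drift_regression({"theta": _pairwise_from_values(values)},
                           {"H_E": div})
    assert np.isnan(res["slope"][0])


def test_drift_regression_negative_slope_under_drift(rng):
    """Pairs involving strongly drifted (low-diversity) populations are the
    most differentiated, so the regression slope is negative."""
    from islepop import heterozygosity, lynx_default_scenario, simulate_scenario

    neg = 0
    for r in range(5):
        sc = lynx_default_scenario(seed=100 + r, scale=0.08, s=0.0)
        data, _ = simulate_scenario(sc, track_trajectories=False)
        div = heterozygosity(data)
        theta = compute_differentiation(data, "theta", n_boot=0)
        tab = div.per_population.rename(columns={"H_E": "value"})[
            ["population", "value"]]
        res = drift_regression({"theta": theta}, {"H_E": tab})
        neg += res["slope"][0] < 0
    assert neg >= 4
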