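"""Candidate-locus selection evidence: envelope, contrasts, outlier scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from islepop import (
    GenotypeDataset, admixture_assignment, allele_frequencies,
    candidate_frequency_contrast, jostd_envelope,
)
from islepop.differentiation import PairwiseStatResult
from islepop.selection import _conditional_band, fdist_scan


def _result(per_locus_values, pair=("A", "B"), statistic="jostd",
            candidate=False):
    """Build a PairwiseStatResult from explicit per-locus values."""
    rows = [{"pop1": pair[0], "pop2": pair[1], "locus": f"L{i}", "value": v}
            for i, v in enumerate(per_locus_values)]
    if candidate:
        rows = [{**rows[0], "locus": "IGF1"}]
        est = per_locus_values[0]
    else:
        est = float(np.mean(per_locus_values))
    return PairwiseStatResult(
        statistic, list(pair), {frozenset(pair): est}, pd.DataFrame(rows),
        marker_set="candidate" if candidate else "neutral",
    )


def test_envelope_trivial_classifications():
    neutral_vals = [0.1, 0.2, 0.3, 0.2, 0.2]
    mean = np.mean(neutral_vals)
    sem = np.std(neutral_vals, ddof=1) / np.sqrt(5)
    neutral = _result(neutral_vals)
    for value, expected in [(mean, "within"), (mean + 10 * sem, "above"),
                            (mean - 10 * sem, "below")]:
        cand = _result([value], candidate=True)
        env = jostd_envelope(neutral, cand)
        assert env.table["classification"][0] == expected


def test_envelope_invariant_to_locus_order(rng):
    vals = list(rng.random(8))
    cand = _result([0.5], candidate=True)
    e1 = jostd_envelope(_result(vals), cand)
    e2 = jostd_envelope(_result(vals[::-1]), cand)
    pd.testing.assert_frame_equal(e1.table, e2.table)


def test_envelope_sem_scales_inverse_sqrt_l(rng):
    vals = list(rng.random(6))
    cand = _result([0.5], candidate=True)
    sem1 = jostd_envelope(_result(vals), cand).table["sem"][0]
    sem4 = jostd_envelope(_result(vals * 4), cand).table["sem"][0]
    # duplicating the loci 4x shrinks the SEM by 2, up to the exact
    # ddof-1 correction: sd_24 = sd_6 * sqrt((4*5)/23)
    assert sem4 == pytest.approx(sem1 / 2 * np.sqrt(20 / 23))


def test_envelope_single_locus_errors():
    with pytest.raises(ValueError, match="SEM"):
        jostd_envelope(_result([0.2]), _result([0.3], candidate=True))


def test_admixture_assignment_rules():
    q = np.array([
        [0.9, 0.1, 0.0],
        [0.5, 0.5, 0.0],
        [0.4, 0.35, 0.25],
        [0.2, 0.29, 0.51],
    ])
    out = admixture_assignment(q, labels=["c1", "c2", "c3"])
    assert out == ["c1", "unassigned", "unassigned", "c3"]
    with pytest.raises(ValueError):
        admixture_assignment(np.array([[0.6, 0.6]]))


def test_candidate_contrast_disjoint_alleles(rng):
    calls = np.concatenate([
        np.full((10, 1, 2), 1), np.full((10, 1, 2), 5)
    ])
    d = GenotypeDataset(
        [f"i{k}" for k in range(20)], ["A"] * 10 + ["B"] * 10, ["IGF1"],
        calls, "IGF1",
    )
    pvals, ftab = candidate_frequency_contrast(
        allele_frequencies(d), "IGF1", n_mc=199, seed=0
    )
    assert pvals["p"][0] == pytest.approx(1 / 200)
    modal = ftab[ftab.population == "A"]["modal_allele"].iloc[0]
    assert modal == 1


def test_candidate_contrast_2x2_matches_hypergeometric(rng):
    counts = {("A", "IGF1"): {1: 12, 2: 4}, ("B", "IGF1"): {1: 5, 2: 11}}
    from islepop.io import AlleleFrequencyTable

    table = AlleleFrequencyTable(["A", "B"], ["IGF1"], counts)
    pvals, _ = candidate_frequency_contrast(table, "IGF1", n_mc=4000, seed=2)
    _, p_exact = stats.fisher_exact(np.array([[12, 5], [4, 11]]))
    se = np.sqrt(p_exact * (1 - p_exact) / 4000)
    assert abs(pvals["p"][0] - p_exact) < 4 * se + 1e-3


def test_conditional_band_monotone_in_confidence(rng):
    cloud = pd.DataFrame({"het": rng.random(2000),
                          "fst": rng.normal(0.1, 0.05, 2000)})
    lo50, hi50 = _conditional_band(cloud, 0.5, 0.5, 400)
    lo95, hi95 = _conditional_band(cloud, 0.5, 0.95, 400)
    assert lo95 <= lo50 <= hi50 <= hi95


def test_fdist_scan_smoke(rng):
    """Envelope machinery runs end to end and brackets most neutral loci."""
    from islepop.coalescent import sample_island

    n_loci, gpd = 25, 20
    calls = np.empty((2 * gpd // 2, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        demes = sample_island(2, gpd, 10.0, 1.0, model="smm", rng=rng)
        calls[:, li, :] = np.concatenate(demes).reshape(-1, 2)
    d = GenotypeDataset(
        [f"i{k}" for k in range(gpd)], ["A"] * (gpd // 2) + ["B"] * (gpd // 2),
        [f"L{j}" for j in range(n_loci)], calls,
    )
    res = fdist_scan(d, n_sim=1000, seed=4, bisect_batch=100,
                     genes_per_deme=gpd)
    assert len(res.verdicts) == n_loci
    assert (res.verdicts["lower"] <= res.verdicts["upper"]).all()
    flagged = (res.verdicts["verdict"] != "neutral").mean()
    assert flagged <= 0.3  # most self-simulated loci are neutral
    assert res.bisection_trace  # bisection ran and was recorded
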