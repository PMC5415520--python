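"""Self-validation experiments for the analysis chain.

Each routine regenerates its own synthetic inputs, runs the relevant part
of the package, and measures a calibration or recovery quantity:
estimator checks against closed forms, rarefaction exactness against
exhaustive enumeration, bottleneck-test type-I rate and power, coancestry
N_eb parameter recovery, the end-to-end Jost's-D envelope experiment, and
the outlier-scan false-positive rate.  Problem sizes are chosen so the
whole battery runs in minutes on one core; the methods note records them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .coalescent import sample_island, sample_panmictic
from .differentiation import multilocus_estimate, per_locus_estimate
from .drift import bottleneck_test, coancestry_neb
from .io import GenotypeDataset
from .selection import fdist_scan, jostd_envelope
from .simulate import (
    _mutate_genes, _tpm_q, lynx_default_scenario, simulate_breeding_cohort,
    simulate_scenario,
)
from . import compute_differentiation


def _dataset_from_pops(pop_genes: list[np.ndarray], n_loci_axis=None
                       ) -> GenotypeDataset:
    """Single-locus dataset from per-population gene arrays (paired)."""
    individuals, populations, calls = [], [], []
    for pi, genes in enumerate(pop_genes):
        g = genes.reshape(-1, 2)
        for j in range(len(g)):
            individuals.append(f"p{pi}_{j}")
            populations.append(f"P{pi + 1}")
        calls.append(g[:, None, :])
    return GenotypeDataset(
        individuals, populations, ["L1"], np.concatenate(calls), None
    )


# ---------------------------------------------------------------------------
# estimator correctness (fixed / null / island closed form)


def estimator_checks(seed: int, n_null: int = 500, n_island: int = 200,
                     loci_per_set: int = 8) -> dict:
    rng = np.random.default_rng(seed)
    out: dict = {}
    # fully fixed divergent pair: all three statistics must equal 1
    g1, g2 = np.full((12, 2), 101), np.full((12, 2), 105)
    for stat in ("theta", "gst", "jostd"):
        out[f"{stat}_fixed"] = per_locus_estimate([g1, g2], stat)
    # panmictic null: mean over n_null random halves of one pool
    sums = {s: 0.0 for s in ("theta", "gst", "jostd")}
    for _ in range(n_null):
        freqs = rng.dirichlet(np.ones(4))
        pool = rng.choice(4, p=freqs, size=(60, 2)) + 101
        gs = [pool[:30], pool[30:]]
        for stat in sums:
            v = per_locus_estimate(gs, stat)
            sums[stat] += v if np.isfinite(v) else 0.0
    for stat in sums:
        out[f"{stat}_null_mean"] = sums[stat] / n_null
    # island-model equilibrium at 4Nm = 9: E[theta] ~ 1/(1+4Nm) = 0.1
    # (100-deme finite-island coalescent, 2 demes sampled, low mutation)
    reps = []
    for _ in range(n_island):
        sets = []
        for _ in range(loci_per_set):
            demes = sample_island(2, 50, 9.0, 0.5, model="smm", rng=rng)
            sets.append([d.reshape(-1, 2) for d in demes])
        reps.append(multilocus_estimate(sets, "theta"))
    out["island_theta_mean"] = float(np.nanmean(reps))
    return out


# ---------------------------------------------------------------------------
# rarefaction exactness


def _exhaustive_ar(genes: np.ndarray, g: int) -> float:
    tot = 0
    n_sub = 0
    for sub in combinations(range(len(genes)), g):
        tot += len(set(genes[list(sub)]))
        n_sub += 1
    return tot / n_sub


def rarefaction_exactness(seed: int, n_fixtures: int = 8) -> dict:
    """Max |AR_g - exhaustive subset enumeration| over small fixtures."""
    from .diversity import allelic_richness

    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for _ in range(n_fixtures):
        n_genes = int(rng.integers(6, 11))
        if n_genes % 2:
            n_genes += 1
        k = int(rng.integers(2, 5))
        genes = rng.integers(101, 101 + k, n_genes)
        data = _dataset_from_pops([genes, rng.integers(101, 101 + k, 8)])
        for g in range(2, n_genes + 1):
            res = allelic_richness(data, g, adjust_g=True)
            got = float(
                res.per_locus.query("population == 'P1'")["AR"].iloc[0]
            )
            g_eff = int(
                res.per_locus.query("population == 'P1'")["g"].iloc[0]
            )
            want = _exhaustive_ar(genes, g_eff)
            worst = max(worst, abs(got - want))
            n_checked += 1
    return {"max_abs_error": worst, "n_comparisons": n_checked}


# ---------------------------------------------------------------------------
# bottleneck calibration and power


def _equilibrium_dataset(n_ind: int, n_loci: int, theta: float,
                         rng: np.random.Generator) -> GenotypeDataset:
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        calls[:, li, :] = rng.permutation(sample_panmictic(
            2 * n_ind, theta, model="smm", rng=rng
        )).reshape(n_ind, 2)
    return GenotypeDataset(
        [f"i{j}" for j in range(n_ind)], ["pop1"] * n_ind,
        [f"L{li + 1:02d}" for li in range(n_loci)], calls,
    )


def _crashed_dataset(n_ind: int, n_loci: int, theta: float, crash_n: int,
                     crash_gens: int, mu: float,
                     rng: np.random.Generator) -> GenotypeDataset:
    """Equilibrium population put through a recent crash to ``crash_n``."""
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    q = _tpm_q(30.0)
    counter = [10_000_000]
    for li in range(n_loci):
        genes = sample_panmictic(2 * crash_n, theta, model="smm", rng=rng)
        for _ in range(crash_gens):
            genes = genes[rng.integers(0, genes.size, 2 * crash_n)]
            genes = _mutate_genes(genes, mu, "smm", 0.7, q, rng, counter)
        rows = rng.choice(crash_n, size=min(n_ind, crash_n), replace=False)
        calls[:, li, :] = genes.reshape(crash_n, 2)[rows]
    n_eff = min(n_ind, crash_n)
    return GenotypeDataset(
        [f"i{j}" for j in range(n_eff)], ["pop1"] * n_eff,
        [f"L{li + 1:02d}" for li in range(n_loci)], calls[:n_eff],
    )


def bottleneck_calibration(
    seed: int, n_datasets: int = 200, n_loci: int = 12, n_ind: int = 25,
    theta: float = 3.0, n_iter: int = 200, alpha: float = 0.05,
) -> dict:
    """Type-I rate at equilibrium and power after a 20-fold crash."""
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_datasets):
        data = _equilibrium_dataset(n_ind, n_loci, theta, rng)
        res = bottleneck_test(
            data, model="smm", n_iter=n_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
        p = res.per_population["p_excess"].iloc[0]
        if np.isfinite(p):
            tested += 1
            rejections += p < alpha
    type1 = rejections / tested if tested else np.nan

    # power: an N = 500 population (theta = 4) crashed 20-fold to N = 25
    # and sampled 15 generations later, inside the transient-excess window
    rej_p = 0
    tested_p = 0
    for _ in range(n_datasets):
        data = _crashed_dataset(
            n_ind, n_loci, theta=4.0, crash_n=25, crash_gens=15,
            mu=4.0 / (4 * 500), rng=rng,
        )
        res = bottleneck_test(
            data, model="smm", n_iter=n_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
        p = res.per_population["p_excess"].iloc[0]
        if np.isfinite(p):
            tested_p += 1
            rej_p += p < alpha
    power = rej_p / tested_p if tested_p else np.nan
    return {"type1_rate": float(type1), "power": float(power),
            "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# N_eb recovery


def neb_recovery(seed: int, n_rep: int = 200, n_pairs: int = 10,
                 n_offspring: int = 30) -> dict:
    """Median coancestry N_eb across simulated cohorts; truth = 2*n_pairs."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_rep):
        ds = simulate_breeding_cohort(
            n_pairs, n_offspring, n_loci=14, theta=10.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        vals.append(coancestry_neb(ds).table["N_eb"].iloc[0])
    vals = np.array(vals, dtype=float)
    finite = vals[np.isfinite(vals)]
    # large random-mating population: the infinite flag must engage
    from .simulate import simulate_equilibrium_population

    big = simulate_equilibrium_population(
        60, 12, 5e-4, "smm", N=800, seed=seed, burnin_factor=0
    )
    inf_flag = bool(coancestry_neb(big).table["infinite"].iloc[0])
    return {
        "median_neb": float(np.median(vals)),
        "truth": 2 * n_pairs,
        "relative_error": float(abs(np.median(vals) - 2 * n_pairs)
                                / (2 * n_pairs)),
        "infinite_flag_large_pop": inf_flag,
        "n_finite": int(finite.size),
    }


# ---------------------------------------------------------------------------
# envelope end-to-end


def envelope_experiment(
    seed: int, n_rep: int = 100, scale: float = 0.1, s: float = 0.05,
) -> dict:
    """Fractions of island-mainland candidate classifications by class.

    Runs the island-mainland scenario ``n_rep`` times at selection
    coefficient ``s`` and classifies the candidate locus against the
    neutral Jost's-D envelope for every island-mainland pair.
    """
    rng = np.random.default_rng(seed)
    mainland = {"QCN_LAB", "QCS_NB"}
    counts = {"above": 0, "within": 0, "below": 0, "NA": 0}
    n_pairs = 0
    for _ in range(n_rep):
        sc = lynx_default_scenario(
            seed=int(rng.integers(2**31 - 1)), scale=scale, s=s
        )
        data, _ = simulate_scenario(sc, track_trajectories=False)
        neut = compute_differentiation(data, "jostd", n_boot=0)
        cand = compute_differentiation(
            data, "jostd", n_boot=0, loci=[data.candidate_locus],
            marker_set="candidate",
        )
        env = jostd_envelope(neut, cand)
        for _, row in env.table.iterrows():
            pair = {row["pop1"], row["pop2"]}
            if pair <= mainland or not (pair & mainland):
                continue  # keep island-mainland pairs only
            counts[row["classification"]] += 1
            n_pairs += 1
    return {
        "above_fraction": counts["above"] / n_pairs,
        "within_fraction": counts["within"] / n_pairs,
        "below_fraction": counts["below"] / n_pairs,
        "n_pairs": n_pairs,
        "s": s,
    }


# ---------------------------------------------------------------------------
# fdist self-consistency


def fdist_selfconsistency(
    seed: int, n_obs_loci: int = 200, n_sim: int = 5000,
    n_pops: int = 4, genes_per_deme: int = 40, M: float = 11.0,
    theta: float = 1.0, conf: float = 0.95,
) -> dict:
    """False-positive rate of the outlier scan on self-simulated data."""
    rng = np.random.default_rng(seed)
    individuals, populations = [], []
    calls = np.empty(
        (n_pops * genes_per_deme // 2, n_obs_loci, 2), dtype=np.int64
    )
    for li in range(n_obs_loci):
        demes = sample_island(
            n_pops, genes_per_deme, M, theta, model="smm", rng=rng
        )
        calls[:, li, :] = np.concatenate(demes).reshape(-1, 2)
    n_per = genes_per_deme // 2
    for pi in range(n_pops):
        for j in range(n_per):
            individuals.append(f"p{pi}_{j}")
            populations.append(f"P{pi + 1}")
    data = GenotypeDataset(
        individuals, populations,
        [f"L{li + 1:03d}" for li in range(n_obs_loci)], calls,
    )
    res = fdist_scan(
        data, n_sim=n_sim, conf=conf, mutation_model="smm",
        seed=int(rng.integers(2**31 - 1)), bisect_batch=200,
        genes_per_deme=genes_per_deme,
    )
    v = res.verdicts.dropna(subset=["fst"])
    flagged = float((v["verdict"] != "neutral").mean())
    return {"flagged_fraction": flagged, "n_loci": int(len(v)),
            "conf": conf, "n_sim": n_sim}
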