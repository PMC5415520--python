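"""Selection evidence at the candidate functional locus.

Allele-frequency contrasts between clusters, the Jost's-D neutral-envelope
outlier test (candidate-locus D compared against the mean +/- SEM band of
the neutral loci, per population pair), and a simplified FDist-style
F_ST-vs-heterozygosity coalescent outlier scan with a trimmed neutral mean
and bisection-fitted migration parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .coalescent import sample_island
from .differentiation import (
    PairwiseStatResult, mc_fisher_pvalue, theta_components,
)
from .io import AlleleFrequencyTable, GenotypeDataset


# ---------------------------------------------------------------------------
# candidate-locus allele-frequency contrasts


def candidate_frequency_contrast(
    freqs: AlleleFrequencyTable, candidate: str, n_mc: int = 2000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Monte-Carlo exact tests on candidate-locus allele counts.

    Returns (pairwise p table, per-population frequency table including the
    modal allele and its frequency).
    """
    rng = np.random.default_rng(seed)
    pops = [p for p in freqs.populations if not freqs.is_empty(p, candidate)]
    if len(pops) < 2:
        raise ValueError("candidate locus scored in < 2 populations")
    alleles = freqs.alleles(candidate)
    rows = []
    for p1, p2 in combinations(freqs.populations, 2):
        if freqs.is_empty(p1, candidate) or freqs.is_empty(p2, candidate):
            rows.append({"pop1": p1, "pop2": p2, "p": np.nan})
            continue
        c1 = np.array([freqs.counts[(p1, candidate)].get(a, 0) for a in alleles])
        c2 = np.array([freqs.counts[(p2, candidate)].get(a, 0) for a in alleles])
        keep = (c1 + c2) > 0
        p = mc_fisher_pvalue(c1[keep], c2[keep], n_mc, rng)
        rows.append({"pop1": p1, "pop2": p2, "p": p})
    freq_rows = []
    for pop in pops:
        f = freqs.frequencies(pop, candidate)
        modal = max(f, key=f.get)
        for a in alleles:
            freq_rows.append(
                {"population": pop, "allele": a, "frequency": f.get(a, 0.0),
                 "n_genes": freqs.gene_count(pop, candidate),
                 "modal_allele": modal, "modal_frequency": f[modal]}
            )
    return pd.DataFrame(rows), pd.DataFrame(freq_rows)


# ---------------------------------------------------------------------------
# Jost's-D neutral envelope


@dataclass
class EnvelopeVerdict:
    """Per-pair neutral mean +/- SEM of Jost's D vs the candidate value."""

    table: pd.DataFrame  # pop1, pop2, D_neutral_mean, sem, n_loci,
    #                      D_candidate, classification
    z: float = 1.0


def jostd_envelope(
    neutral: PairwiseStatResult, candidate: PairwiseStatResult,
    z: float = 1.0,
) -> EnvelopeVerdict:
    """Classify the candidate locus against the neutral Jost's-D band.

    For each population pair, the mean and standard error of the mean of
    the per-locus neutral D values define the neutrality band (mean +/-
    z*SEM, z = 1 by default, the band as drawn); the candidate locus's
    single-locus D is classified above/within/below it.
    """
    pairs = set(map(frozenset, neutral.pairs()))
    cpairs = set(map(frozenset, candidate.pairs()))
    if pairs != cpairs:
        raise ValueError("neutral and candidate results cover different pairs")
    rows = []
    for p1, p2 in neutral.pairs():
        vals = neutral.per_locus_values(p1, p2).dropna()
        if len(vals) < 2:
            raise ValueError(
                f"SEM undefined with {len(vals)} neutral locus value(s) "
                f"for pair ({p1}, {p2})"
            )
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        d_cand = candidate.get(p1, p2)
        if not np.isfinite(d_cand):
            cls = "NA"
        elif d_cand > mean + z * sem:
            cls = "above"
        elif d_cand < mean - z * sem:
            cls = "below"
        else:
            cls = "within"
        rows.append({"pop1": p1, "pop2": p2, "D_neutral_mean": mean,
                     "sem": sem, "n_loci": len(vals),
                     "D_candidate": d_cand, "classification": cls})
    return EnvelopeVerdict(pd.DataFrame(rows), z)


# ---------------------------------------------------------------------------
# FDist-style outlier scan


@dataclass
class FdistEnvelope:
    """Simulated (heterozygosity, F_ST) cloud with conditional envelopes."""

    cloud: pd.DataFrame       # het, fst for each simulated locus
    verdicts: pd.DataFrame    # locus, het, fst, lower, upper, verdict
    target_fst: float
    fitted_M: float
    bisection_trace: list = field(default_factory=list)
    conf: float = 0.95
    n_sim: int = 0


def _locus_het_fst(gs: list[np.ndarray]) -> tuple[float, float]:
    """(mean within-population gene diversity, W&C theta) for one locus."""
    hets = []
    for g in gs:
        genes = g.ravel()
        n = genes.size
        if n < 2:
            continue
        _, counts = np.unique(genes, return_counts=True)
        h = 1.0 - float(np.sum((counts / n) ** 2))
        hets.append(n / (n - 1) * h)
    a, abc = theta_components(gs)
    fst = a / abc if (np.isfinite(a) and abc != 0) else np.nan
    return (float(np.mean(hets)) if hets else np.nan, fst)


def _genes_to_genotypes(states: np.ndarray) -> np.ndarray:
    return states.reshape(-1, 2)


def _simulate_cloud(
    n_loci: int, n_pops: int, genes_per_deme: int, M: float,
    n_demes: int, model: str, rng: np.random.Generator,
    theta_range: tuple[float, float] = (0.05, 20.0),
) -> pd.DataFrame:
    rows = []
    log_lo, log_hi = np.log(theta_range[0]), np.log(theta_range[1])
    for _ in range(n_loci):
        theta = float(np.exp(rng.uniform(log_lo, log_hi)))
        demes = sample_island(
            n_pops, genes_per_deme, M, theta, n_demes=n_demes, model=model,
            rng=rng,
        )
        gs = [_genes_to_genotypes(d) for d in demes]
        het, fst = _locus_het_fst(gs)
        if np.isfinite(fst):
            rows.append({"het": het, "fst": fst})
    return pd.DataFrame(rows)


def _mean_fst(df: pd.DataFrame) -> float:
    return float(df["fst"].mean())


def _conditional_band(
    cloud: pd.DataFrame, het: float, conf: float, k: int,
) -> tuple[float, float]:
    """Empirical conf-level quantile band of F_ST among the k simulated
    loci nearest in heterozygosity."""
    order = (cloud["het"] - het).abs().to_numpy().argsort()[:k]
    fst = cloud["fst"].to_numpy()[order]
    lo = float(np.quantile(fst, (1 - conf) / 2))
    hi = float(np.quantile(fst, (1 + conf) / 2))
    return lo, hi


def observed_locus_stats(
    data: GenotypeDataset, loci: list[str] | None = None,
) -> pd.DataFrame:
    """Observed per-locus (het, theta) across all populations."""
    if loci is None:
        loci = list(data.loci)
    pops = data.population_names()
    rows = []
    for locus in loci:
        gs = [data.pop_calls(p, locus) for p in pops]
        gs = [g for g in gs if len(g)]
        het, fst = _locus_het_fst(gs)
        rows.append({"locus": locus, "het": het, "fst": fst})
    return pd.DataFrame(rows)


def fdist_scan(
    data: GenotypeDataset, n_sim: int = 50000, conf: float = 0.95,
    mutation_model: str = "smm", seed: int | None = None,
    n_demes: int = 100, trim_iterations: int = 1,
    loci: list[str] | None = None, bisect_batch: int = 400,
    bisect_tol: float = 0.004, genes_per_deme: int | None = None,
) -> FdistEnvelope:
    """Coalescent F_ST-outlier scan with forced neutral mean.

    Mirrors the FDist workflow: (i) a trimmed "neutral" mean F_ST is
    obtained by one round of provisional outlier removal; (ii) the scaled
    migration rate M of a ``n_demes``-island model is fitted by bisection
    so the simulated mean F_ST matches the target; (iii) ``n_sim`` neutral
    loci simulated under that model yield conditional quantile envelopes of
    F_ST given heterozygosity; (iv) observed loci outside the envelope are
    flagged (above: positive-selection candidate; below: balancing
    candidate).
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    pops = data.population_names()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    obs = observed_locus_stats(data, loci)
    obs_ok = obs.dropna(subset=["fst"])
    if genes_per_deme is None:
        # representative sample size: median individuals per population
        med = int(np.median([
            sum(p == q for q in data.populations) for p in pops
        ]))
        genes_per_deme = max(2 * med, 4)

    trace: list[dict] = []

    def fit_M(target: float, n_batch: int) -> float:
        # initial guess from the finite-island closed form
        corr = (n_demes / (n_demes - 1)) ** 2
        target = min(max(target, 1e-3), 0.95)
        M0 = (1.0 / target - 1.0) / corr
        lo, hi = M0 / 16, M0 * 16
        for it in range(12):
            mid = float(np.sqrt(lo * hi))
            cloud = _simulate_cloud(
                n_batch, len(pops), genes_per_deme, mid, n_demes,
                mutation_model, rng,
            )
            m = _mean_fst(cloud)
            trace.append({"iteration": it, "M": mid, "mean_fst": m,
                          "target": target})
            if abs(m - target) < bisect_tol:
                return mid
            if m > target:
                lo = mid  # too little migration -> raise M
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    neutral_mask = np.ones(len(obs_ok), dtype=bool)
    target = float(np.mean(obs_ok["fst"]))
    M_fit = fit_M(target, bisect_batch)
    for _ in range(trim_iterations):
        # provisional envelope from a modest cloud; drop outliers; refit
        cloud = _simulate_cloud(
            max(2000, n_sim // 5), len(pops), genes_per_deme, M_fit,
            n_demes, mutation_model, rng,
        )
        k = max(100, len(cloud) // 20)
        for i, (_, row) in enumerate(obs_ok.iterrows()):
            lo, hi = _conditional_band(cloud, row["het"], conf, k)
            neutral_mask[i] = lo <= row["fst"] <= hi
        if neutral_mask.sum() >= 2:
            target = float(np.mean(obs_ok["fst"].to_numpy()[neutral_mask]))
        M_fit = fit_M(target, bisect_batch)

    cloud = _simulate_cloud(
        n_sim, len(pops), genes_per_deme, M_fit, n_demes, mutation_model,
        rng,
    )
    k = max(250, len(cloud) // 20)
    verdict_rows = []
    for _, row in obs.iterrows():
        if not np.isfinite(row["fst"]):
            verdict_rows.append({**row, "lower": np.nan, "upper": np.nan,
                                 "verdict": "NA"})
            continue
        lo, hi = _conditional_band(cloud, row["het"], conf, k)
        if row["fst"] > hi:
            verdict = "positive-selection candidate"
        elif row["fst"] < lo:
            verdict = "balancing candidate"
        else:
            verdict = "neutral"
        verdict_rows.append({**row, "lower": lo, "upper": hi,
                             "verdict": verdict})
    return FdistEnvelope(
        cloud, pd.DataFrame(verdict_rows), target, M_fit, trace, conf, n_sim
    )


# ---------------------------------------------------------------------------
# admixture assignment rule


def admixture_assignment(
    q_matrix: np.ndarray | pd.DataFrame, labels: list[str] | None = None,
    threshold: float = 0.5,
) -> list[str]:
    """Assign individuals to the cluster holding > 50% of their ancestry.

    Rows are per-individual ancestry proportions (must sum to 1); rows with
    no cluster above the threshold are 'unassigned'.
    """
    if isinstance(q_matrix, pd.DataFrame):
        labels = labels or [str(c) for c in q_matrix.columns]
        q = q_matrix.to_numpy(dtype=float)
    else:
        q = np.asarray(q_matrix, dtype=float)
        labels = labels or [f"cluster{i + 1}" for i in range(q.shape[1])]
    if q.ndim != 2:
        raise ValueError("q_matrix must be 2-dimensional")
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(q < 0):
        raise ValueError("ancestry rows must be non-negative and sum to 1")
    out = []
    for row in q:
        j = int(np.argmax(row))
        out.append(labels[j] if row[j] > threshold else "unassigned")
    return out
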