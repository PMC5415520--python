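"""Pairwise and global genetic differentiation.

Weir & Cockerham's theta (variance-components F_ST), Nei's G_ST with the
Nei-Chesser sample-size corrections, and Jost's D, each with per-locus
values, multilocus combinations and percentile bootstrap CIs; Monte-Carlo
genotypic exact tests between population pairs; and the per-locus
mean-allele-number diagnostic regression used to judge mutation-rate bias.

Negative estimates are reported as computed, never truncated to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset

STATISTICS = ("theta", "gst", "jostd")

#: floor applied to non-positive per-locus Jost's D values inside the
#: harmonic-mean combination only (the per-locus values themselves are
#: reported untruncated).
HARMONIC_EPS = 1e-4


@dataclass
class PairwiseStatResult:
    """Symmetric population-pair matrix for one differentiation statistic."""

    statistic: str
    populations: list[str]
    estimates: dict  # frozenset({p1,p2}) -> multilocus estimate
    per_locus: pd.DataFrame  # columns: pop1, pop2, locus, value
    ci: dict = field(default_factory=dict)  # pair -> (low, high)
    n_boot: int = 0
    marker_set: str = "neutral"

    def pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.populations, 2))

    def get(self, p1: str, p2: str) -> float:
        return self.estimates[frozenset((p1, p2))]

    def matrix(self) -> pd.DataFrame:
        pops = self.populations
        m = pd.DataFrame(np.nan, index=pops, columns=pops)
        for (p1, p2) in self.pairs():
            v = self.get(p1, p2)
            m.loc[p1, p2] = v
            m.loc[p2, p1] = v
        return m

    def per_locus_values(self, p1: str, p2: str) -> pd.Series:
        df = self.per_locus
        sel = df[((df.pop1 == p1) & (df.pop2 == p2))
                 | ((df.pop1 == p2) & (df.pop2 == p1))]
        return sel.set_index("locus")["value"]


# ---------------------------------------------------------------------------
# per-locus estimator cores (operate on lists of genotype matrices)


def _allele_stats(gs: list[np.ndarray]):
    """Shared per-pair/per-locus tallies.

    ``gs``: one (n_i, 2) valid-call genotype matrix per population.
    Returns (alleles, n_i array, freq matrix [pop x allele], het-freq matrix).
    """
    alleles = np.unique(np.concatenate([g.ravel() for g in gs]))
    r = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    p = np.zeros((r, len(alleles)))
    h = np.zeros((r, len(alleles)))
    for i, g in enumerate(gs):
        if len(g) == 0:
            continue
        for j, a in enumerate(alleles):
            p[i, j] = np.sum(g == a) / (2 * len(g))
            h[i, j] = np.mean((g[:, 0] == a) ^ (g[:, 1] == a))
    return alleles, n, p, h


def theta_components(gs: list[np.ndarray]) -> tuple[float, float]:
    """Weir-Cockerham (1984) variance components summed over alleles.

    Returns (sum_a, sum_abc) for one locus; the multilocus estimator is the
    ratio of these sums accumulated over loci.
    """
    gs = [g for g in gs if len(g) > 0]
    r = len(gs)
    if r < 2:
        return (np.nan, np.nan)
    alleles, n, p, h = _allele_stats(gs)
    nbar = n.mean()
    if nbar <= 1:
        return (np.nan, np.nan)
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return (np.nan, np.nan)
    suma = sumabc = 0.0
    for j in range(len(alleles)):
        pbar = float(np.sum(n * p[:, j]) / (r * nbar))
        s2 = float(np.sum(n * (p[:, j] - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h[:, j]) / (r * nbar))
        a = (nbar / nc) * (
            s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        suma += a
        sumabc += a + b + c
    return suma, sumabc


def nei_chesser_hs_ht(gs: list[np.ndarray]) -> tuple[float, float]:
    """Nei & Chesser (1983) unbiased H_S and H_T for one locus."""
    gs = [g for g in gs if len(g) > 0]
    r = len(gs)
    if r < 2:
        return (np.nan, np.nan)
    alleles, n, p, h = _allele_stats(gs)
    ntilde = r / np.sum(1.0 / n)  # harmonic mean sample size
    ho = float(np.mean([np.mean(g[:, 0] != g[:, 1]) for g in gs]))
    xbar = float(np.mean(np.sum(p**2, axis=1)))
    hs = ntilde / (ntilde - 1) * (1 - xbar - ho / (2 * ntilde))
    pbar = p.mean(axis=0)
    ht = 1 - float(np.sum(pbar**2)) + hs / (ntilde * r) - ho / (2 * ntilde * r)
    return hs, ht


def jost_d_locus(gs: list[np.ndarray]) -> float:
    """Jost's D for one locus: (r/(r-1)) (H_T - H_S)/(1 - H_S)."""
    r = len([g for g in gs if len(g) > 0])
    hs, ht = nei_chesser_hs_ht(gs)
    if not np.isfinite(hs) or hs >= 1.0:
        return np.nan
    return (r / (r - 1)) * (ht - hs) / (1 - hs)


def _harmonic_mean_d(values: np.ndarray, eps: float = HARMONIC_EPS) -> float:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return np.nan
    v = np.where(v <= eps, eps, v)
    return float(v.size / np.sum(1.0 / v))


def multilocus_estimate(
    gs_by_locus: list[list[np.ndarray]], statistic: str,
    d_combine: str = "harmonic",
) -> float:
    """Combine per-locus data into one multilocus estimate."""
    if statistic == "theta":
        num = den = 0.0
        for gs in gs_by_locus:
            a, abc = theta_components(gs)
            if np.isfinite(a):
                num += a
                den += abc
        return num / den if den != 0 else np.nan
    if statistic == "gst":
        hs_list, ht_list = [], []
        for gs in gs_by_locus:
            hs, ht = nei_chesser_hs_ht(gs)
            if np.isfinite(hs):
                hs_list.append(hs)
                ht_list.append(ht)
        if not hs_list:
            return np.nan
        hsm, htm = float(np.mean(hs_list)), float(np.mean(ht_list))
        return (htm - hsm) / htm if htm != 0 else np.nan
    if statistic == "jostd":
        d = np.array([jost_d_locus(gs) for gs in gs_by_locus])
        if d_combine == "harmonic":
            return _harmonic_mean_d(d)
        return float(np.nanmean(d)) if np.isfinite(d).any() else np.nan
    raise ValueError(f"unknown statistic {statistic!r}")


def per_locus_estimate(gs: list[np.ndarray], statistic: str) -> float:
    if statistic == "theta":
        a, abc = theta_components(gs)
        return a / abc if (np.isfinite(a) and abc != 0) else np.nan
    if statistic == "gst":
        hs, ht = nei_chesser_hs_ht(gs)
        return (ht - hs) / ht if (np.isfinite(ht) and ht != 0) else np.nan
    if statistic == "jostd":
        return jost_d_locus(gs)
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# public API


def _collect_calls(data: GenotypeDataset, pops: list[str], loci: list[str]):
    """dict (pop -> list over loci of (n_i, 2) valid-call matrices)."""
    out = {}
    poparr = np.asarray(data.populations)
    for pop in pops:
        rows = np.flatnonzero(poparr == pop)
        per_locus = []
        for locus in loci:
            li = data.locus_index(locus)
            g = data.calls[rows][:, li, :]
            per_locus.append(g[(g != MISSING).all(axis=1)])
        out[pop] = per_locus
    return out


def compute_differentiation(
    data: GenotypeDataset, statistic: str = "theta", n_boot: int = 999,
    seed: int | None = None, loci: list[str] | None = None,
    marker_set: str = "neutral", boot_unit: str = "individuals",
    d_combine: str = "harmonic", global_estimate: bool = False,
) -> PairwiseStatResult:
    """Pairwise multilocus differentiation with percentile bootstrap CIs.

    By default the neutral loci are used; pass ``loci=[candidate]`` and
    ``marker_set='candidate'`` for the single-locus candidate analysis (the
    candidate locus is never pooled with neutral loci).  The default
    bootstrap resamples individuals within populations, keeping loci fixed;
    ``boot_unit='loci'`` resamples loci instead.  ``n_boot=0`` skips CIs.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    pops = data.population_names()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if loci is None:
        loci = data.neutral_loci() if marker_set == "neutral" else list(data.loci)
    rng = np.random.default_rng(seed)
    calls = _collect_calls(data, pops, loci)

    estimates: dict = {}
    ci: dict = {}
    rows = []
    pair_list = (
        [tuple(pops)] if global_estimate else list(combinations(pops, 2))
    )
    for pair in pair_list:
        gs_by_locus = [
            [calls[p][li] for p in pair] for li in range(len(loci))
        ]
        if all(all(len(g) == 0 for g in gs) for gs in gs_by_locus):
            estimates[frozenset(pair)] = np.nan
            continue
        est = multilocus_estimate(gs_by_locus, statistic, d_combine)
        estimates[frozenset(pair)] = est
        for li, locus in enumerate(loci):
            rows.append({"pop1": pair[0], "pop2": pair[-1], "locus": locus,
                         "value": per_locus_estimate(gs_by_locus[li], statistic)})
        if n_boot > 0:
            reps = np.empty(n_boot)
            for r in range(n_boot):
                if boot_unit == "individuals":
                    res = []
                    for li in range(len(loci)):
                        gs = []
                        for p in pair:
                            g = calls[p][li]
                            if len(g):
                                idx = rng.integers(0, len(g), len(g))
                                gs.append(g[idx])
                            else:
                                gs.append(g)
                        res.append(gs)
                elif boot_unit == "loci":
                    pick = rng.integers(0, len(loci), len(loci))
                    res = [gs_by_locus[i] for i in pick]
                else:
                    raise ValueError("boot_unit must be 'individuals' or 'loci'")
                reps[r] = multilocus_estimate(res, statistic, d_combine)
            reps = reps[np.isfinite(reps)]
            if reps.size:
                ci[frozenset(pair)] = tuple(np.percentile(reps, [2.5, 97.5]))
    return PairwiseStatResult(
        statistic, pops, estimates, pd.DataFrame(rows), ci, n_boot, marker_set
    )


# ---------------------------------------------------------------------------
# genotypic exact tests


def _log_table_prob(table: np.ndarray) -> float:
    """log multivariate hypergeometric probability of an r x 2 table."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    lp = -math.lgamma(n + 1)
    lp += sum(math.lgamma(x + 1) for x in row)
    lp += sum(math.lgamma(x + 1) for x in col)
    lp -= sum(math.lgamma(x + 1) for x in table.ravel())
    return lp


def mc_fisher_pvalue(
    counts1: np.ndarray, counts2: np.ndarray, n_mc: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo Fisher exact p for a categories x 2 count table.

    Null tables are drawn by permuting category labels conditional on the
    margins; the rejection region orders tables by hypergeometric
    probability (smaller-or-equal probability than observed counts as
    extreme).
    """
    obs = np.column_stack([counts1, counts2]).astype(int)
    lp_obs = _log_table_prob(obs)
    items = np.repeat(np.arange(len(counts1)), counts1 + counts2)
    n1 = int(counts1.sum())
    k = len(counts1)
    le = 1
    for _ in range(n_mc):
        rng.shuffle(items)
        c1 = np.bincount(items[:n1], minlength=k)
        tab = np.column_stack([c1, counts1 + counts2 - c1])
        if _log_table_prob(tab) <= lp_obs + 1e-9:
            le += 1
    return le / (n_mc + 1)


def genotypic_exact_test(
    data: GenotypeDataset, n_mc: int = 2000, alpha: float = 0.001,
    seed: int | None = None, loci: list[str] | None = None,
) -> pd.DataFrame:
    """Per-pair genotypic differentiation by Monte-Carlo Fisher exact tests.

    Per locus the genotype-count x population-pair table is tested; loci
    monomorphic across the pair are excluded; per-pair global p-values
    combine loci with Fisher's method.
    """
    if n_mc < 99:
        raise ValueError("n_mc must be >= 99")
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = data.neutral_loci()
    pops = data.population_names()
    rows = []
    for p1, p2 in combinations(pops, 2):
        pvals = []
        for locus in loci:
            g1, g2 = data.pop_calls(p1, locus), data.pop_calls(p2, locus)
            if len(g1) == 0 or len(g2) == 0:
                continue
            both = np.sort(np.vstack([g1, g2]), axis=1)
            cats, codes = np.unique(both, axis=0, return_inverse=True)
            if len(cats) < 2:
                continue  # monomorphic across the pair
            c1 = np.bincount(codes[: len(g1)], minlength=len(cats))
            c2 = np.bincount(codes[len(g1):], minlength=len(cats))
            pvals.append(mc_fisher_pvalue(c1, c2, n_mc, rng))
        if pvals:
            chi2 = -2.0 * np.sum(np.log(pvals))
            global_p = float(stats.chi2.sf(chi2, 2 * len(pvals)))
        else:
            global_p = np.nan
        rows.append({"pop1": p1, "pop2": p2, "p": global_p,
                     "n_loci": len(pvals), "significant": global_p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mean allele number vs differentiation diagnostic


def allele_count_vs_diff(
    data: GenotypeDataset, result: PairwiseStatResult,
) -> tuple[pd.DataFrame, dict]:
    """Per-locus (mean allele number, global statistic) pairs and OLS fit.

    A positive slope indicates that high-mutation-rate (allele-rich) loci
    are not deflating the differentiation estimates.
    """
    loci = sorted(set(result.per_locus["locus"]), key=data.loci.index)
    mean_alleles = []
    for locus in loci:
        counts = []
        for pop in data.population_names():
            g = data.pop_calls(pop, locus)
            if len(g):
                counts.append(len(np.unique(g.ravel())))
        mean_alleles.append(np.mean(counts) if counts else np.nan)
    per_locus_stat = (
        result.per_locus.groupby("locus", sort=False)["value"].mean()
        .reindex(loci)
    )
    table = pd.DataFrame(
        {"locus": loci, "mean_alleles": mean_alleles,
         "value": per_locus_stat.to_numpy()}
    ).dropna()
    if len(table) < 3:
        return table, {"slope": np.nan, "r2": np.nan, "p": np.nan}
    if np.allclose(table["value"].var(), 0.0):
        return table, {"slope": 0.0, "r2": 0.0, "p": 1.0}
    if np.allclose(table["mean_alleles"].var(), 0.0):
        return table, {"slope": np.nan, "r2": np.nan, "p": np.nan}
    fit = stats.linregress(table["mean_alleles"], table["value"])
    return table, {"slope": float(fit.slope), "r2": float(fit.rvalue**2),
                   "p": float(fit.pvalue)}
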