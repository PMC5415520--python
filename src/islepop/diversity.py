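"""Within-population diversity and disequilibrium screening.

Observed and unbiased expected heterozygosity, rarefied allelic richness and
private allelic richness (gene-copy rarefaction), Weir-Cockerham F_IS with a
bootstrap CI, chi-square Hardy-Weinberg tests and permutation G-tests of
linkage disequilibrium, both with Bonferroni correction over the tests
actually performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset, allele_frequencies


@dataclass
class DiversitySummary:
    """Tidy per-(population, locus) diversity statistics.

    ``per_locus`` columns: population, locus, n (valid individuals), H_O,
    H_E, allele_count, and optionally AR_g / private_AR_g at rarefaction
    size ``g`` gene copies.  ``per_population`` holds multilocus means.
    """

    per_locus: pd.DataFrame
    per_population: pd.DataFrame
    g: int | None = None
    fis: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# heterozygosity


def _pop_locus_stats(data: GenotypeDataset) -> list[dict]:
    rows = []
    for pop in data.population_names():
        for locus in data.loci:
            g = data.pop_calls(pop, locus)
            n = len(g)
            if n == 0:
                rows.append(
                    {"population": pop, "locus": locus, "n": 0,
                     "H_O": np.nan, "H_E": np.nan, "allele_count": 0}
                )
                continue
            ho = float(np.mean(g[:, 0] != g[:, 1]))
            alleles, counts = np.unique(g.ravel(), return_counts=True)
            p = counts / counts.sum()
            two_n = 2 * n
            he = two_n / (two_n - 1) * (1.0 - float(np.sum(p**2))) if two_n > 1 else np.nan
            rows.append(
                {"population": pop, "locus": locus, "n": n,
                 "H_O": ho, "H_E": he, "allele_count": len(alleles)}
            )
    return rows


def heterozygosity(data: GenotypeDataset) -> DiversitySummary:
    """Observed and Nei-unbiased expected heterozygosity per (pop, locus).

    H_O is the heterozygote fraction among valid calls; H_E is the unbiased
    estimator (2n/(2n-1)) (1 - sum p^2).  Entries with no valid calls are NaN.
    """
    per_locus = pd.DataFrame(_pop_locus_stats(data))
    per_pop = (
        per_locus.groupby("population", sort=False)[["H_O", "H_E", "allele_count"]]
        .mean()
        .reset_index()
    )
    return DiversitySummary(per_locus, per_pop)


def ho_he_ttest(summary: DiversitySummary, population: str | None = None):
    """Two-sided paired t-test of H_E vs H_O across loci.

    When ``population`` is None, loci values are first averaged across
    populations so the pairing unit is the locus.
    """
    df = summary.per_locus
    if population is not None:
        df = df[df["population"] == population]
    piv = df.groupby("locus", sort=False)[["H_O", "H_E"]].mean().dropna()
    if len(piv) < 2:
        raise ValueError("paired t-test needs >= 2 loci")
    d = piv["H_E"].to_numpy() - piv["H_O"].to_numpy()
    if np.allclose(d.std(ddof=1), 0.0):
        # degenerate: zero variance in differences
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return math.inf * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(piv["H_E"], piv["H_O"])
    return float(t), float(p)


# ---------------------------------------------------------------------------
# rarefied allelic richness


def _rarefaction_absent_prob(N: int, Ni: int, g: int) -> float:
    """P(allele with Ni of N gene copies absent from a g-subsample)."""
    if Ni == 0:
        return 1.0
    if N - Ni < g:
        return 0.0
    return math.comb(N - Ni, g) / math.comb(N, g)


def allelic_richness(
    data: GenotypeDataset, g: int, private: bool = False,
    adjust_g: bool = True,
) -> DiversitySummary:
    """Rarefied allelic richness (and optionally private allelic richness).

    AR_g at a locus is the expected number of distinct alleles in a random
    subsample of ``g`` gene copies; private AR_g is the expected number of
    alleles present in the focal population's g-sample but absent from every
    other population's g-sample (hypergeometric rarefaction).  When missing
    data leaves fewer than ``g`` gene copies at some (population, locus), the
    rarefaction size at that locus is reduced to the minimum available count
    if ``adjust_g``; otherwise an error names the offending cell.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    freqs = allele_frequencies(data)
    pops = freqs.populations
    rows = []
    for locus in data.loci:
        counts = {p: freqs.counts[(p, locus)] for p in pops}
        Ns = {p: sum(c.values()) for p, c in counts.items()}
        avail = [n for n in Ns.values() if n > 0]
        if not avail:
            for p in pops:
                rows.append({"population": p, "locus": locus, "g": g,
                             "AR": np.nan, "private_AR": np.nan})
            continue
        g_loc = g
        if min(avail) < g:
            if not adjust_g:
                bad = min(Ns, key=lambda p: Ns[p] if Ns[p] > 0 else 10**9)
                raise ValueError(
                    f"g={g} exceeds {Ns[bad]} gene copies at ({bad}, {locus})"
                )
            g_loc = min(avail)
        for p in pops:
            if Ns[p] == 0:
                rows.append({"population": p, "locus": locus, "g": g_loc,
                             "AR": np.nan, "private_AR": np.nan})
                continue
            ar = 0.0
            priv = 0.0
            for allele in freqs.alleles(locus):
                q_focal = _rarefaction_absent_prob(
                    Ns[p], counts[p].get(allele, 0), g_loc
                )
                ar += 1.0 - q_focal
                if private:
                    q_others = 1.0
                    for other in pops:
                        if other == p or Ns[other] == 0:
                            continue
                        q_others *= _rarefaction_absent_prob(
                            Ns[other], counts[other].get(allele, 0), g_loc
                        )
                    priv += (1.0 - q_focal) * q_others
            row = {"population": p, "locus": locus, "g": g_loc, "AR": ar}
            if private:
                row["private_AR"] = priv
            rows.append(row)
    per_locus = pd.DataFrame(rows)
    value_cols = ["AR"] + (["private_AR"] if private else [])
    per_pop = (
        per_locus.groupby("population", sort=False)[value_cols]
        .mean()
        .reset_index()
    )
    return DiversitySummary(per_locus, per_pop, g=g)


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham within-population f)


def _fis_components(data: GenotypeDataset, pop: str, loci: list[str]):
    """Per-locus Weir-Cockerham b and c sums for a single population."""
    out = {}
    for locus in loci:
        g = data.pop_calls(pop, locus)
        n = len(g)
        if n < 2:
            continue
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        if len(alleles) < 2:
            continue
        p = counts / (2 * n)
        b_sum = 0.0
        c_sum = 0.0
        for a, pa in zip(alleles, p):
            h = float(np.mean((g[:, 0] == a) ^ (g[:, 1] == a)))
            b = n / (n - 1) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * h)
            c = h / 2.0
            b_sum += b
            c_sum += c
        out[locus] = (b_sum, c_sum)
    return out


def f_is(
    data: GenotypeDataset, n_boot: int = 999, seed: int | None = None,
    population: str | None = None, boot_unit: str = "loci",
) -> pd.DataFrame:
    """Multilocus Weir-Cockerham F_IS per population with a percentile CI.

    f = 1 - sum(c) / sum(b + c) over loci.  The default bootstrap resamples
    loci with replacement (inter-locus variance); ``boot_unit='individuals'``
    resamples individuals within the population instead.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    pops = [population] if population else data.population_names()
    loci = data.neutral_loci()
    rows = []
    for pop in pops:
        comp = _fis_components(data, pop, loci)
        usable = list(comp)
        if not usable:
            rows.append({"population": pop, "F_IS": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "significant": False, "n_loci": 0})
            continue
        b = np.array([comp[l][0] for l in usable])
        c = np.array([comp[l][1] for l in usable])

        def estimate(bs, cs):
            denom = np.sum(bs + cs)
            if denom == 0:
                return np.nan
            return 1.0 - np.sum(cs) / denom

        point = estimate(b, c)
        reps = np.empty(n_boot)
        if boot_unit == "loci":
            for r in range(n_boot):
                idx = rng.integers(0, len(usable), len(usable))
                reps[r] = estimate(b[idx], c[idx])
        elif boot_unit == "individuals":
            sub = data.population_subset([pop])
            n = sub.n_individuals
            for r in range(n_boot):
                idx = rng.integers(0, n, n)
                rcomp = _fis_components(sub.subset_individuals(idx), pop, loci)
                if not rcomp:
                    reps[r] = np.nan
                    continue
                rb = np.array([v[0] for v in rcomp.values()])
                rc = np.array([v[1] for v in rcomp.values()])
                reps[r] = estimate(rb, rc)
        else:
            raise ValueError("boot_unit must be 'loci' or 'individuals'")
        reps = reps[~np.isnan(reps)]
        if reps.size:
            lo, hi = np.percentile(reps, [2.5, 97.5])
        else:
            lo = hi = np.nan
        rows.append({"population": pop, "F_IS": point,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "significant": bool(lo > 0 or hi < 0),
                     "n_loci": len(usable)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg chi-square


def hwe_chisq_single(g: np.ndarray) -> tuple[float, float, int]:
    """Chi-square HWE test on one (population, locus) genotype matrix.

    Returns (chi2, p, df) with df = k(k-1)/2 for k alleles, comparing
    observed genotype-class counts to n*p_i^2 / 2n*p_i*p_j expectations.
    """
    n = len(g)
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    k = len(alleles)
    if n == 0 or k < 2:
        return (np.nan, np.nan, 0)
    p = dict(zip(alleles.tolist(), (counts / (2 * n)).tolist()))
    gsort = np.sort(g, axis=1)
    chi2 = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            obs = int(np.sum((gsort[:, 0] == min(a, b)) & (gsort[:, 1] == max(a, b))))
            exp = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    df = k * (k - 1) // 2
    return float(chi2), float(stats.chi2.sf(chi2, df)), df


def hwe_test(data: GenotypeDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square HWE tests per (population, locus), Bonferroni corrected.

    The Bonferroni threshold divides ``alpha`` by the number of tests that
    could actually be performed (monomorphic / empty cells are NA and do not
    count).
    """
    rows = []
    for pop in data.population_names():
        for locus in data.loci:
            g = data.pop_calls(pop, locus)
            chi2, p, df = hwe_chisq_single(g)
            rows.append({"population": pop, "locus": locus,
                         "chi2": chi2, "df": df, "p": p})
    out = pd.DataFrame(rows)
    n_tests = int(out["p"].notna().sum())
    thr = alpha / n_tests if n_tests else np.nan
    out["bonferroni_threshold"] = thr
    out["significant"] = out["p"] < thr
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium (permutation G-test)


def _g_statistic(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        return 0.0
    total = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / exp[mask])))


def _genotype_codes(g: np.ndarray) -> np.ndarray:
    """Map unordered genotype rows to small integer categories."""
    gs = np.sort(g, axis=1)
    _, codes = np.unique(gs, axis=0, return_inverse=True)
    return codes


def ld_test(
    data: GenotypeDataset, n_perm: int = 999, alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise linkage-disequilibrium screen.

    Per population and locus pair, a G statistic on the two-locus genotype
    contingency table is compared with a permutation null built by shuffling
    one locus's genotypes among individuals; per-pair global p-values combine
    populations by Fisher's method, with Bonferroni over pairs.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    pops = data.population_names()
    pairs = list(combinations(data.loci, 2))
    percomb = []
    for l1, l2 in pairs:
        i1, i2 = data.locus_index(l1), data.locus_index(l2)
        pvals = []
        for pop in pops:
            rows = [i for i, p in enumerate(data.populations) if p == pop]
            g1 = data.calls[rows, i1, :]
            g2 = data.calls[rows, i2, :]
            ok = (g1 != MISSING).all(axis=1) & (g2 != MISSING).all(axis=1)
            g1, g2 = g1[ok], g2[ok]
            if len(g1) < 2:
                continue
            c1, c2 = _genotype_codes(g1), _genotype_codes(g2)
            k1, k2 = c1.max() + 1, c2.max() + 1
            if k1 < 2 or k2 < 2:
                continue
            obs_tab = np.zeros((k1, k2))
            np.add.at(obs_tab, (c1, c2), 1)
            g_obs = _g_statistic(obs_tab)
            ge = 1
            for _ in range(n_perm):
                perm = rng.permutation(c2)
                tab = np.zeros((k1, k2))
                np.add.at(tab, (c1, perm), 1)
                if _g_statistic(tab) >= g_obs - 1e-12:
                    ge += 1
            pvals.append(ge / (n_perm + 1))
        if pvals:
            chi2 = -2.0 * np.sum(np.log(pvals))
            global_p = float(stats.chi2.sf(chi2, 2 * len(pvals)))
        else:
            global_p = np.nan
        percomb.append({"locus1": l1, "locus2": l2, "p": global_p,
                        "n_pops_tested": len(pvals)})
    out = pd.DataFrame(percomb)
    n_tests = int(out["p"].notna().sum())
    thr = alpha / n_tests if n_tests else np.nan
    out["bonferroni_threshold"] = thr
    out["significant"] = out["p"] < thr
    return out
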