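"""Drift diagnostics: effective number of breeders, bottleneck test, and the
differentiation-on-diversity regression.

Three complementary lines of evidence for genetic drift in small isolated
populations:

* ``coancestry_neb`` — effective number of breeders from molecular
  coancestry (allele sharing between individuals), with an infinite flag
  for large populations;
* ``bottleneck_test`` — transient heterozygosity excess relative to the
  mutation-drift-equilibrium expectation given the observed allele count
  (one-tailed Wilcoxon signed-rank across loci);
* ``drift_regression`` — pairwise differentiation regressed on the pair's
  average within-population diversity; a negative slope is the classic
  drift signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coalescent import equilibrium_het_given_k
from .differentiation import PairwiseStatResult
from .io import GenotypeDataset


# ---------------------------------------------------------------------------
# molecular coancestry N_eb

#: estimates above this ceiling are reported as infinite
NE_CEILING_DEFAULT = 5000.0


@dataclass
class NeEstimate:
    """Per-population effective-number-of-breeders estimates."""

    table: pd.DataFrame  # population, f1, N_eb, ci_low, ci_high, infinite


def _identity_sums(g: np.ndarray) -> tuple[float, float, float, float]:
    """Between- and within-individual gene-identity sums for one locus.

    ``g``: (n, 2) valid diploid calls.  Returns (Q_b, w_b, Q_w, w_w):
    mean identity of two gene copies drawn from different individuals /
    from the same individual, with their pair counts as weights.
    """
    n = len(g)
    if n < 2:
        return (np.nan, 0.0, np.nan, 0.0)
    genes = g.ravel()
    vals, counts = np.unique(genes, return_counts=True)
    two_n = 2 * n
    total_ordered_same = float(np.sum(counts * (counts - 1)))  # distinct gene pairs
    within_same = float(2 * np.sum(g[:, 0] == g[:, 1]))  # ordered within-ind pairs
    between_same = total_ordered_same - within_same
    n_between = two_n * (two_n - 2)  # ordered cross-individual gene pairs
    q_b = between_same / n_between
    q_w = within_same / (2 * n)
    return q_b, float(n_between), q_w, float(2 * n)


def coancestry_neb(
    data: GenotypeDataset, seed: int | None = None,
    ceiling: float = NE_CEILING_DEFAULT, loci: list[str] | None = None,
) -> NeEstimate:
    """Effective number of breeders from molecular coancestry.

    For each locus the mean gene identity between individuals (Q_b) is
    contrasted with the within-individual identity (Q_w, the reference for
    the parental gene pool of a non-inbred cohort); the corrected mean
    coancestry f1 = sum_l (Q_b - Q_w) / sum_l (1 - Q_w) estimates the
    average kinship of the cohort, and N_eb = 1 / (2 f1).  Following the
    NeEstimator convention, f1 <= 0 (or an estimate above ``ceiling``) is
    reported as infinite.  The 95% CI comes from a delete-one jackknife
    over loci.
    """
    if loci is None:
        loci = data.neutral_loci()
    rows = []
    for pop in data.population_names():
        sub = data.population_subset([pop])
        if sub.n_individuals < 2:
            rows.append({"population": pop, "f1": np.nan, "N_eb": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "infinite": False, "n_loci": 0})
            continue
        num, den = [], []
        for locus in loci:
            g = sub.pop_calls(pop, locus)
            q_b, w_b, q_w, _ = _identity_sums(g)
            if not np.isfinite(q_b) or (1 - q_w) <= 0:
                continue
            num.append(w_b * (q_b - q_w))
            den.append(w_b * (1 - q_w))
        num, den = np.array(num), np.array(den)
        if den.size == 0 or den.sum() <= 0:
            rows.append({"population": pop, "f1": np.nan, "N_eb": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "infinite": False, "n_loci": 0})
            continue
        f1 = float(num.sum() / den.sum())

        def neb_of(f: float) -> float:
            if f <= 0:
                return np.inf
            nb = 1.0 / (2.0 * f)
            return np.inf if nb > ceiling else nb

        point = neb_of(f1)
        # jackknife over loci on the f1 scale
        if den.size > 1:
            jack = np.array([
                (num.sum() - num[i]) / (den.sum() - den[i])
                for i in range(den.size)
            ])
            f_lo, f_hi = np.percentile(jack, [2.5, 97.5])
            mean_j = jack.mean()
            se = np.sqrt((den.size - 1) / den.size
                         * np.sum((jack - mean_j) ** 2))
            f_lo, f_hi = f1 - 1.96 * se, f1 + 1.96 * se
            ci = (neb_of(f_hi), neb_of(f_lo))  # Ne decreasing in f
        else:
            f_lo = f1
            ci = (np.nan, np.nan)
        # infinite when coancestry is non-positive or not distinguishable
        # from zero (upper CI unbounded): the Table-2 "infinity" situation
        infinite = bool(np.isinf(point) or f_lo <= 0)
        rows.append({"population": pop, "f1": f1, "N_eb": point,
                     "ci_low": ci[0], "ci_high": ci[1],
                     "infinite": infinite,
                     "n_loci": int(den.size)})
    return NeEstimate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bottleneck heterozygosity-excess test


@dataclass
class BottleneckResult:
    """Heterozygosity-excess test output.

    ``per_locus`` columns: population, locus, k, n_genes, H_E, Heq_mean,
    Heq_sd, n_sim, std_dev (standardized deviation).  ``per_population``:
    one-tailed Wilcoxon signed-rank p for excess plus locus counts.
    """

    model: str
    p_ss: float
    variance: float
    per_locus: pd.DataFrame
    per_population: pd.DataFrame


def bottleneck_test(
    data: GenotypeDataset, model: str = "tpm", p_ss: float = 0.7,
    variance: float = 30.0, n_iter: int = 1000, seed: int | None = None,
    loci: list[str] | None = None,
) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test under IAM/SMM/TPM mutation.

    For each polymorphic locus, coalescent genealogies conditioned (by
    rejection) on the observed allele count give the equilibrium
    heterozygosity distribution; a recent bottleneck inflates observed H_E
    above its conditional mean.  Significance per population is a
    one-tailed Wilcoxon signed-rank across loci on the standardized
    deviations.  Fewer than 4 polymorphic loci yields p = NA (no power).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if model.lower() not in ("iam", "smm", "tpm"):
        raise ValueError("model must be IAM, SMM or TPM")
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = data.neutral_loci()
    rows = []
    pop_rows = []
    for pop in data.population_names():
        # first pass: polymorphic loci, their allele counts and H_E
        locus_stats = []
        for locus in loci:
            g = data.pop_calls(pop, locus)
            n = len(g)
            if n < 2:
                continue
            vals, counts = np.unique(g.ravel(), return_counts=True)
            k = len(vals)
            if k < 2:
                continue  # monomorphic loci excluded
            two_n = 2 * n
            p = counts / two_n
            he = two_n / (two_n - 1) * (1 - float(np.sum(p**2)))
            locus_stats.append((locus, two_n, k, he))
        if not locus_stats:
            pop_rows.append({"population": pop, "n_loci": 0,
                             "wilcoxon_stat": np.nan, "p_excess": np.nan})
            continue
        # one mutation parameter per population: all loci share the same
        # mutation-drift regime, so theta is tuned on the mean allele
        # count.  The sampling uncertainty of that mean (shared by every
        # locus) is propagated by conditioning on a three-point theta
        # mixture spanning +/- one standard error of the mean allele count;
        # without it the Wilcoxon is anticonservative.
        from .coalescent import tune_theta_for_mean_k

        med_n = int(np.median([s[1] for s in locus_stats]))
        ks = np.array([s[2] for s in locus_stats], dtype=float)
        mean_k = float(ks.mean())
        se_k = float(ks.std(ddof=1) / np.sqrt(ks.size)) if ks.size > 1 else 0.0
        thetas = [
            tune_theta_for_mean_k(
                med_n, max(target, 1.2), model=model, p_ss=p_ss,
                variance=variance, rng=rng,
            )
            for target in (mean_k - se_k, mean_k, mean_k + se_k)
        ]
        devs = []
        for locus, two_n, k, he in locus_stats:
            parts = []
            low_acc = False
            for theta_hat in thetas:
                c = equilibrium_het_given_k(
                    two_n, k, model=model, p_ss=p_ss, variance=variance,
                    n_iter=max(n_iter // len(thetas), 50), rng=rng,
                    theta=theta_hat,
                )
                parts.append(c.het)
                low_acc = low_acc or c.low_acceptance
            from .coalescent import ConditionalHet

            cond = ConditionalHet(
                np.concatenate(parts), thetas[1], 0, low_acc
            )
            if cond.het.size < 10:
                continue
            mu, sd = float(cond.het.mean()), float(cond.het.std(ddof=1))
            std_dev = (he - mu) / sd if sd > 0 else np.nan
            # probability-scale deviation: rank of observed H within the
            # conditional distribution, minus 1/2.  Exactly symmetric about
            # 0 under the null (H|k is skewed, so mean-centred deviations
            # are not), which keeps the one-tailed Wilcoxon at its nominal
            # level.
            m = cond.het.size
            prob_dev = (
                (np.sum(cond.het < he) + 0.5 * np.sum(cond.het == he) + 0.5)
                / (m + 1) - 0.5
            )
            rows.append({"population": pop, "locus": locus, "k": k,
                         "n_genes": two_n, "H_E": he, "Heq_mean": mu,
                         "Heq_sd": sd, "n_sim": int(m),
                         "std_dev": std_dev, "prob_dev": prob_dev,
                         "low_acceptance": cond.low_acceptance})
            if np.isfinite(prob_dev):
                devs.append(prob_dev)
        if len(devs) >= 4:
            stat, pval = stats.wilcoxon(devs, alternative="greater")
            pop_rows.append({"population": pop, "n_loci": len(devs),
                             "wilcoxon_stat": float(stat),
                             "p_excess": float(pval)})
        else:
            pop_rows.append({"population": pop, "n_loci": len(devs),
                             "wilcoxon_stat": np.nan, "p_excess": np.nan})
    return BottleneckResult(
        model.lower(), p_ss, variance,
        pd.DataFrame(rows), pd.DataFrame(pop_rows),
    )


# ---------------------------------------------------------------------------
# differentiation-vs-diversity regression


def drift_regression(
    diff_results: dict[str, PairwiseStatResult],
    diversity_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """OLS of pairwise differentiation on mean within-population diversity.

    ``diff_results`` maps a statistic name (e.g. 'theta', 'jostd') to its
    pairwise result; ``diversity_tables`` maps a diversity metric name
    (e.g. 'H_O', 'H_E', 'AR') to a DataFrame with columns ``population``
    and ``value``.  For each population pair the predictor is the
    arithmetic mean of the two populations' diversity values.  Under pure
    drift the slope is negative: pairs involving diversity-poor (strongly
    drifted) populations are the most differentiated.
    """
    rows = []
    for dname, result in diff_results.items():
        pairs = result.pairs()
        if len(pairs) < 3:
            raise ValueError("need >= 3 population pairs")
        for mname, table in diversity_tables.items():
            vals = dict(zip(table["population"], table["value"]))
            x = np.array([(vals[p1] + vals[p2]) / 2 for p1, p2 in pairs])
            y = np.array([result.get(p1, p2) for p1, p2 in pairs])
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.allclose(np.var(x), 0):
                rows.append({"diff_metric": dname, "diversity_metric": mname,
                             "slope": np.nan, "intercept": np.nan,
                             "r2": np.nan, "p": np.nan, "n_pairs": len(x)})
                continue
            fit = stats.linregress(x, y)
            rows.append({"diff_metric": dname, "diversity_metric": mname,
                         "slope": float(fit.slope),
                         "intercept": float(fit.intercept),
                         "r2": float(fit.rvalue**2), "p": float(fit.pvalue),
                         "n_pairs": len(x)})
    return pd.DataFrame(rows)
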