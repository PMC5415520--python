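"""Genotype-morphology association tests.

Two-way ANOVAs of each measured trait by candidate-locus genotype and sex
(additive model, Type II sums of squares, Bonferroni over traits, with a
Levene homogeneity check), and age-trait correlations whose method (Pearson
vs Spearman) is gated on a Shapiro-Wilk normality test of the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

TRAITS_DEFAULT = [
    "total_length", "tail_length", "hind_foot_length", "carcass_weight",
    "skull_length", "zygomatic_width", "mandible_length",
]


@dataclass
class MorphTable:
    """Per-individual trait measurements with sex, age and genotype.

    ``data`` columns: id, sex, age, genotype (diploid candidate-locus
    genotype as a string factor, e.g. "101/103"), plus one column per
    trait.  Individuals missing a value for a given trait are excluded
    from that trait's model only.
    """

    data: pd.DataFrame
    traits: list[str]

    def __post_init__(self):
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise ValueError(f"traits absent from table: {missing}")


def read_morph_table(
    path: str | Path, sep: str = "\t", traits: list[str] | None = None,
) -> MorphTable:
    df = pd.read_csv(path, sep=sep)
    traits = traits or [
        c for c in df.columns if c not in ("id", "sex", "age", "genotype")
    ]
    return MorphTable(df, traits)


def attach_genotypes(morph: pd.DataFrame, data, candidate: str) -> pd.DataFrame:
    """Join candidate-locus genotype strings onto a morphology table by id."""
    li = data.locus_index(candidate)
    gt = {}
    for i, ind in enumerate(data.individuals):
        a, b = sorted(data.calls[i, li])
        gt[ind] = f"{a}/{b}" if a > 0 else np.nan
    out = morph.copy()
    out["genotype"] = out["id"].map(gt)
    return out


def anova_genotype_sex(
    table: MorphTable, alpha: float = 0.05, typ: int = 2,
    interaction: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA (genotype + sex) per trait, Bonferroni over traits.

    The additive model reports one F per factor per trait; Type II sums of
    squares handle unbalanced cells (Type I available via ``typ``).
    Levene's test of variance homogeneity across genotype-by-sex cells is
    reported alongside.  A factor with a single observed level is NA.
    """
    rows = []
    for trait in table.traits:
        df = table.data[["genotype", "sex", trait]].dropna()
        df = df.rename(columns={trait: "y"})
        n_geno = df["genotype"].nunique()
        n_sex = df["sex"].nunique()
        if len(df) < 4 or (n_geno < 2 and n_sex < 2) or df["y"].var() == 0:
            rows.append({"trait": trait, "n": len(df),
                         "F_genotype": np.nan, "p_genotype": np.nan,
                         "F_sex": np.nan, "p_sex": np.nan,
                         "levene_p": np.nan})
            continue
        terms = []
        if n_geno >= 2:
            terms.append("C(genotype)")
        if n_sex >= 2:
            terms.append("C(sex)")
        formula = "y ~ " + (" * " if interaction else " + ").join(terms)
        fit = smf.ols(formula, data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=typ)
        def pick(term):
            if term in tab.index:
                return float(tab.loc[term, "F"]), float(tab.loc[term, "PR(>F)"])
            return np.nan, np.nan
        fg, pg = pick("C(genotype)")
        fs, ps = pick("C(sex)")
        groups = [
            g["y"].to_numpy() for _, g in df.groupby(["genotype", "sex"])
            if len(g) >= 2
        ]
        lev_p = (
            float(stats.levene(*groups).pvalue) if len(groups) >= 2 else np.nan
        )
        rows.append({"trait": trait, "n": len(df),
                     "F_genotype": fg, "p_genotype": pg,
                     "F_sex": fs, "p_sex": ps, "levene_p": lev_p})
    out = pd.DataFrame(rows)
    thr = alpha / len(table.traits)
    out["bonferroni_threshold"] = thr
    out["genotype_significant"] = out["p_genotype"] < thr
    out["sex_significant"] = out["p_sex"] < thr
    return out


def age_correlation(table: MorphTable, alpha: float = 0.05) -> pd.DataFrame:
    """Age-trait correlations, Pearson or Spearman per normality gate.

    Shapiro-Wilk at ``alpha`` on the trait values decides the method:
    normal traits get Pearson's r, non-normal get Spearman's rho.
    """
    rows = []
    for trait in table.traits:
        df = table.data[["age", trait]].dropna()
        x, y = df["age"].to_numpy(float), df[trait].to_numpy(float)
        if len(df) < 4 or np.var(y) == 0 or np.var(x) == 0:
            rows.append({"trait": trait, "n": len(df), "method": "NA",
                         "coefficient": np.nan, "p": np.nan})
            continue
        sw_p = float(stats.shapiro(y).pvalue)
        if sw_p >= alpha:
            r, p = stats.pearsonr(x, y)
            method = "pearson"
        else:
            r, p = stats.spearmanr(x, y)
            method = "spearman"
        rows.append({"trait": trait, "n": len(df), "method": method,
                     "shapiro_p": sw_p, "coefficient": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows)
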