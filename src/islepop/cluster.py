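"""Cluster-number support: the Evanno delta-K statistic.

Post-processing for externally run Bayesian clustering: given replicate
ln-probability values L(K) per number of clusters K, compute the
second-order rate of change DeltaK(K) = mean|L(K+1) - 2 L(K) + L(K-1)| /
sd(L(K)) and report its argmax.  The clustering MCMC itself is out of
scope; input is a plain (K, lnP) table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class KSelectionTable:
    """Per-K summary: mean/sd of L(K), first and second differences, DeltaK."""

    table: pd.DataFrame
    best_k: int | None


def evanno_delta_k(runs: pd.DataFrame) -> KSelectionTable:
    """Evanno delta-K from replicate clustering log-likelihoods.

    ``runs`` needs columns ``K`` and ``lnP``; each K should have >= 2
    replicates, and >= 3 consecutive K values are required.  DeltaK is NA
    at the endpoints and wherever sd(L(K)) = 0 (with a warning).
    """
    if not {"K", "lnP"} <= set(runs.columns):
        raise ValueError("runs must have columns 'K' and 'lnP'")
    grp = runs.groupby("K")["lnP"]
    ks = np.array(sorted(grp.groups))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >= 3 consecutive K values")
    counts = grp.count().reindex(ks)
    if (counts < 2).any():
        raise ValueError("each K needs >= 2 replicates")
    mean = grp.mean().reindex(ks).to_numpy()
    sd = grp.std(ddof=1).reindex(ks).to_numpy()
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(mean)
    lsecond = np.full(len(ks), np.nan)
    lsecond[1:-1] = np.abs(mean[2:] - 2 * mean[1:-1] + mean[:-2])
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] == 0:
            warnings.warn(f"sd(L(K)) = 0 at K={ks[i]}; DeltaK undefined")
            continue
        delta[i] = lsecond[i] / sd[i]
    table = pd.DataFrame({
        "K": ks, "n_reps": counts.to_numpy(), "mean_lnP": mean, "sd_lnP": sd,
        "Lprime": lprime, "Lsecond_abs": lsecond, "deltaK": delta,
    })
    best_k = (
        int(ks[np.nanargmax(delta)]) if np.isfinite(delta).any() else None
    )
    return KSelectionTable(table, best_k)


def read_lnp_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column (K, lnP) table; tolerant of extra columns."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    kcol = cols.get("k")
    pcol = cols.get("lnp") or cols.get("ln p(d)") or cols.get("lnp(d)")
    if kcol is None or pcol is None:
        raise ValueError("table must contain columns K and lnP")
    return df[[kcol, pcol]].rename(columns={kcol: "K", pcol: "lnP"})


def read_structure_results(path: str | Path) -> pd.DataFrame:
    """Convenience parser for the common clustering results-file layout.

    Extracts one (K, lnP) pair per run from lines of the form
    ``K = 4`` ... ``Estimated Ln Prob of Data = -1234.5``.
    """
    text = Path(path).read_text()
    ks = [int(m) for m in re.findall(r"^\s*K\s*=\s*(\d+)", text, re.M)]
    lps = [float(m) for m in re.findall(
        r"Estimated Ln Prob of Data\s*=\s*(-?\d+\.?\d*)", text)]
    if len(ks) != len(lps) or not ks:
        raise ValueError("could not pair K values with Ln Prob entries")
    return pd.DataFrame({"K": ks, "lnP": lps})
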