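"""Genotype data model and file I/O.

The canonical in-memory container is :class:`GenotypeDataset`: diploid,
codominant allele calls (integer repeat-size codes) for individuals grouped
into populations, with at most one locus flagged as the candidate functional
locus.  Readers/writers cover the GENEPOP dialect (2- and 3-digit allele
coding) and a plain delimited genotype table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing allele call.  A genotype is missing iff
#: both allele slots equal MISSING; half-missing genotypes are not
#: representable (GENEPOP cannot encode them) and are read as fully missing.
MISSING = 0


class GenepopParseError(ValueError):
    """Raised for malformed GENEPOP input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    individuals : list of str
        Individual identifiers, one per row of ``calls``.
    populations : list of str
        Population label per individual (exactly one each).
    loci : list of str
        Ordered locus names; order is stable across all derived tables.
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Unordered allele pairs; positive integers are allele size codes and
        ``MISSING`` (0) marks an absent call.
    candidate_locus : str or None
        Name of the single candidate functional locus, if present.  All
        other loci are treated as neutral.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray
    candidate_locus: str | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be positive or MISSING (0)")
        if self.candidate_locus is not None and self.candidate_locus not in self.loci:
            raise ValueError(f"candidate locus {self.candidate_locus!r} not in loci")
        # half-missing genotypes collapse to fully missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            self.calls = self.calls.copy()
            self.calls[half] = MISSING

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def neutral_loci(self) -> list[str]:
        return [l for l in self.loci if l != self.candidate_locus]

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def subset_individuals(self, keep: Sequence[int]) -> "GenotypeDataset":
        keep = list(keep)
        return GenotypeDataset(
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
            list(self.loci),
            self.calls[keep],
            self.candidate_locus,
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeDataset":
        idx = [self.locus_index(l) for l in loci]
        cand = self.candidate_locus if self.candidate_locus in loci else None
        return GenotypeDataset(
            list(self.individuals),
            list(self.populations),
            list(loci),
            self.calls[:, idx, :],
            cand,
        )

    def population_subset(self, pops: Sequence[str]) -> "GenotypeDataset":
        keep = [i for i, p in enumerate(self.populations) if p in set(pops)]
        return self.subset_individuals(keep)

    def pop_calls(self, pop: str, locus: str) -> np.ndarray:
        """Valid (non-missing) genotype rows for one population and locus."""
        li = self.locus_index(locus)
        rows = [i for i, p in enumerate(self.populations) if p == pop]
        g = self.calls[rows, li, :]
        return g[(g != MISSING).all(axis=1)]


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele counts and frequencies.

    Missing calls are excluded from gene counts; entries where no valid call
    exists are flagged empty rather than zero-divided.
    """

    populations: list[str]
    loci: list[str]
    counts: dict = field(default_factory=dict)  # (pop, locus) -> {allele: count}

    def gene_count(self, pop: str, locus: str) -> int:
        return sum(self.counts.get((pop, locus), {}).values())

    def is_empty(self, pop: str, locus: str) -> bool:
        return self.gene_count(pop, locus) == 0

    def frequencies(self, pop: str, locus: str) -> dict[int, float]:
        c = self.counts.get((pop, locus), {})
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}

    def alleles(self, locus: str) -> list[int]:
        """All alleles observed at a locus, across populations, sorted."""
        out: set[int] = set()
        for pop in self.populations:
            out.update(self.counts.get((pop, locus), {}))
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, locus), c in self.counts.items():
            n = sum(c.values())
            for a, k in sorted(c.items()):
                rows.append(
                    {"population": pop, "locus": locus, "allele": a,
                     "count": k, "gene_count": n, "frequency": k / n}
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations


def allele_frequencies(data: GenotypeDataset) -> AlleleFrequencyTable:
    """Tally allele counts and frequencies per (population, locus)."""
    table = AlleleFrequencyTable(data.population_names(), list(data.loci))
    pops = np.asarray(data.populations)
    for li, locus in enumerate(data.loci):
        for pop in table.populations:
            g = data.calls[pops == pop, li, :].ravel()
            g = g[g != MISSING]
            if g.size:
                vals, cnts = np.unique(g, return_counts=True)
                table.counts[(pop, locus)] = dict(
                    zip(vals.tolist(), cnts.tolist())
                )
            else:
                table.counts[(pop, locus)] = {}
    return table


def filter_missing(data: GenotypeDataset, max_missing_loci: int = 2) -> GenotypeDataset:
    """Drop individuals missing more than ``max_missing_loci`` neutral loci.

    Counts missingness over neutral loci only (the candidate locus does not
    contribute).  Survivor order is preserved.
    """
    if max_missing_loci < 0:
        raise ValueError("max_missing_loci must be >= 0")
    neutral_idx = [data.locus_index(l) for l in data.neutral_loci()]
    miss = data.missing_mask()[:, neutral_idx].sum(axis=1)
    keep = [i for i in range(data.n_individuals) if miss[i] <= max_missing_loci]
    return data.subset_individuals(keep)


def merge_populations(
    data: GenotypeDataset, grouping: Mapping[str, str]
) -> GenotypeDataset:
    """Relabel site populations into clusters according to ``grouping``."""
    unknown = [p for p in data.population_names() if p not in grouping]
    if unknown:
        raise KeyError(f"sites not in grouping: {unknown}")
    return replace(
        data, populations=[grouping[p] for p in data.populations],
        individuals=list(data.individuals), loci=list(data.loci),
        calls=data.calls.copy(),
    )


# ---------------------------------------------------------------------------
# GENEPOP reader / writer

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _parse_genotype(token: str, lineno: int) -> tuple[int, int]:
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenepopParseError(
            f"bad genotype token {token!r} (need 4 or 6 digits)", lineno
        )
    w = len(token) // 2
    a, b = int(token[:w]), int(token[w:])
    if a == 0 or b == 0:  # half-missing collapses to missing
        return (MISSING, MISSING)
    return (a, b)


def read_genepop(path: str | Path, candidate_locus: str | None = None) -> GenotypeDataset:
    """Read a GENEPOP file (2- or 3-digit allele coding).

    The first line is a title; locus names follow, one per line or
    comma-separated on one line; ``POP`` lines delimit populations.  ``00`` /
    ``000`` allele codes parse as missing.  Population names follow the
    GENEPOP convention: the label of the first individual in each POP block.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GENEPOP", len(lines))
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        if not chunk:
            raise GenepopParseError("empty locus-name line", i + 1)
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP delimiter found", i)

    individuals: list[str] = []
    populations: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pop_label: str | None = None
    pop_count = 0
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0]
        if not line.strip():
            continue
        if _POP_RE.match(line):
            pop_count += 1
            pop_label = None
            continue
        if pop_count == 0:
            raise GenepopParseError("genotype row before first POP", lineno0 + 1)
        if "," in line:
            name, rest = line.split(",", 1)
        else:
            # tolerate missing comma: first token is the id
            parts = line.split()
            name, rest = parts[0], " ".join(parts[1:])
        name = name.strip()
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"expected {len(loci)} genotypes, got {len(tokens)}", lineno0 + 1
            )
        if pop_label is None:
            pop_label = name
        individuals.append(name)
        populations.append(pop_label)
        calls.append([_parse_genotype(t, lineno0 + 1) for t in tokens])

    arr = np.array(calls, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeDataset(individuals, populations, loci, arr, candidate_locus)


def write_genepop(
    data: GenotypeDataset, path: str | Path, title: str = "islepop export",
    digits: int = 3,
) -> None:
    """Write a GENEPOP file with fixed-width (2- or 3-digit) allele codes."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxallele = int(data.calls.max(initial=0))
    if maxallele >= 10 ** digits:
        raise ValueError(f"allele code {maxallele} does not fit {digits} digits")
    out = [title]
    out.extend(data.loci)
    pops = np.asarray(data.populations)
    for pop in data.population_names():
        out.append("POP")
        for i in np.flatnonzero(pops == pop):
            gts = " ".join(
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in data.calls[i]
            )
            out.append(f"{data.individuals[i]} , {gts}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# delimited genotype table

def read_genotype_table(
    path: str | Path, sep: str = "\t", candidate_locus: str | None = None
) -> GenotypeDataset:
    """Read a delimited genotype table.

    Layout: one row per individual with columns ``id``, ``population`` and
    then two columns per locus named ``<locus>.1`` / ``<locus>.2`` (missing
    coded as 0 or blank).
    """
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns)
    if cols[:2] != ["id", "population"]:
        raise ValueError("first two columns must be 'id' and 'population'")
    locus_cols = cols[2:]
    if len(locus_cols) % 2:
        raise ValueError("need two allele columns per locus")
    loci = []
    for j in range(0, len(locus_cols), 2):
        name = locus_cols[j].rsplit(".", 1)[0]
        loci.append(name)
    arr = (
        df[locus_cols].fillna(0).to_numpy(dtype=np.int64)
        .reshape(len(df), len(loci), 2)
    )
    return GenotypeDataset(
        df["id"].astype(str).tolist(), df["population"].astype(str).tolist(),
        loci, arr, candidate_locus,
    )


def write_genotype_table(data: GenotypeDataset, path: str | Path, sep: str = "\t") -> None:
    cols: dict[str, object] = {
        "id": data.individuals, "population": data.populations,
    }
    for li, locus in enumerate(data.loci):
        cols[f"{locus}.1"] = data.calls[:, li, 0]
        cols[f"{locus}.2"] = data.calls[:, li, 1]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
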