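"""Synthetic island-mainland genotype data.

A forward Wright-Fisher simulator (non-overlapping generations, random
union of gametes) generates genotype datasets with the statistical
structure the analysis pipeline assumes: large mainland demes initialised
from a shared mutation-drift-equilibrium gene pool, small island demes
founded from them through a founder bottleneck, stepwise/two-phase/infinite
-alleles mutation, optional weak migration, and optional island-only genic
selection at the single candidate locus (fitnesses 1, 1+s, 1+2s by favored
-allele dosage).

Forward time is used because founder events, unequal deme sizes and
selection are simplest to specify exactly forward; the outlier scan's
coalescent null lives independently in :mod:`islepop.coalescent`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coalescent import sample_panmictic
from .io import GenotypeDataset


@dataclass
class IslandSpec:
    """One island deme: founded from ``source`` ``founding_time`` generations
    before the present with ``founder_size`` diploid founders, then held at
    ``post_size``."""

    source: str
    founder_size: int
    founding_time: int
    post_size: int


@dataclass
class SimScenario:
    """Demographic, mutational and selective parameters of one simulation.

    ``migration`` maps (recipient, source) deme pairs to the per-gamete
    probability of drawing the parent gene from the source deme.  Selection
    (coefficient ``s``) applies at the candidate locus in island demes
    only; ``s = 0`` makes the candidate exactly neutral.  The favored
    allele is chosen at initialisation as the mainland allele whose
    frequency is closest to ``favored_init_freq``.
    """

    mainland_demes: dict = field(default_factory=dict)  # name -> diploid size
    island_demes: dict = field(default_factory=dict)    # name -> IslandSpec
    migration: dict = field(default_factory=dict)       # (to, from) -> rate
    n_neutral_loci: int = 14
    mu: float = 5e-4
    model: str = "smm"
    p_ss: float = 0.7
    variance: float = 30.0
    s: float = 0.0
    favored_init_freq: float = 0.10
    #: scaled mutation rate of the ancestral equilibrium pool; defaults to
    #: 4 * N_max * mu.  Override to give mu = 0 runs standing variation.
    init_theta: float | None = None
    sample_sizes: dict = field(default_factory=dict)    # deme -> n sampled
    run_generations: int = 120
    candidate_name: str = "IGF1"
    seed: int | None = None

    def __post_init__(self):
        for name, size in self.mainland_demes.items():
            if size < 1:
                raise ValueError(f"deme {name} size must be >= 1")
        for name, isl in self.island_demes.items():
            if isinstance(isl, dict):
                self.island_demes[name] = isl = IslandSpec(**isl)
            if min(isl.founder_size, isl.post_size) < 1:
                raise ValueError(f"island {name} sizes must be >= 1")
            if isl.founding_time > self.run_generations:
                raise ValueError(
                    f"island {name} founding_time exceeds run_generations"
                )
            if isl.source not in self.mainland_demes:
                raise ValueError(f"island {name} source {isl.source!r} unknown")
        out_mig: dict = {}
        for (to, frm), m in self.migration.items():
            if m < 0:
                raise ValueError("migration rates must be >= 0")
            out_mig[to] = out_mig.get(to, 0.0) + m
        if any(v >= 1 for v in out_mig.values()):
            raise ValueError("total in-migration per deme must be < 1")
        if self.s < 0:
            raise ValueError("s must be >= 0")

    @property
    def loci(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_neutral_loci)] + [
            self.candidate_name
        ]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["migration"] = {f"{k[0]}<-{k[1]}": v for k, v in self.migration.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        d = yaml.safe_load(Path(path).read_text())
        mig = {}
        for k, v in (d.get("migration") or {}).items():
            to, frm = k.split("<-")
            mig[(to, frm)] = v
        d["migration"] = mig
        return cls(**d)


def lynx_default_scenario(seed: int | None = None, scale: float = 1.0,
                          s: float = 0.05) -> SimScenario:
    """The default island-mainland scenario.

    Two large mainland demes, two small islands founded from them with 20
    individuals (post-founding sizes 100 and 250, founding 100 and 30
    generations ago), 14 neutral dinucleotide loci plus one candidate locus
    under island-convergent selection, and present-day sample sizes shaped
    like the study's clusters (347 / 179 / 24 / 38).  ``scale`` shrinks
    the mainland deme size while preserving 4*N*mu (and caps samples at
    the deme size) so the same scenario can be run cheaply.
    """
    n_main = max(int(round(5000 * scale)), 300)
    mu = 5e-4 * (5000 / n_main)
    return SimScenario(
        mainland_demes={"QCN_LAB": n_main, "QCS_NB": n_main},
        island_demes={
            "NFLD": IslandSpec("QCN_LAB", 20, 30, 250),
            "CBI": IslandSpec("QCS_NB", 20, 100, 100),
        },
        migration={("QCN_LAB", "QCS_NB"): 2e-4, ("QCS_NB", "QCN_LAB"): 2e-4},
        n_neutral_loci=14, mu=mu, model="smm", s=s,
        favored_init_freq=0.10,
        sample_sizes={"QCN_LAB": min(347, n_main), "QCS_NB": min(179, n_main),
                      "NFLD": 24, "CBI": 38},
        run_generations=120, seed=seed,
    )


# ---------------------------------------------------------------------------
# forward engine


def _mutate_genes(genes: np.ndarray, mu: float, model: str, p_ss: float,
                  q: float, rng: np.random.Generator,
                  iam_counter: list[int]) -> np.ndarray:
    hits = np.flatnonzero(rng.random(genes.size) < mu)
    if hits.size == 0:
        return genes
    genes = genes.copy()
    if model == "iam":
        new = np.arange(iam_counter[0], iam_counter[0] + hits.size)
        iam_counter[0] += hits.size
        genes[hits] = new
        return genes
    steps = np.ones(hits.size, dtype=np.int64)
    if model == "tpm":
        multi = rng.random(hits.size) >= p_ss
        if multi.any():
            steps[multi] = rng.geometric(q, size=int(multi.sum()))
    signs = np.where(rng.random(hits.size) < 0.5, -1, 1)
    genes[hits] += steps * signs
    return genes


@dataclass
class TruthLog:
    """Ground truth emitted alongside a simulated dataset."""

    favored_allele: int
    trajectories: pd.DataFrame      # generation, deme, locus-type trajectories
    realized_theta: pd.DataFrame    # per-locus W&C theta over full demes
    breeder_counts: dict            # deme -> census breeder count at present


def _tpm_q(variance: float) -> float:
    return (-1.0 + np.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)


def simulate_scenario(
    scenario: SimScenario, seed: int | None = None,
    track_trajectories: bool = True,
) -> tuple[GenotypeDataset, TruthLog]:
    """Run the forward Wright-Fisher scenario and sample a dataset.

    Loci are unlinked and simulated independently given the shared
    demography (random mating implies no inter-locus associations).  The
    candidate locus is diploid-resolved so viability selection can weight
    parents by favored-allele dosage.  Identical scenario + seed gives an
    identical dataset.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    q = _tpm_q(scenario.variance)
    loci = scenario.loci
    candidate = scenario.candidate_name
    demes = dict(scenario.mainland_demes)
    T = scenario.run_generations

    # ancestral equilibrium pool per locus, shared by the mainland demes
    theta_anc = (
        scenario.init_theta if scenario.init_theta is not None
        else 4 * max(scenario.mainland_demes.values()) * scenario.mu
    )
    pools: dict[str, dict[str, np.ndarray]] = {d: {} for d in demes}
    iam_counter = [10_000_000]
    anc_freqs: dict[str, np.ndarray] = {}
    for locus in loci:
        anc = sample_panmictic(
            2 * max(demes.values()), theta_anc, model=scenario.model,
            p_ss=scenario.p_ss, variance=scenario.variance, rng=rng,
        )
        anc_freqs[locus] = anc
        for d, n in demes.items():
            pools[d][locus] = rng.choice(anc, size=(n, 2), replace=True)

    # favored allele: the ancestral allele nearest favored_init_freq
    vals, counts = np.unique(anc_freqs[candidate], return_counts=True)
    freqs = counts / counts.sum()
    favored = int(vals[np.argmin(np.abs(freqs - scenario.favored_init_freq))])

    founding_gen = {
        name: T - isl.founding_time for name, isl in scenario.island_demes.items()
    }
    sizes = dict(demes)
    traj_rows = []

    def record(gen: int):
        if not track_trajectories:
            return
        for d in pools:
            g = pools[d][candidate]
            p_fav = float(np.mean(g == favored))
            het = []
            for locus in loci:
                genes = pools[d][locus].ravel()
                _, c = np.unique(genes, return_counts=True)
                p = c / c.sum()
                het.append(1.0 - float(np.sum(p**2)))
            traj_rows.append({"generation": gen, "deme": d,
                              "favored_freq": p_fav,
                              "mean_exp_het": float(np.mean(het))})

    record(0)
    for gen in range(1, T + 1):
        # founder events
        for name, isl in scenario.island_demes.items():
            if founding_gen[name] == gen - 1:
                rows = rng.choice(
                    sizes[isl.source], size=isl.founder_size, replace=False
                )
                pools[name] = {
                    locus: pools[isl.source][locus][rows].copy()
                    for locus in loci
                }
                sizes[name] = isl.founder_size
        next_pools: dict[str, dict[str, np.ndarray]] = {}
        for d in pools:
            n_next = (
                scenario.island_demes[d].post_size
                if d in scenario.island_demes else scenario.mainland_demes[d]
            )
            next_pools[d] = {}
            is_island = d in scenario.island_demes
            for locus in loci:
                n_gam = 2 * n_next
                use_selection = (
                    is_island and locus == candidate and scenario.s > 0
                )
                cur = pools[d][locus]
                if use_selection:
                    dosage = (cur == favored).sum(axis=1)
                    w = 1.0 + scenario.s * dosage
                    p = w / w.sum()
                    parents = rng.choice(len(cur), size=n_gam, p=p)
                    gam = cur[parents, rng.integers(0, 2, n_gam)]
                else:
                    pool = cur.ravel()
                    gam = pool[rng.integers(0, pool.size, n_gam)]
                # migration: replace a fraction of gametes from source demes
                for (to, frm), m in scenario.migration.items():
                    if to != d or frm not in pools or m <= 0:
                        continue
                    mask = np.flatnonzero(rng.random(n_gam) < m)
                    if mask.size:
                        src = pools[frm][locus].ravel()
                        gam[mask] = src[rng.integers(0, src.size, mask.size)]
                gam = _mutate_genes(
                    gam, scenario.mu, scenario.model, scenario.p_ss, q, rng,
                    iam_counter,
                )
                next_pools[d][locus] = gam.reshape(n_next, 2)
            sizes[d] = n_next
        pools = next_pools
        record(gen)

    # sample individuals and assemble the dataset
    deme_order = list(scenario.mainland_demes) + list(scenario.island_demes)
    individuals, populations, calls = [], [], []
    for d in deme_order:
        n_samp = scenario.sample_sizes.get(d, sizes[d])
        if n_samp > sizes[d]:
            raise ValueError(f"sample size for {d} exceeds deme size")
        for j in range(n_samp):
            individuals.append(f"{d}_{j + 1:04d}")
            populations.append(d)
        rows = {
            locus: rng.choice(sizes[d], size=n_samp, replace=False)
            for locus in loci
        }
        block = np.stack(
            [pools[d][locus][rows[locus]] for locus in loci], axis=1
        )
        calls.append(block)
    calls_arr = np.concatenate(calls, axis=0)
    # map allele states onto positive 3-digit-friendly codes
    uniq = np.unique(calls_arr)
    remap = {int(a): i + 1 for i, a in enumerate(np.sort(uniq))}
    if scenario.model in ("smm", "tpm") and uniq.min() > 0 and uniq.max() < 999:
        remap = {int(a): int(a) for a in uniq}  # repeat codes already valid
    calls_arr = np.vectorize(lambda a: remap[int(a)])(calls_arr)
    favored_code = remap.get(favored, -1)

    data = GenotypeDataset(
        individuals, populations, loci, calls_arr, candidate_locus=candidate
    )

    from .differentiation import per_locus_estimate  # local import, no cycle
    theta_rows = []
    for locus in loci:
        gs = [pools[d][locus] for d in deme_order]
        theta_rows.append({
            "locus": locus,
            "theta": per_locus_estimate(gs, "theta"),
            "is_candidate": locus == candidate,
        })
    truth = TruthLog(
        favored_allele=favored_code,
        trajectories=pd.DataFrame(traj_rows),
        realized_theta=pd.DataFrame(theta_rows),
        breeder_counts=dict(sizes),
    )
    return data, truth


def simulate_equilibrium_population(
    n_ind: int, n_loci: int, mu: float, model: str, N: int,
    seed: int | None = None, burnin_factor: int = 10, p_ss: float = 0.7,
    variance: float = 30.0,
) -> GenotypeDataset:
    """Single-deme forward run to mutation-drift equilibrium.

    The deme is initialised from a coalescent equilibrium sample and run a
    further ``burnin_factor * N`` generations forward, then ``n_ind``
    individuals are sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    q = _tpm_q(variance)
    theta = 4 * N * mu
    iam_counter = [10_000_000]
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        genes = rng.permutation(sample_panmictic(
            2 * N, theta, model=model, p_ss=p_ss, variance=variance, rng=rng
        ))
        for _ in range(burnin_factor * N):
            genes = genes[rng.integers(0, genes.size, genes.size)]
            genes = _mutate_genes(genes, mu, model, p_ss, q, rng, iam_counter)
        rows = rng.choice(N, size=n_ind, replace=False)
        calls[:, li, :] = genes.reshape(N, 2)[rows]
    uniq = np.unique(calls)
    remap = {int(a): i + 1 for i, a in enumerate(np.sort(uniq))}
    calls = np.vectorize(lambda a: remap[int(a)])(calls)
    return GenotypeDataset(
        [f"ind_{i + 1:03d}" for i in range(n_ind)], ["pop1"] * n_ind, loci,
        calls,
    )


def simulate_breeding_cohort(
    n_pairs: int, n_offspring: int, n_loci: int = 14, theta: float = 10.0,
    seed: int | None = None, model: str = "smm",
) -> GenotypeDataset:
    """Offspring cohort from ``n_pairs`` monogamous breeding pairs.

    Parents draw genotypes from a diverse equilibrium pool; each offspring
    picks a couple uniformly and one gamete per parent.  The effective
    number of breeders is ~2*n_pairs; used as the parameter-recovery
    fixture for the coancestry estimator.
    """
    rng = np.random.default_rng(seed)
    n_parents = 2 * n_pairs
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    calls = np.empty((n_offspring, n_loci, 2), dtype=np.int64)
    couples = rng.integers(0, n_pairs, size=n_offspring)
    for li in range(n_loci):
        parents = rng.permutation(sample_panmictic(
            2 * n_parents, theta, model=model, rng=rng
        )).reshape(n_parents, 2)
        dams, sires = parents[:n_pairs], parents[n_pairs:]
        calls[:, li, 0] = dams[couples, rng.integers(0, 2, n_offspring)]
        calls[:, li, 1] = sires[couples, rng.integers(0, 2, n_offspring)]
    uniq = np.unique(calls)
    remap = {int(a): i + 1 for i, a in enumerate(np.sort(uniq))}
    calls = np.vectorize(lambda a: remap[int(a)])(calls)
    return GenotypeDataset(
        [f"off_{i + 1:03d}" for i in range(n_offspring)],
        ["cohort"] * n_offspring, loci, calls,
    )


# ---------------------------------------------------------------------------
# morphology fixture


TRAIT_BASELINES = {
    "total_length": 850.0, "tail_length": 100.0, "hind_foot_length": 220.0,
    "carcass_weight": 8500.0, "skull_length": 120.0,
    "zygomatic_width": 88.0, "mandible_length": 80.0,
}

SEX_OFFSETS = {
    "total_length": 25.0, "tail_length": 3.0, "hind_foot_length": 6.0,
    "carcass_weight": 900.0, "skull_length": 4.0, "zygomatic_width": 3.0,
    "mandible_length": 2.5,
}


def simulate_morphology(
    data: GenotypeDataset, effect_map: dict | None = None,
    noise_sd: dict | float = 0.0, seed: int | None = None,
    favored_allele: int | None = None, sex_offsets: dict | None = None,
    age_slope: dict | None = None, population: str | None = None,
):
    """Morphology fixture: traits = baseline + sex offset (+ genotype
    effect per favored-allele dosage) + Gaussian noise.

    ``effect_map`` maps trait name to the additive per-allele effect of the
    favored candidate allele; ``noise_sd`` is a scalar fraction of the
    baseline or a per-trait dict of absolute standard deviations.  Age is
    drawn independently (1-14 years) unless ``age_slope`` adds a per-year
    trait increment.
    """
    from .morphology import MorphTable

    rng = np.random.default_rng(seed)
    if population is not None:
        data = data.population_subset([population])
    if data.candidate_locus is None:
        raise ValueError("dataset has no candidate locus")
    li = data.locus_index(data.candidate_locus)
    effect_map = effect_map or {}
    sex_offsets = sex_offsets if sex_offsets is not None else SEX_OFFSETS
    age_slope = age_slope or {}
    traits = list(TRAIT_BASELINES)
    n = data.n_individuals
    sex = rng.choice(["F", "M"], size=n)
    age = rng.integers(1, 15, size=n)
    rows: dict[str, object] = {
        "id": data.individuals, "sex": sex, "age": age,
    }
    geno = np.sort(data.calls[:, li, :], axis=1)
    dosage = (
        (geno == favored_allele).sum(axis=1) if favored_allele is not None
        else np.zeros(n)
    )
    rows["genotype"] = [
        f"{a}/{b}" if a > 0 else "" for a, b in geno
    ]
    for trait in traits:
        base = TRAIT_BASELINES[trait]
        if isinstance(noise_sd, dict):
            sd = noise_sd.get(trait, 0.0)
        else:
            sd = noise_sd * base
        vals = (
            base
            + (sex == "M") * sex_offsets.get(trait, 0.0)
            + dosage * effect_map.get(trait, 0.0)
            + age * age_slope.get(trait, 0.0)
            + rng.normal(0.0, sd, size=n)
        )
        rows[trait] = np.maximum(vals, 0.0)
    return MorphTable(pd.DataFrame(rows), traits)
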