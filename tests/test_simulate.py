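"""Forward Wright-Fisher generator: determinism, drift and mutation laws."""

import numpy as np
import pytest
from scipy import stats

from islepop import (
    IslandSpec, SimScenario, heterozygosity, lynx_default_scenario,
    simulate_equilibrium_population, simulate_morphology, simulate_scenario,
    write_genepop,
)


def _mini_scenario(**kw):
    base = dict(
        mainland_demes={"M1": 60, "M2": 60},
        island_demes={"I1": IslandSpec("M1", 10, 15, 30)},
        n_neutral_loci=4, mu=1e-3, model="smm", s=0.0, init_theta=3.0,
        sample_sizes={"M1": 20, "M2": 20, "I1": 15},
        run_generations=20,
    )
    base.update(kw)
    return SimScenario(**base)


def test_seed_reproducibility_byte_identical(tmp_path):
    sc = _mini_scenario()
    d1, _ = simulate_scenario(sc, seed=7)
    d2, _ = simulate_scenario(sc, seed=7)
    p1, p2 = tmp_path / "a.gen", tmp_path / "b.gen"
    write_genepop(d1, p1)
    write_genepop(d2, p2)
    assert p1.read_text() == p2.read_text()
    d3, _ = simulate_scenario(sc, seed=8)
    assert not np.array_equal(d1.calls, d3.calls)


def test_scenario_validation():
    with pytest.raises(ValueError, match="founding_time"):
        _mini_scenario(island_demes={"I1": IslandSpec("M1", 10, 99, 30)})
    with pytest.raises(ValueError, match="source"):
        _mini_scenario(island_demes={"I1": IslandSpec("XX", 10, 5, 30)})
    with pytest.raises(ValueError, match="migration"):
        _mini_scenario(migration={("M1", "M2"): -0.1})


def test_yaml_roundtrip(tmp_path):
    sc = lynx_default_scenario(seed=3)
    p = tmp_path / "sc.yaml"
    sc.to_yaml(p)
    back = SimScenario.from_yaml(p)
    assert back == sc


def test_pure_drift_fst_matches_expectation(rng):
    """No mutation, no migration: E[F_ST] ~ 1 - (1 - 1/2N)^t."""
    N, t = 30, 12
    thetas = []
    for r in range(60):
        sc = SimScenario(
            mainland_demes={"M1": N, "M2": N}, n_neutral_loci=5, mu=0.0,
            s=0.0, init_theta=2.0, sample_sizes={"M1": N, "M2": N},
            run_generations=t, seed=1000 + r,
        )
        data, truth = simulate_scenario(sc, track_trajectories=False)
        vals = truth.realized_theta["theta"].to_numpy()
        thetas.extend(vals[np.isfinite(vals)])
    expected = 1 - (1 - 1 / (2 * N)) ** t
    got = float(np.mean(thetas))
    se = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
    assert abs(got - expected) < 4 * se + 0.01


def test_island_model_migration_equilibrium(rng):
    """d-deme island model at 4Nm = 9 approaches the closed-form F_ST."""
    N, d_demes, M = 50, 10, 9.0
    m = M / (4 * N)
    names = [f"D{i}" for i in range(d_demes)]
    mig = {(a, b): m / (d_demes - 1) for a in names for b in names if a != b}
    thetas = []
    for r in range(8):
        sc = SimScenario(
            mainland_demes={n: N for n in names}, migration=mig,
            n_neutral_loci=6, mu=2e-3, s=0.0,
            sample_sizes={n: N for n in names},
            run_generations=250, seed=400 + r,
        )
        _, truth = simulate_scenario(sc, track_trajectories=False)
        thetas.extend(truth.realized_theta["theta"])
    expected = 1 / (1 + M * (d_demes / (d_demes - 1)) ** 2)
    assert np.mean(thetas) == pytest.approx(expected, abs=0.035)


def test_zero_mutation_long_run_fixes():
    sc = SimScenario(
        mainland_demes={"M1": 20}, n_neutral_loci=3, mu=0.0, s=0.0,
        sample_sizes={"M1": 20}, run_generations=400, seed=5,
    )
    data, _ = simulate_scenario(sc, track_trajectories=False)
    div = heterozygosity(data)
    assert (div.per_locus["allele_count"] == 1).all()


def test_equilibrium_population_iam_heterozygosity():
    """Long-run IAM H_E ~ theta/(1+theta) with theta = 4*N*mu."""
    N, mu = 50, 5e-3
    theta = 4 * N * mu
    hes = []
    for r in range(25):
        d = simulate_equilibrium_population(
            30, 4, mu, "iam", N, seed=600 + r, burnin_factor=4
        )
        hes.extend(heterozygosity(d).per_locus["H_E"])
    target = theta / (1 + theta)
    se = np.std(hes, ddof=1) / np.sqrt(len(hes))
    assert abs(np.mean(hes) - target) < 4 * se + 0.02


def test_neutral_candidate_indistinguishable_from_neutral_loci(rng):
    """With s = 0 the candidate's per-locus theta distribution matches the
    neutral loci's (two-sample KS at a coarse level)."""
    cand, neut = [], []
    for r in range(40):
        sc = _mini_scenario(run_generations=15)
        _, truth = simulate_scenario(sc, seed=2000 + r,
                                     track_trajectories=False)
        t = truth.realized_theta
        cand.extend(t[t.is_candidate]["theta"])
        neut.extend(t[~t.is_candidate]["theta"])
    cand = np.array(cand); neut = np.array(neut)
    _, p = stats.ks_2samp(cand[np.isfinite(cand)], neut[np.isfinite(neut)])
    assert p > 0.01


def test_selection_raises_candidate_differentiation():
    above = 0
    for r in range(10):
        sc = _mini_scenario(s=0.3, run_generations=25, mu=1e-3,
                            favored_init_freq=0.15)
        _, truth = simulate_scenario(sc, seed=3000 + r,
                                     track_trajectories=False)
        t = truth.realized_theta
        if (t[t.is_candidate]["theta"].iloc[0]
                > t[~t.is_candidate]["theta"].median()):
            above += 1
    assert above >= 7


def test_heterozygosity_decay_rate(rng):
    """Isolated-deme expected heterozygosity decays ~ 1/(2N) per generation."""
    N = 40
    sc = SimScenario(
        mainland_demes={"M1": N}, n_neutral_loci=12, mu=0.0, s=0.0,
        init_theta=4.0, sample_sizes={"M1": N}, run_generations=30, seed=11,
    )
    _, truth = simulate_scenario(sc, track_trajectories=True)
    tr = truth.trajectories
    y = np.log(tr["mean_exp_het"].to_numpy())
    t = tr["generation"].to_numpy()
    slope = stats.linregress(t, y).slope
    assert slope == pytest.approx(-1 / (2 * N), rel=0.5)


def test_morphology_fixture_effects(rng):
    sc = _mini_scenario()
    data, truth = simulate_scenario(sc, seed=21, track_trajectories=False)
    morph = simulate_morphology(
        data, effect_map={"total_length": -40.0}, noise_sd=0.01,
        favored_allele=truth.favored_allele, seed=2,
    )
    assert set(morph.data.columns) >= {"id", "sex", "age", "genotype"}
    assert (morph.data[morph.traits] >= 0).all().all()
    # configured sex offset is detectable
    from islepop.morphology import anova_genotype_sex

    out = anova_genotype_sex(morph)
    row = out[out.trait == "total_length"].iloc[0]
    assert row["p_sex"] < 0.01
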