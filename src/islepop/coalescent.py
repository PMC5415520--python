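"""Coalescent samplers for microsatellite loci.

Two neutral genealogical samplers back the inferential machinery:

* a panmictic sampler (sequential jump-chain construction) used to draw
  mutation-drift-equilibrium samples and, by rejection on the observed
  allele count, the equilibrium-heterozygosity distributions of the
  bottleneck test;
* a finite-island structured coalescent (default 100 demes, a subset
  sampled) used as the neutral null of the F_ST-outlier scan.

Mutation models: infinite alleles (IAM), strict stepwise (SMM) and the
two-phase model (TPM: single-step with probability ``p_ss``, otherwise a
geometric multi-step of configurable variance).  Allele states live on an
unbounded integer lattice initialised at 100 repeats; IAM alleles are fresh
integers.  Inner loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MODEL_CODES = {"iam": 0, "smm": 1, "tpm": 2}


def _model_params(model: str, p_ss: float, variance: float):
    code = MODEL_CODES[model.lower()]
    if code == 2:
        # geometric multi-step on {1,2,...}: var = (1-q)/q^2 = variance
        q = (-1.0 + np.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)
    else:
        q = 0.5
    return code, float(p_ss), float(q)


@njit(cache=False)
def _mutate(states, t, model, p_ss, q, nxt):
    if model == 0:
        nxt += 1
        states[t] = nxt
        return nxt
    step = 1
    if model == 2 and np.random.random() >= p_ss:
        step = 1 + int(np.log(np.random.random()) / np.log(1.0 - q))
    if np.random.random() < 0.5:
        step = -step
    states[t] += step
    return nxt


@njit(cache=False)
def _pan_core(states, n_genes, theta, model, p_ss, q):
    """Fill ``states`` with one panmictic equilibrium sample.

    Sequential construction: replaying the reversed jump chain, each new
    lineage duplicates a random existing one, then a geometric number of
    mutations (competing at rate theta/2 per lineage against pairwise
    coalescence) hit uniformly chosen lineages.
    """
    states[0] = 100
    nxt = 1_000_000
    for j in range(2, n_genes + 1):
        states[j - 1] = states[np.random.randint(j - 1)]
        pmut = theta / (theta + (j - 1))
        while np.random.random() < pmut:
            t = np.random.randint(j)
            nxt = _mutate(states, t, model, p_ss, q, nxt)


@njit(cache=False)
def _k_and_h(states, n_genes):
    s = np.sort(states[:n_genes])
    k = 1
    sum_sq = 0.0
    run = 1
    for i in range(1, n_genes):
        if s[i] != s[i - 1]:
            k += 1
            sum_sq += run * run
            run = 1
        else:
            run += 1
    sum_sq += run * run
    h = 1.0 - sum_sq / (n_genes * n_genes)
    h *= n_genes / (n_genes - 1.0)  # unbiased gene diversity
    return k, h


@njit(cache=False)
def _pan_batch_k(n_sims, n_genes, theta, model, p_ss, q, seed):
    """Mean allele count over ``n_sims`` equilibrium samples."""
    np.random.seed(seed)
    states = np.empty(n_genes, dtype=np.int64)
    tot = 0.0
    for _ in range(n_sims):
        _pan_core(states, n_genes, theta, model, p_ss, q)
        k, _ = _k_and_h(states, n_genes)
        tot += k
    return tot / n_sims


@njit(cache=False)
def _pan_conditional(n_iter, max_attempts, n_genes, k_obs, theta, model,
                     p_ss, q, seed):
    """Equilibrium heterozygosities conditional on k_obs alleles."""
    np.random.seed(seed)
    states = np.empty(n_genes, dtype=np.int64)
    out = np.empty(n_iter)
    got = 0
    attempts = 0
    while got < n_iter and attempts < max_attempts:
        attempts += 1
        _pan_core(states, n_genes, theta, model, p_ss, q)
        k, h = _k_and_h(states, n_genes)
        if k == k_obs:
            out[got] = h
            got += 1
    return out[:got], attempts


@njit(cache=False)
def _pan_sample(n_genes, theta, model, p_ss, q, seed):
    np.random.seed(seed)
    states = np.empty(n_genes, dtype=np.int64)
    _pan_core(states, n_genes, theta, model, p_ss, q)
    return states


@njit(cache=False)
def _island_locus(n_demes, genes_per_deme, n_sampled, M, theta, model,
                  p_ss, q, seed):
    """One locus under the finite-island structured coalescent.

    ``n_sampled`` demes each contribute ``genes_per_deme`` gene copies;
    leaves are ordered by deme.  Returns the leaf allele states.  Event
    competition (within-deme coalescence C(k_d,2), migration M/2 per
    lineage, mutation theta/2 per lineage) follows the scaled jump chain;
    branch mutations are accumulated per tree node and resolved root-down.
    """
    np.random.seed(seed)
    K = n_sampled * genes_per_deme
    n_nodes = 2 * K - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    net_step = np.zeros(n_nodes, dtype=np.int64)   # stepwise models
    fresh = np.full(n_nodes, -1, dtype=np.int64)   # IAM: fresh allele id
    act_node = np.empty(K, dtype=np.int64)
    act_deme = np.empty(K, dtype=np.int64)
    cnt = np.zeros(n_demes, dtype=np.int64)
    for i in range(K):
        act_node[i] = i
        act_deme[i] = i // genes_per_deme
        cnt[i // genes_per_deme] += 1
    n_act = K
    next_node = K
    nxt_allele = 1_000_000
    while n_act > 1:
        r_coal = 0.0
        for d in range(n_demes):
            r_coal += cnt[d] * (cnt[d] - 1) / 2.0
        r_mig = n_act * M / 2.0
        r_mut = n_act * theta / 2.0
        u = np.random.random() * (r_coal + r_mig + r_mut)
        if u < r_coal:
            # pick deme weighted by pair count
            acc = 0.0
            dsel = -1
            for d in range(n_demes):
                acc += cnt[d] * (cnt[d] - 1) / 2.0
                if u < acc:
                    dsel = d
                    break
            # pick two distinct active lineages in deme dsel
            j1 = np.random.randint(cnt[dsel])
            j2 = np.random.randint(cnt[dsel] - 1)
            if j2 >= j1:
                j2 += 1
            i1 = -1
            i2 = -1
            seen = 0
            for i in range(n_act):
                if act_deme[i] == dsel:
                    if seen == j1:
                        i1 = i
                    if seen == j2:
                        i2 = i
                    seen += 1
            parent[act_node[i1]] = next_node
            parent[act_node[i2]] = next_node
            act_node[i1] = next_node
            next_node += 1
            # remove lineage i2
            act_node[i2] = act_node[n_act - 1]
            act_deme[i2] = act_deme[n_act - 1]
            n_act -= 1
            cnt[dsel] -= 1
        elif u < r_coal + r_mig:
            i = np.random.randint(n_act)
            d_old = act_deme[i]
            d_new = np.random.randint(n_demes - 1)
            if d_new >= d_old:
                d_new += 1
            act_deme[i] = d_new
            cnt[d_old] -= 1
            cnt[d_new] += 1
        else:
            i = np.random.randint(n_act)
            node = act_node[i]
            if model == 0:
                fresh[node] = nxt_allele
                nxt_allele += 1
            else:
                step = 1
                if model == 2 and np.random.random() >= p_ss:
                    step = 1 + int(
                        np.log(np.random.random()) / np.log(1.0 - q)
                    )
                if np.random.random() < 0.5:
                    step = -step
                net_step[node] += step
    # resolve states root-down (parent id always exceeds child id)
    state = np.empty(n_nodes, dtype=np.int64)
    root = next_node - 1
    state[root] = 100
    for node in range(root - 1, -1, -1):
        p = parent[node]
        if fresh[node] >= 0:
            state[node] = fresh[node]
        else:
            state[node] = state[p] + net_step[node]
    return state[:K]


# ---------------------------------------------------------------------------
# python-level API


def sample_panmictic(
    n_genes: int, theta: float, model: str = "smm", p_ss: float = 0.7,
    variance: float = 30.0, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one equilibrium sample of ``n_genes`` allele states."""
    rng = rng or np.random.default_rng()
    code, p_ss, q = _model_params(model, p_ss, variance)
    seed = int(rng.integers(2**31 - 1))
    return np.asarray(
        _pan_sample(n_genes, float(theta), code, p_ss, q, seed)
    )


def sample_island(
    n_sampled: int, genes_per_deme: int, M: float, theta: float,
    n_demes: int = 100, model: str = "smm", p_ss: float = 0.7,
    variance: float = 30.0, rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """One locus from the finite-island model; list of per-deme gene arrays."""
    rng = rng or np.random.default_rng()
    code, p_ss, q = _model_params(model, p_ss, variance)
    seed = int(rng.integers(2**31 - 1))
    states = np.asarray(
        _island_locus(n_demes, genes_per_deme, n_sampled, float(M),
                      float(theta), code, p_ss, q, seed)
    )
    return [
        states[d * genes_per_deme:(d + 1) * genes_per_deme]
        for d in range(n_sampled)
    ]


def ewens_theta_guess(n_genes: int, k_obs: int) -> float:
    """Solve Ewens' E[K] = sum theta/(theta+i) for theta (IAM guess)."""
    if k_obs <= 1:
        return 1e-3
    if k_obs >= n_genes:
        return 1e3
    lo, hi = 1e-4, 1e4
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        ek = np.sum(mid / (mid + np.arange(n_genes)))
        if ek < k_obs:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


@dataclass
class ConditionalHet:
    """Equilibrium-heterozygosity distribution conditional on allele count."""

    het: np.ndarray
    theta: float
    attempts: int
    low_acceptance: bool


def tune_theta_for_mean_k(
    n_genes: int, k_target: float, model: str = "tpm", p_ss: float = 0.7,
    variance: float = 30.0, rng: np.random.Generator | None = None,
    batch: int = 128, rounds: int = 6,
) -> float:
    """theta whose equilibrium samples of ``n_genes`` average ``k_target``
    alleles (Ewens-formula start, multiplicative adaptation on batches)."""
    rng = rng or np.random.default_rng()
    code, p_ss_f, q = _model_params(model, p_ss, variance)
    theta = ewens_theta_guess(n_genes, int(round(k_target)))
    for _ in range(rounds):
        mean_k = _pan_batch_k(
            batch, n_genes, theta, code, p_ss_f, q,
            int(rng.integers(2**31 - 1)),
        )
        if abs(mean_k - k_target) < 0.15:
            break
        ratio = (k_target - 1.0) / max(mean_k - 1.0, 1e-3)
        theta *= float(np.clip(ratio, 0.25, 4.0))
        theta = float(np.clip(theta, 1e-4, 1e4))
    return float(theta)


def equilibrium_het_given_k(
    n_genes: int, k_obs: int, model: str = "tpm", p_ss: float = 0.7,
    variance: float = 30.0, n_iter: int = 1000,
    rng: np.random.Generator | None = None, max_attempt_factor: int = 200,
    theta: float | None = None,
) -> ConditionalHet:
    """Simulate H at mutation-drift equilibrium conditional on ``k_obs``.

    Conditioning is by rejection on exact allele count.  When ``theta`` is
    None it is tuned so the expected allele count matches ``k_obs``;
    passing a dataset-wide theta (all loci share one mutation-drift
    regime) avoids the per-locus tuning bias.  Acceptance below 1% of
    attempts is flagged.
    """
    rng = rng or np.random.default_rng()
    code, p_ss_f, q = _model_params(model, p_ss, variance)
    if theta is None:
        theta = tune_theta_for_mean_k(
            n_genes, k_obs, model, p_ss, variance, rng
        )
    max_attempts = max_attempt_factor * n_iter
    het, attempts = _pan_conditional(
        n_iter, max_attempts, n_genes, k_obs, theta, code, p_ss_f, q,
        int(rng.integers(2**31 - 1)),
    )
    het = np.asarray(het)
    low = het.size < n_iter or (attempts > 0 and het.size / attempts < 0.01)
    return ConditionalHet(het, theta, int(attempts), bool(low))
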