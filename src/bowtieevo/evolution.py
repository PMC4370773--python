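"""Mutation-selection dynamics for layered linear networks.

Each generation the population of ``N`` individuals (each a chain of ``L``
``D x D`` matrices) is duplicated; one copy is kept intact and each matrix
element of the other copy mutates independently with probability ``p``
(product rule: multiply by ``Normal(1, sigma)``; sum rule: add
``Normal(0, sigma)``).  All ``2N`` individuals are scored against the goal by
``F = -||A(L)...A(1) - G||`` (sum of squared entries) and ``N`` survivors are
drawn by tournament selection.  The loop stops when the mean population
fitness comes within ``convergence_tolerance`` of the optimum (0) or at the
generation cap.

The engine exploits two structural facts without changing the dynamics: an
individual whose copy received no mutation has the same fitness as its parent
(fitness is cached and only mutated copies are re-evaluated), and per-element
Bernoulli mutation is sampled sparsely (a binomial count per individual plus
distinct element positions).  Under temporal noise neither shortcut is valid
and every individual is re-evaluated each generation with fresh noise.

:func:`run_ensemble` advances many independent replicate runs in lock-step,
each with its own random stream, so that array operations are batched across
runs; :func:`run_evolution` is the single-run case of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .goals import GoalMatrix
from .network import LayeredLinearNetwork

__all__ = [
    "MutationConfig",
    "EvolutionConfig",
    "RunRecord",
    "init_population",
    "mutate",
    "tournament_select",
    "noisy_fitness",
    "run_evolution",
    "run_ensemble",
    "fluctuation_magnitude",
]


@dataclass(frozen=True)
class MutationConfig:
    """Mutation rule and rates.

    ``per_element_rate=None`` means the default 0.2 / (L * D**2): on average
    20% of individuals carry a fresh mutation each generation, so beneficial
    mutants reproduce for several generations before being hit again.
    """

    rule: Literal["product", "sum"] = "product"
    per_element_rate: float | None = None
    size: float = 0.1

    def __post_init__(self) -> None:
        if self.rule not in ("product", "sum"):
            raise ValueError("mutation rule must be 'product' or 'sum'")
        if self.per_element_rate is not None and not 0 <= self.per_element_rate <= 1:
            raise ValueError("per_element_rate must be in [0, 1]")
        if self.size < 0:
            raise ValueError("mutation size must be non-negative")

    def rate_for(self, n_layers: int, d: int) -> float:
        if self.per_element_rate is not None:
            return self.per_element_rate
        return 0.2 / (n_layers * d * d)


@dataclass(frozen=True)
class EvolutionConfig:
    """All evolutionary-dynamics parameters of one run.

    ``init_range`` defaults to uniform (0, 0.1): interactions start weak
    relative to the goal scale (entries of 10), so the input-output function
    must be built up by selective amplification.  During that growth phase
    multiplicative mutations preferentially amplify the strongest paths, which
    is what concentrates signal flow onto few nodes; an initialization whose
    chain product already matches the goal scale removes the growth phase and
    no bow-tie forms on accessible timescales.
    """

    population_size: int = 100
    mutation: MutationConfig = field(default_factory=MutationConfig)
    tournament_size: int = 4
    max_generations: int = 100_000
    convergence_tolerance: float = 0.01
    temporal_noise_sigma: float = 0.0
    seed: int = 0
    init_range: tuple[float, float] = (0.0, 0.1)
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be at least 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.temporal_noise_sigma < 0:
            raise ValueError("temporal_noise_sigma must be non-negative")


@dataclass
class RunRecord:
    """One simulation trajectory and its final population.

    ``mean_fitness[g]`` / ``best_fitness[g]`` are population statistics after
    the (g+1)-th mutation-selection step; the initial population's statistics
    are kept separately.  ``converged`` means the mean population fitness was
    within ``convergence_tolerance`` of 0 when the run stopped.
    """

    mean_fitness: np.ndarray
    best_fitness: np.ndarray
    final_population: np.ndarray  # (N, L, D, D)
    final_fitness: np.ndarray  # (N,)
    generations_run: int
    converged: bool
    config: EvolutionConfig
    seed: int
    goal: GoalMatrix
    initial_mean_fitness: float = np.nan
    initial_best_fitness: float = np.nan

    def best_network(self) -> LayeredLinearNetwork:
        """The fittest individual of the final population, as a network."""
        i = int(np.argmax(self.final_fitness))
        return LayeredLinearNetwork(
            matrices=tuple(self.final_population[i]),
            metadata={"seed": self.seed, "generation": self.generations_run},
        )


def init_population(
    cfg: EvolutionConfig, n_layers: int, d: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Initial population: ``N * L * D**2`` iid uniform draws on ``init_range``.

    Returns an array of shape ``(N, L, D, D)``; deterministic given the
    config seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    return rng.uniform(lo, hi, size=(cfg.population_size, n_layers, d, d))


def mutate(
    net: LayeredLinearNetwork, m: MutationConfig, rng: np.random.Generator
) -> LayeredLinearNetwork:
    """Return a mutated copy of a single network.

    Each matrix element is independently selected with probability
    ``per_element_rate``; selected elements are multiplied by ``Normal(1,
    size)`` (product rule) or incremented by ``Normal(0, size)`` (sum rule).
    An exact zero is a fixed point of product-rule mutation.
    """
    d = net.matrices[0].shape[0]
    p = m.rate_for(net.n_layers, d)
    out = []
    for mat in net.matrices:
        mat = mat.copy()
        mask = rng.random(mat.shape) < p
        k = int(mask.sum())
        if k:
            if m.rule == "product":
                mat[mask] *= rng.normal(1.0, m.size, size=k)
            else:
                mat[mask] += rng.normal(0.0, m.size, size=k)
        out.append(mat)
    return LayeredLinearNetwork(matrices=tuple(out), metadata=dict(net.metadata))


def tournament_select(
    fitnesses: np.ndarray,
    s: int,
    n_select: int,
    rng: np.random.Generator,
    pool: Sequence | None = None,
):
    """Tournament selection: each slot gets the fittest of ``s`` uniform draws.

    Draws are uniform over the pool with replacement (both within a group and
    across slots); ties are broken uniformly at random because the group order
    is itself random.  Returns winner indices into the pool, or the selected
    pool members if ``pool`` is given.
    """
    if s < 1:
        raise ValueError("tournament size must be at least 1")
    fitnesses = np.asarray(fitnesses, dtype=float)
    draws = rng.integers(0, len(fitnesses), size=(n_select, s))
    winners = draws[np.arange(n_select), np.argmax(fitnesses[draws], axis=1)]
    if pool is not None:
        return [pool[i] for i in winners]
    return winners


def noisy_fitness(
    net: LayeredLinearNetwork,
    goal: GoalMatrix | np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> float:
    """Fitness under temporal noise: one fresh noise realization per call.

    ``F = -|| (A(L)+eps_L) ... (A(1)+eps_1) - (G+eps_G) ||`` with all noise
    entries iid ``Normal(0, sigma)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    g = goal.values if isinstance(goal, GoalMatrix) else np.asarray(goal, float)
    p = None
    for mat in net.matrices:
        a = mat + rng.normal(0.0, sigma, size=mat.shape) if sigma else mat
        p = a if p is None else a @ p
    gn = g + rng.normal(0.0, sigma, size=g.shape) if sigma else g
    d = p - gn
    return -float(np.sum(d * d))


def fluctuation_magnitude(record: RunRecord, window: int) -> float:
    """Relative fitness fluctuation std/|mean| over the last ``window`` generations.

    Measured on the mean-population-fitness trajectory after the run has
    settled; used to quantify the overall effect of temporal noise.
    """
    traj = record.mean_fitness
    if window > len(traj):
        raise ValueError(f"window {window} exceeds trajectory length {len(traj)}")
    tail = traj[-window:]
    m = np.mean(tail)
    if m == 0.0:
        return 0.0
    return float(np.std(tail) / abs(m))


# ---------------------------------------------------------------------------
# engine

#: generations of randomness drawn per run per batch; a fixed constant so a
#: run's random stream does not depend on which other runs it is batched with
_CHUNK = 128


def _chain_product(mats: np.ndarray) -> np.ndarray:
    """Product A(L)...A(1) for a batch of chains, shape (..., L, D, D)."""
    p = mats[..., -1, :, :]
    for l in range(mats.shape[-3] - 2, -1, -1):
        p = p @ mats[..., l, :, :]
    return p


def _batch_fitness(mats: np.ndarray, goals: np.ndarray) -> np.ndarray:
    d = _chain_product(mats) - goals
    return -np.einsum("...ij,...ij->...", d, d)


def run_ensemble(
    cfg: EvolutionConfig,
    goals: GoalMatrix | Sequence[GoalMatrix],
    n_layers: int,
    seeds: Sequence[int] | None = None,
) -> list[RunRecord]:
    """Run independent replicate simulations advanced in lock-step.

    ``goals`` is either one goal shared by all runs or one goal per run;
    ``seeds`` gives each run its own random stream (default: ``cfg.seed + i``).
    Results are identical to running each replicate on its own with the same
    seed.  Returns one :class:`RunRecord` per run, in input order.
    """
    if isinstance(goals, GoalMatrix):
        if seeds is None:
            seeds = [cfg.seed]
        goal_list = [goals] * len(seeds)
    else:
        goal_list = list(goals)
        if seeds is None:
            seeds = [cfg.seed + i for i in range(len(goal_list))]
        if len(goal_list) != len(seeds):
            raise ValueError("need one goal per seed")
    n_runs = len(seeds)
    d = goal_list[0].d_output
    for g in goal_list:
        if g.values.shape != (d, d):
            raise ValueError(
                "the ensemble engine requires square goals of equal size; "
                f"got {g.values.shape}"
            )

    n = cfg.population_size
    L = n_layers
    m_flat = L * d * d
    p = cfg.mutation.rate_for(L, d)
    sigma = cfg.mutation.size
    product_rule = cfg.mutation.rule == "product"
    s = cfg.tournament_size
    tol = cfg.convergence_tolerance
    noise = cfg.temporal_noise_sigma
    cap = cfg.max_generations

    rngs = [np.random.default_rng(seed) for seed in seeds]
    goal_arr = np.stack([g.values for g in goal_list])  # (R, D, D)

    pop = np.empty((n_runs, n, L, d, d))
    for i, rng in enumerate(rngs):
        pop[i] = init_population(cfg, L, d, rng)
    if noise:
        fit = np.empty((n_runs, n))
        for i, rng in enumerate(rngs):
            eps = rng.normal(0.0, noise, size=(n, L, d, d))
            eg = rng.normal(0.0, noise, size=(n, d, d))
            fit[i] = _batch_fitness(pop[i] + eps, goal_arr[i] + eg)
    else:
        fit = _batch_fitness(pop, goal_arr[:, None])

    mean_traj = np.empty((n_runs, cap))
    best_traj = np.empty((n_runs, cap))
    init_mean = fit.mean(axis=1)
    init_best = fit.max(axis=1)
    gens_run = np.full(n_runs, 0, dtype=int)
    converged = np.zeros(n_runs, dtype=bool)
    final_pop = [None] * n_runs
    final_fit = [None] * n_runs

    run_ids = np.arange(n_runs)
    goal_act = goal_arr
    rng_act = rngs
    frozen = np.zeros(n_runs, dtype=bool)

    def _capture(j: int) -> None:
        rid = run_ids[j]
        converged[rid] = True
        final_pop[rid] = pop[j].copy()
        final_fit[rid] = fit[j].copy()

    # a run already at the optimum needs no generations at all
    if cfg.early_stop and not noise:
        conv0 = init_mean >= -tol
        for j in np.nonzero(conv0)[0]:
            _capture(j)
        frozen |= conv0

    # Randomness is drawn in fixed-size chunks per run (each run from its own
    # stream, in a fixed per-chunk order), so the generation loop is pure
    # array work.  A run that converges keeps its captured state; it is
    # carried along until the chunk ends and dropped before the next chunk,
    # which keeps every run's stream consumption independent of the others.
    gen = 0
    while gen < cap:
        if frozen.any():
            keep = ~frozen
            pop = pop[keep]
            fit = fit[keep]
            run_ids = run_ids[keep]
            goal_act = goal_act[keep]
            rng_act = [r for r, k in zip(rng_act, keep) if k]
            frozen = frozen[keep]
        ra = len(run_ids)
        if ra == 0:
            break
        chunk = min(_CHUNK, cap - gen)

        # --- one chunk of randomness per run ---
        draws_b = np.empty((ra, chunk, n, s), dtype=np.int64)
        parts = []
        for j, rng in enumerate(rng_act):
            c = rng.binomial(m_flat, p, size=(chunk, n))
            tot = int(c.sum())
            pos = rng.integers(0, m_flat, size=tot)
            fac = rng.normal(1.0 if product_rule else 0.0, sigma, size=tot)
            draws_b[j] = rng.integers(0, 2 * n, size=(chunk, n, s))
            slot = np.repeat(np.arange(chunk * n), c.reshape(-1))
            # element-wise Bernoulli means distinct positions per individual;
            # redraw the (rare) collisions
            key = slot * m_flat + pos
            while True:
                order = np.argsort(key, kind="stable")
                sk = key[order]
                dup = np.zeros(tot, dtype=bool)
                dup[1:] = sk[1:] == sk[:-1]
                if not dup.any():
                    break
                bad = order[dup]
                pos[bad] = rng.integers(0, m_flat, size=bad.size)
                key[bad] = slot[bad] * m_flat + pos[bad]
            parts.append((slot // n, np.full(tot, j), slot % n, pos, fac))
        a_gen = np.concatenate([x[0] for x in parts])
        order = np.argsort(a_gen, kind="stable")
        a_gen = a_gen[order]
        a_run = np.concatenate([x[1] for x in parts])[order]
        a_ind = np.concatenate([x[2] for x in parts])[order]
        a_pos = np.concatenate([x[3] for x in parts])[order]
        a_fac = np.concatenate([x[4] for x in parts])[order]
        offsets = np.searchsorted(a_gen, np.arange(chunk + 1))
        ar_col = np.arange(ra)[:, None]

        for g_local in range(chunk):
            lo, hi = offsets[g_local], offsets[g_local + 1]
            mrun = a_run[lo:hi]
            mind = a_ind[lo:hi]

            if hi > lo:
                # changed children: one row per (run, individual) with >=1 hit
                child_key = mrun * n + mind
                uniq, inverse = np.unique(child_key, return_inverse=True)
                crun = uniq // n
                cind = uniq % n
                children = pop[crun, cind].copy()  # (K, L, D, D)
                cflat = children.reshape(len(uniq), m_flat)
                if product_rule:
                    cflat[inverse, a_pos[lo:hi]] *= a_fac[lo:hi]
                else:
                    cflat[inverse, a_pos[lo:hi]] += a_fac[lo:hi]
            else:
                crun = cind = np.empty(0, dtype=int)
                children = np.empty((0, L, d, d))

            # --- fitness of the 2N pool (parents cached unless noisy) ---
            draws = draws_b[:, g_local]
            if noise:
                pool = np.concatenate([pop, pop], axis=1)  # (Ra, 2N, L, D, D)
                if len(crun):
                    pool[crun, n + cind] = children
                pool_fit = np.empty((ra, 2 * n))
                for j, rng in enumerate(rng_act):
                    eps = rng.normal(0.0, noise, size=(2 * n, L, d, d))
                    eg = rng.normal(0.0, noise, size=(2 * n, d, d))
                    pool_fit[j] = _batch_fitness(pool[j] + eps, goal_act[j] + eg)
            else:
                pool_fit = np.concatenate([fit, fit], axis=1)  # (Ra, 2N)
                if len(crun):
                    pool_fit[crun, n + cind] = _batch_fitness(
                        children, goal_act[crun]
                    )

            # --- tournament selection ---
            gathered = pool_fit[np.arange(ra)[:, None, None], draws]  # (Ra, N, s)
            sel = np.argmax(gathered, axis=2)
            winners = np.take_along_axis(draws, sel[:, :, None], axis=2)[:, :, 0]

            # --- next generation ---
            src = winners % n
            new_pop = pop[ar_col, src]
            if len(crun):
                child_map = np.full((ra, n), -1, dtype=int)
                child_map[crun, cind] = np.arange(len(crun))
                cm = np.where(winners >= n, child_map[ar_col, src], -1)
                hit = cm >= 0
                if hit.any():
                    new_pop[hit] = children[cm[hit]]
            pop = new_pop
            fit = np.take_along_axis(pool_fit, winners, axis=1)

            live = ~frozen
            mean_f = fit.mean(axis=1)
            ids = run_ids[live]
            mean_traj[ids, gen + g_local] = mean_f[live]
            best_traj[ids, gen + g_local] = fit.max(axis=1)[live]
            gens_run[ids] = gen + g_local + 1

            if cfg.early_stop:
                newly = live & (mean_f >= -tol)
                if newly.any():
                    for j in np.nonzero(newly)[0]:
                        _capture(j)
                    frozen |= newly
                    if frozen.all():
                        break
        gen += chunk
        if frozen.all():
            break

    # runs that ran to the generation cap
    for j in np.nonzero(~frozen)[0]:
        rid = run_ids[j]
        final_pop[rid] = pop[j]
        final_fit[rid] = fit[j]
        if fit[j].mean() >= -tol:
            converged[rid] = True

    records = []
    for i in range(n_runs):
        g = gens_run[i]
        records.append(
            RunRecord(
                mean_fitness=mean_traj[i, :g].copy(),
                best_fitness=best_traj[i, :g].copy(),
                final_population=final_pop[i],
                final_fitness=final_fit[i],
                generations_run=int(g),
                converged=bool(converged[i]),
                config=replace(cfg, seed=int(seeds[i])),
                seed=int(seeds[i]),
                goal=goal_list[i],
                initial_mean_fitness=float(init_mean[i]),
                initial_best_fitness=float(init_best[i]),
            )
        )
    return records


def run_evolution(
    cfg: EvolutionConfig, goal: GoalMatrix, n_layers: int
) -> RunRecord:
    """Evolve one population towards ``goal``; fully reproducible from the seed."""
    return run_ensemble(cfg, goal, n_layers, seeds=[cfg.seed])[0]
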