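"""The 4-pixel retina: a nonlinear test of waist-equals-effective-rank.

A 2x2 Boolean image feeds a 4-4-4-4 perceptron (3 weight layers with node
thresholds and transfer ``f(x) = (1 + tanh x) / 2``).  The four target
outputs — object on the left, object on the right, left AND right, left OR
right — are functions of just two features of the image (left/right column
occupancy), so the task has an effective rank of 2 even though there are 4
inputs.  Evolution with product-rule mutations typically discovers this and
leaves only two active nodes in an intermediate layer.

Activity is scored per *weight* here: each weight is zeroed in turn and its
relative fitness effect measured; a node is inactive iff all its outgoing
weights are negligible.  Thresholds are never knocked out — a node with no
inputs can still act as a constant bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .analysis import FITNESS_FLOOR, LayerActivity, _waist_of_counts
from .evolution import EvolutionConfig, MutationConfig

__all__ = [
    "RetinaNetwork",
    "RetinaGoal",
    "RetinaRunRecord",
    "retina_goal_table",
    "retina_forward",
    "retina_fitness",
    "retina_config",
    "run_retina_evolution",
    "run_retina_ensemble",
    "retina_active_nodes",
]

#: geometry of the retina problem: 4 node layers of width 4, 3 weight layers
N_WEIGHT_LAYERS = 3
WIDTH = 4
#: pixel order within the input vector: top-left, top-right, bottom-left,
#: bottom-right; the left column is pixels {0, 2}.
LEFT_PIXELS = (0, 2)
RIGHT_PIXELS = (1, 3)


def transfer(x):
    """The node transfer function f(x) = (1 + tanh x) / 2, with range (0, 1)."""
    return 0.5 * (1.0 + np.tanh(x))


@dataclass(frozen=True)
class RetinaNetwork:
    """Weights ``A(l)`` (3 matrices, 4x4) and thresholds ``T(l+1)`` (3 vectors)."""

    weights: np.ndarray  # (3, 4, 4)
    thresholds: np.ndarray  # (3, 4)
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        t = np.asarray(self.thresholds, float)
        if w.shape != (N_WEIGHT_LAYERS, WIDTH, WIDTH):
            raise ValueError(f"weights must have shape (3, 4, 4), got {w.shape}")
        if t.shape != (N_WEIGHT_LAYERS, WIDTH):
            raise ValueError(f"thresholds must have shape (3, 4), got {t.shape}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "thresholds", t)


@dataclass(frozen=True)
class RetinaGoal:
    """Truth table of the task: 16 input patterns -> 4 Boolean targets."""

    inputs: np.ndarray  # (16, 4) 0/1
    targets: np.ndarray  # (16, 4) 0/1


def retina_goal_table() -> RetinaGoal:
    """All 16 pixel patterns with targets (left, right, left AND right, left OR right)."""
    n = 2**WIDTH
    inputs = ((np.arange(n)[:, None] >> np.arange(WIDTH - 1, -1, -1)) & 1).astype(float)
    left = np.clip(inputs[:, LEFT_PIXELS].sum(axis=1), 0, 1)
    right = np.clip(inputs[:, RIGHT_PIXELS].sum(axis=1), 0, 1)
    targets = np.column_stack([left, right, left * right, np.clip(left + right, 0, 1)])
    return RetinaGoal(inputs=inputs, targets=targets)


def retina_forward(
    net: RetinaNetwork, pixels, return_intermediates: bool = False
):
    """Forward pass: three applications of ``u <- f(A u - T)``."""
    u = np.asarray(pixels, dtype=float)
    squeeze = u.ndim == 1
    u = np.atleast_2d(u).T  # (4, n_patterns)
    layers = [u]
    for l in range(N_WEIGHT_LAYERS):
        u = transfer(net.weights[l] @ u - net.thresholds[l][:, None])
        layers.append(u)
    out = u[:, 0] if squeeze else u.T
    if return_intermediates:
        return out, layers
    return out


def retina_fitness(
    net: RetinaNetwork,
    goal: RetinaGoal | None = None,
    pattern_reduction: Literal["sum", "mean"] = "sum",
) -> float:
    """F = -(1/16) sum over patterns of the (summed) squared output errors.

    The per-pattern error is the sum of squared differences over the 4
    outputs by default (``pattern_reduction="mean"`` divides by 4 as well);
    either way the result is averaged over the 16 input patterns.  Strictly
    negative for any finite-weight network, since f never reaches 0 or 1:
    for Boolean targets the output error is evaluated as
    ``|f(z) - t| = expit(-2z)`` (t = 1) or ``expit(2z)`` (t = 0), which stays
    representable long after ``(1 + tanh z)/2`` would round to exactly 0 or 1
    in floating point.  Without this the selection gradient — and with it the
    pruning pressure on superfluous weights — artificially vanishes once
    networks saturate.
    """
    if goal is None:
        goal = retina_goal_table()
    err2 = _output_sq_errors(
        net.weights[None], net.thresholds[None], goal.inputs.T, goal.targets.T
    )[0]
    per_pattern = err2.sum(axis=0)  # (16,)
    if pattern_reduction == "mean":
        per_pattern = per_pattern / goal.targets.shape[1]
    return -float(per_pattern.mean())


def _output_sq_errors(
    w: np.ndarray, t: np.ndarray, inputs_t: np.ndarray, targets_t: np.ndarray
) -> np.ndarray:
    """Squared output errors, shape (batch, 4, 16); stable for Boolean targets.

    Uses the sign trick |f(z) - t| = sigmoid(-2z) (t = 1) / sigmoid(2z)
    (t = 0) and evaluates the sigmoid as 1/(1 + e^-x) with in-place ufuncs;
    the overflow of e^-x for strongly wrong outputs correctly saturates the
    error at 1.
    """
    sign = np.where(targets_t > 0.5, -2.0, 2.0)
    u = np.broadcast_to(inputs_t, (w.shape[0],) + inputs_t.shape)
    for l in range(N_WEIGHT_LAYERS - 1):
        z = w[:, l] @ u
        z -= t[:, l, :, None]
        np.tanh(z, out=z)
        z += 1.0
        z *= 0.5
        u = z
    z = w[:, -1] @ u
    z -= t[:, -1, :, None]
    np.multiply(z, sign, out=z)
    with np.errstate(over="ignore"):
        np.negative(z, out=z)
        np.exp(z, out=z)
        z += 1.0
        np.reciprocal(z, out=z)
    np.square(z, out=z)
    return z


def retina_config(
    rule: Literal["product", "sum"] = "product",
    seed: int = 0,
    max_generations: int = 10_000,
    **overrides,
) -> EvolutionConfig:
    """Evolution parameters of the retina experiment.

    Per-term mutation probability 0.2, product multiplier Normal(1, 0.5)
    (sign-flip probability ~ Phi(-2) ~ 0.02) or additive Normal(0, 0.5) for
    the sum-rule control, N = 100, weights and thresholds initialized
    uniformly on [-2, 2], a fixed budget of 10^4 generations, and inclusion
    of a run in the analysis only if its best individual ends within 1e-4 of
    the optimum.
    """
    defaults = dict(
        population_size=100,
        mutation=MutationConfig(rule=rule, per_element_rate=0.2, size=0.5),
        tournament_size=4,
        max_generations=max_generations,
        convergence_tolerance=1e-4,
        seed=seed,
        init_range=(-2.0, 2.0),
        early_stop=False,
    )
    defaults.update(overrides)
    return EvolutionConfig(**defaults)


@dataclass
class RetinaRunRecord:
    """One retina simulation trajectory and its final population."""

    mean_fitness: np.ndarray
    best_fitness: np.ndarray
    final_weights: np.ndarray  # (N, 3, 4, 4)
    final_thresholds: np.ndarray  # (N, 3, 4)
    final_fitness: np.ndarray
    generations_run: int
    converged: bool  # best individual within tolerance of the optimum
    config: EvolutionConfig
    seed: int
    goal: RetinaGoal = field(default_factory=retina_goal_table)

    def best_network(self) -> RetinaNetwork:
        i = int(np.argmax(self.final_fitness))
        return RetinaNetwork(
            weights=self.final_weights[i],
            thresholds=self.final_thresholds[i],
            metadata={"seed": self.seed, "generation": self.generations_run},
        )


_N_WEIGHTS = N_WEIGHT_LAYERS * WIDTH * WIDTH  # 48
_N_TERMS = _N_WEIGHTS + N_WEIGHT_LAYERS * WIDTH  # 60: weights + thresholds


def _batch_retina_fitness(
    geno: np.ndarray, inputs_t: np.ndarray, targets_t: np.ndarray
) -> np.ndarray:
    """Fitness of a (B, 60) genotype batch; inputs_t/targets_t are (4, 16)."""
    b = geno.shape[0]
    w = geno[:, :_N_WEIGHTS].reshape(b, N_WEIGHT_LAYERS, WIDTH, WIDTH)
    t = geno[:, _N_WEIGHTS:].reshape(b, N_WEIGHT_LAYERS, WIDTH)
    err2 = _output_sq_errors(w, t, inputs_t, targets_t)
    return -err2.sum(axis=1).mean(axis=1)


def run_retina_ensemble(
    cfg: EvolutionConfig, seeds: Sequence[int] | None = None
) -> list[RetinaRunRecord]:
    """Replicate retina runs advanced in lock-step, one random stream per run.

    Same duplicate -> mutate -> evaluate -> tournament-select loop as the
    linear engine, with mutations applied to weights *and* thresholds.  Runs
    use the full generation budget (no early stopping by default): the
    sparsification that carves out the bow-tie continues long after fitness
    has converged.
    """
    if seeds is None:
        seeds = [cfg.seed]
    n = cfg.population_size
    p = cfg.mutation.per_element_rate
    if p is None:
        p = 0.2
    sigma = cfg.mutation.size
    product_rule = cfg.mutation.rule == "product"
    s = cfg.tournament_size
    cap = cfg.max_generations
    lo, hi = cfg.init_range
    n_runs = len(seeds)

    goal = retina_goal_table()
    inputs_t = goal.inputs.T.copy()  # (4, 16)
    targets_t = goal.targets.T.copy()

    rngs = [np.random.default_rng(seed) for seed in seeds]
    geno = np.empty((n_runs, n, _N_TERMS))
    for i, rng in enumerate(rngs):
        geno[i] = rng.uniform(lo, hi, size=(n, _N_TERMS))
    fit = _batch_retina_fitness(
        geno.reshape(-1, _N_TERMS), inputs_t, targets_t
    ).reshape(n_runs, n)

    mean_traj = np.empty((n_runs, cap))
    best_traj = np.empty((n_runs, cap))
    ar = np.arange(n_runs)

    # randomness is drawn in fixed-size per-run chunks (each run from its own
    # stream) so the generation loop is almost pure array work
    chunk_size = 32
    gen = 0
    while gen < cap:
        chunk = min(chunk_size, cap - gen)
        masks = np.empty((n_runs, chunk, n, _N_TERMS), dtype=bool)
        facs = []
        draws_b = np.empty((n_runs, chunk, n, s), dtype=np.int64)
        for i, rng in enumerate(rngs):
            masks[i] = rng.random((chunk, n, _N_TERMS)) < p
            facs.append(
                rng.normal(1.0 if product_rule else 0.0, sigma, size=int(masks[i].sum()))
            )
            draws_b[i] = rng.integers(0, 2 * n, size=(chunk, n, s))
        offsets = [np.concatenate([[0], masks[i].reshape(chunk, -1).sum(1).cumsum()])
                   for i in range(n_runs)]

        for g in range(chunk):
            # mutation: dense Bernoulli masks (at p = 0.2 almost every copy mutates)
            children = geno.copy()
            for i in range(n_runs):
                fac = facs[i][offsets[i][g] : offsets[i][g + 1]]
                if product_rule:
                    children[i][masks[i, g]] *= fac
                else:
                    children[i][masks[i, g]] += fac
            cfit = _batch_retina_fitness(
                children.reshape(-1, _N_TERMS), inputs_t, targets_t
            ).reshape(n_runs, n)

            draws = draws_b[:, g]
            pool_fit = np.concatenate([fit, cfit], axis=1)  # (R, 2N)
            gathered = pool_fit[ar[:, None, None], draws]
            sel = np.argmax(gathered, axis=2)
            winners = np.take_along_axis(draws, sel[:, :, None], axis=2)[:, :, 0]

            src = winners % n
            from_child = winners >= n
            new_geno = geno[ar[:, None], src]
            child_sel = children[ar[:, None], src]
            new_geno[from_child] = child_sel[from_child]
            geno = new_geno
            fit = np.take_along_axis(pool_fit, winners, axis=1)

            mean_traj[:, gen + g] = fit.mean(axis=1)
            best_traj[:, gen + g] = fit.max(axis=1)
        gen += chunk

    records = []
    for i in range(n_runs):
        best = float(fit[i].max())
        records.append(
            RetinaRunRecord(
                mean_fitness=mean_traj[i].copy(),
                best_fitness=best_traj[i].copy(),
                final_weights=geno[i, :, :_N_WEIGHTS].reshape(
                    n, N_WEIGHT_LAYERS, WIDTH, WIDTH
                ),
                final_thresholds=geno[i, :, _N_WEIGHTS:].reshape(
                    n, N_WEIGHT_LAYERS, WIDTH
                ),
                final_fitness=fit[i].copy(),
                generations_run=cap,
                converged=best >= -cfg.convergence_tolerance,
                config=replace(cfg, seed=int(seeds[i])),
                seed=int(seeds[i]),
                goal=goal,
            )
        )
    return records


def run_retina_evolution(cfg: EvolutionConfig) -> RetinaRunRecord:
    """Evolve one retina population; reproducible from the config seed."""
    return run_retina_ensemble(cfg, seeds=[cfg.seed])[0]


def retina_active_nodes(
    net: RetinaNetwork,
    goal: RetinaGoal | None = None,
    threshold: float = 1e-4,
) -> LayerActivity:
    """Per-weight knockout scoring of a retina network.

    Each weight ``A(l)[i, j]`` is zeroed in turn and its fitness effect
    ``dF`` recorded; effects are compared between the weights of the same
    layer, and a weight is negligible if its effect is below ``threshold``
    relative to the largest effect in its layer.  A node is inactive iff its
    entire set of outgoing weights is negligible; output-layer nodes (which
    have no outgoing weights) carry the network outputs and are always
    counted active.  Thresholds are never knocked out.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if goal is None:
        goal = retina_goal_table()
    f0 = retina_fitness(net, goal)
    df = np.empty((N_WEIGHT_LAYERS, WIDTH, WIDTH))
    for l in range(N_WEIGHT_LAYERS):
        for i in range(WIDTH):
            for j in range(WIDTH):
                if net.weights[l, i, j] == 0.0:
                    df[l, i, j] = 0.0
                    continue
                w = net.weights.copy()
                w[l, i, j] = 0.0
                fk = retina_fitness(RetinaNetwork(w, net.thresholds), goal)
                df[l, i, j] = abs(f0 - fk)
    rel = df / np.maximum(
        df.reshape(N_WEIGHT_LAYERS, -1).max(axis=1)[:, None, None], FITNESS_FLOOR
    )
    significant = rel >= threshold
    counts = []
    effects = []
    for layer in range(N_WEIGHT_LAYERS):  # node layers 1..3: outgoing = column
        counts.append(int(significant[layer].any(axis=0).sum()))
        effects.append(rel[layer].max(axis=0))
    counts.append(WIDTH)  # output layer
    effects.append(np.full(WIDTH, np.inf))
    width_min, idx = _waist_of_counts(counts)
    return LayerActivity(
        active_counts=tuple(counts),
        waist_width=width_min,
        waist_layer_index=idx,
        relative_effects=tuple(effects),
    )
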