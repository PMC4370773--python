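"""Bow-tie statistics of evolved networks.

Evolved matrices contain very small values rather than exact zeros, so layer
widths are measured functionally: each node is knocked out in turn (all its
incoming and outgoing interactions zeroed) and the fitness change ``dF``
recorded.  Knockout effects are compared *within a layer*: a node is active
if its effect is at least a relative threshold (default 0.1%) of the largest
effect in its layer.  Normalizing by the layer's dominant effect rather than
by the fitness itself keeps the criterion well defined for well-converged
networks, whose fitness is arbitrarily close to 0 while the signal carried
by an active node stays on the scale of the goal.  The *waist* is the
narrowest internal node layer; the central result is that over converged
runs the waist width never drops below the rank of the (clean) goal, and
with product-rule mutations it usually equals it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .goals import GoalMatrix
from .network import LayeredLinearNetwork, fitness

__all__ = [
    "LayerActivity",
    "EnsembleSummary",
    "active_nodes",
    "waist",
    "summarize_ensemble",
    "bootstrap_median_error",
]

#: denominator guard for the relative knockout effect when a whole layer has
#: vanishing knockout effects
FITNESS_FLOOR = 1e-12


@dataclass(frozen=True)
class LayerActivity:
    """Per-layer active-node counts of one network (node layers 1..L+1)."""

    active_counts: tuple[int, ...]
    waist_width: int
    waist_layer_index: int  # 1-based node layer
    relative_effects: tuple[np.ndarray, ...]

    @property
    def n_node_layers(self) -> int:
        return len(self.active_counts)


def _knockout_fitness(
    mats: list[np.ndarray], goal: np.ndarray, layer: int, node: int, n_layers: int
) -> float:
    """Fitness after eliminating one node (0-based node layer, 0..L)."""
    patched = list(mats)
    if layer > 0:  # incoming interactions: row of the matrix below
        m = patched[layer - 1].copy()
        m[node, :] = 0.0
        patched[layer - 1] = m
    if layer < n_layers:  # outgoing interactions: column of the matrix above
        m = patched[layer].copy()
        m[:, node] = 0.0
        patched[layer] = m
    p = patched[0]
    for m in patched[1:]:
        p = m @ p
    d = p - goal
    return -float(np.sum(d * d))


def active_nodes(
    net: LayeredLinearNetwork,
    goal: GoalMatrix | np.ndarray,
    threshold: float = 1e-3,
) -> LayerActivity:
    """Score every node by knockout and count active nodes per layer.

    Eliminating node ``k`` of node layer ``l+1`` zeroes row ``k`` of ``A(l)``
    and column ``k`` of ``A(l+1)``; boundary nodes are scored by the same
    knockout applied to their single adjacent matrix.  Within each layer the
    effects ``dF = |F - F_knockout|`` are compared, and a node is active iff
    its effect is at least ``threshold`` times the largest effect in its
    layer (so a node carrying none of the layer's signal is inactive no
    matter how precisely the network has converged).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = goal.values if isinstance(goal, GoalMatrix) else np.asarray(goal, float)
    mats = list(net.matrices)
    L = net.n_layers
    f0 = fitness(net, g)
    counts = []
    effects = []
    for layer in range(L + 1):
        width = mats[0].shape[1] if layer == 0 else mats[layer - 1].shape[0]
        df = np.empty(width)
        for k in range(width):
            fk = _knockout_fitness(mats, g, layer, k, L)
            df[k] = abs(f0 - fk)
        rel = df / max(df.max(), FITNESS_FLOOR)
        effects.append(rel)
        counts.append(int(np.sum(rel >= threshold)))
    width_min, idx = _waist_of_counts(counts)
    return LayerActivity(
        active_counts=tuple(counts),
        waist_width=width_min,
        waist_layer_index=idx,
        relative_effects=tuple(effects),
    )


def _waist_of_counts(counts) -> tuple[int, int]:
    """(min width, 1-based layer) over internal node layers, ties to the middle."""
    n = len(counts)
    if n < 3:
        raise ValueError("waist needs at least one internal layer")
    internal = range(1, n - 1)  # 0-based internal node layers
    mid = (n - 1) / 2.0
    best = min(internal, key=lambda i: (counts[i], abs(i - mid), i))
    return int(counts[best]), best + 1


def waist(activity: LayerActivity) -> tuple[int, int]:
    """Minimum active count over internal layers and its 1-based layer index."""
    return _waist_of_counts(activity.active_counts)


@dataclass
class EnsembleSummary:
    """Aggregate bow-tie statistics over the converged runs of an ensemble."""

    layer_histograms: np.ndarray  # (n_layers, max_width + 1) counts
    layer_medians: np.ndarray  # (n_layers,)
    waist_widths: np.ndarray  # one per converged run
    waist_layers: np.ndarray
    goal_rank: int
    n_converged: int
    n_total: int
    fraction_waist_equals_rank: float
    fraction_waist_above_rank: float
    n_waist_below_rank: int
    activities: list[LayerActivity]

    @property
    def median_waist(self) -> float:
        return float(np.median(self.waist_widths))


def summarize_ensemble(
    records,
    goal: GoalMatrix | None = None,
    threshold: float = 1e-3,
    activity_fn=None,
    converged_only: bool = True,
) -> EnsembleSummary:
    """Filter converged runs, score their best individuals, aggregate widths.

    ``goal`` overrides the per-record goal for knockout scoring (by default
    each run is scored against its own goal, which matters for fixed-noise
    campaigns where every run has a different noisy goal).  The waist is
    always compared against the *clean* declared rank.  ``activity_fn`` lets
    nonlinear networks plug in their own knockout scoring.
    ``converged_only=False`` keeps all runs; used for temporal-noise
    campaigns, where the fitness floor set by the noise makes the usual
    distance-from-optimum filter meaningless.
    """
    records = list(records)
    if not records:
        raise ValueError("no records given")
    converged = [r for r in records if r.converged] if converged_only else records
    if not converged:
        raise ValueError("no converged runs in the ensemble")
    rank = (goal or converged[0].goal).declared_rank
    activities = []
    for rec in converged:
        net = rec.best_network()
        if activity_fn is not None:
            activities.append(activity_fn(net, threshold))
        else:
            activities.append(active_nodes(net, goal or rec.goal, threshold))
    n_layers = activities[0].n_node_layers
    counts = np.array([a.active_counts for a in activities])  # (n_runs, layers)
    max_w = int(counts.max())
    hist = np.zeros((n_layers, max_w + 1), dtype=int)
    for layer in range(n_layers):
        for w in counts[:, layer]:
            hist[layer, w] += 1
    waists = np.array([a.waist_width for a in activities])
    waist_layers = np.array([a.waist_layer_index for a in activities])
    n_below = int(np.sum(waists < rank))
    if n_below:
        warnings.warn(
            f"{n_below} converged run(s) report a waist narrower than the goal "
            f"rank {rank}; this violates the rank bound and suggests a "
            "knockout-threshold or convergence problem",
            stacklevel=2,
        )
    return EnsembleSummary(
        layer_histograms=hist,
        layer_medians=np.median(counts, axis=0),
        waist_widths=waists,
        waist_layers=waist_layers,
        goal_rank=rank,
        n_converged=len(converged),
        n_total=len(records),
        fraction_waist_equals_rank=float(np.mean(waists == rank)),
        fraction_waist_above_rank=float(np.mean(waists > rank)),
        n_waist_below_rank=n_below,
        activities=activities,
    )


def bootstrap_median_error(
    values, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> float:
    """Standard deviation of the median over bootstrap resamples."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    return float(np.std(medians))
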