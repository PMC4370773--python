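"""Goal matrices: the target input-output transformations networks evolve towards.

A goal matrix ``G`` (shape ``d_output x d_input``) prescribes the desired output
vector for every input vector.  Goals are built from 0/``entry_value`` entries
(the reference experiments use 0 and 10) with a prescribed rank: the rank is the
number of linearly independent rows, and it bounds from below the width of the
narrowest layer ("waist") any network realizing the goal can have.  Goals may be
perturbed once per run by additive uniform noise, which makes them technically
full rank but "almost rank deficient".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GoalSpec",
    "GoalMatrix",
    "make_goal",
    "add_fixed_noise",
    "noise_level",
    "numerical_rank",
    "save_goal",
    "load_goal",
]

#: relative singular-value cutoff used for rank decisions; far below the 0/10
#: entry scale, far above double-precision noise.
RANK_TOL = 1e-8

_MAX_PATTERN_TRIES = 1000


@dataclass(frozen=True)
class GoalSpec:
    """Parameters of a 0/``entry_value`` goal matrix of prescribed rank.

    ``noise_range`` is the upper bound of the per-entry uniform noise added to
    the clean goal (0 means a clean goal).
    """

    d_output: int
    d_input: int
    rank: int
    entry_value: float = 10.0
    noise_range: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_output < 1 or self.d_input < 1:
            raise ValueError("goal dimensions must be positive")
        if not 1 <= self.rank <= min(self.d_output, self.d_input):
            raise ValueError(
                f"rank must satisfy 1 <= rank <= min(d_output, d_input); "
                f"got rank={self.rank} for {self.d_output}x{self.d_input}"
            )
        if self.entry_value <= 0:
            raise ValueError("entry_value must be positive")
        if self.noise_range < 0:
            raise ValueError("noise_range must be non-negative")


@dataclass(frozen=True)
class GoalMatrix:
    """A realized goal: dense matrix plus its declared (clean) rank.

    ``noise_level`` is the relative norm difference from the clean goal it was
    derived from (0 for clean goals); ``declared_rank`` always records the rank
    of the clean goal, even after noise makes the matrix numerically full rank.
    """

    values: np.ndarray
    declared_rank: int
    noise_level: float = 0.0
    spec: GoalSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("goal values must be a 2-d matrix")

    @property
    def d_output(self) -> int:
        return self.values.shape[0]

    @property
    def d_input(self) -> int:
        return self.values.shape[1]


def numerical_rank(m: np.ndarray, tol: float = RANK_TOL) -> int:
    """Number of singular values exceeding ``tol`` times the largest one."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    m = np.asarray(m, dtype=float)
    s = np.linalg.svd(m, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > tol * s[0]))


def make_goal(spec: GoalSpec) -> GoalMatrix:
    """Construct a 0/``entry_value`` goal matrix of exactly ``spec.rank``.

    The construction samples ``rank`` distinct nonzero 0/1 row patterns that are
    linearly independent, assigns each of the ``d_output`` rows one of the
    patterns (each pattern used at least once), and scales by ``entry_value``.
    Rejection sampling enforces that no row or column is all zero, so every
    input and output node is constrained by the goal.  Deterministic given
    ``spec.seed``.  If ``spec.noise_range > 0`` the clean goal is perturbed by
    :func:`add_fixed_noise` (same seed).
    """
    rng = np.random.default_rng(spec.seed)
    r, d_out, d_in = spec.rank, spec.d_output, spec.d_input
    for _ in range(_MAX_PATTERN_TRIES):
        patterns = _sample_patterns(rng, r, d_in)
        if patterns is None:
            continue
        # each pattern used at least once; remaining rows assigned uniformly
        assignment = np.concatenate(
            [np.arange(r), rng.integers(0, r, size=d_out - r)]
        )
        rng.shuffle(assignment)
        values = spec.entry_value * patterns[assignment]
        if not np.all(values.any(axis=0)) or not np.all(values.any(axis=1)):
            continue  # a column ended up all zero (zero rows are impossible)
        if numerical_rank(values) != r:
            continue
        goal = GoalMatrix(values=values, declared_rank=r, spec=spec)
        if spec.noise_range > 0:
            goal = add_fixed_noise(goal, spec.noise_range, int(rng.integers(2**31)))
        return goal
    raise RuntimeError(
        f"no 0/{spec.entry_value} pattern of rank {r} found for "
        f"{d_out}x{d_in} after {_MAX_PATTERN_TRIES} tries"
    )


def _sample_patterns(rng: np.random.Generator, r: int, d_in: int) -> np.ndarray | None:
    """Sample ``r`` distinct nonzero, linearly independent 0/1 rows, or None."""
    patterns = rng.integers(0, 2, size=(r, d_in)).astype(float)
    # nonzero, distinct rows
    if not np.all(patterns.any(axis=1)):
        return None
    if len({tuple(row) for row in patterns}) != r:
        return None
    if numerical_rank(patterns) != r:
        return None
    return patterns


def add_fixed_noise(goal: GoalMatrix, noise_range: float, seed: int) -> GoalMatrix:
    """Add one fixed realization of per-entry uniform noise on [0, noise_range].

    The noise is drawn once and frozen for the run ("fixed" goal noise, as
    opposed to temporal noise re-drawn each generation).  ``declared_rank``
    keeps recording the clean rank.
    """
    if noise_range < 0:
        raise ValueError("noise_range must be non-negative")
    if noise_range == 0:
        return replace(goal, noise_level=0.0)
    rng = np.random.default_rng(seed)
    noisy = goal.values + rng.uniform(0.0, noise_range, size=goal.values.shape)
    level = noise_level(goal, GoalMatrix(values=noisy, declared_rank=goal.declared_rank))
    return GoalMatrix(
        values=noisy,
        declared_rank=goal.declared_rank,
        noise_level=level,
        spec=goal.spec,
    )


def noise_level(clean: GoalMatrix | np.ndarray, noisy: GoalMatrix | np.ndarray) -> float:
    """Relative norm difference | ||G*|| - ||G|| | / ||G||.

    The norm here is the *sum of squared entries* (no square root), matching the
    fitness scale.
    """
    c = clean.values if isinstance(clean, GoalMatrix) else np.asarray(clean, float)
    n = noisy.values if isinstance(noisy, GoalMatrix) else np.asarray(noisy, float)
    if c.shape != n.shape:
        raise ValueError("clean and noisy goals must have the same shape")
    norm_c = float(np.sum(c * c))
    if norm_c == 0.0:
        raise ValueError("clean goal is all zeros; noise level undefined")
    norm_n = float(np.sum(n * n))
    return abs(norm_n - norm_c) / norm_c


def save_goal(goal: GoalMatrix, path: str | Path) -> None:
    """Write the dense matrix as CSV with a JSON sidecar of its metadata."""
    path = Path(path)
    np.savetxt(path, goal.values, delimiter=",")
    meta = {
        "d_output": goal.d_output,
        "d_input": goal.d_input,
        "rank": goal.declared_rank,
        "noise_level": goal.noise_level,
    }
    if goal.spec is not None:
        meta.update(
            entry_value=goal.spec.entry_value,
            noise_range=goal.spec.noise_range,
            seed=goal.spec.seed,
        )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_goal(path: str | Path) -> GoalMatrix:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = None
    if "entry_value" in meta:
        spec = GoalSpec(
            d_output=meta["d_output"],
            d_input=meta["d_input"],
            rank=meta["rank"],
            entry_value=meta["entry_value"],
            noise_range=meta["noise_range"],
            seed=meta["seed"],
        )
    return GoalMatrix(
        values=values,
        declared_rank=meta["rank"],
        noise_level=meta.get("noise_level", 0.0),
        spec=spec,
    )
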