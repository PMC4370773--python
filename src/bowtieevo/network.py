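"""Layered linear networks: chains of interaction matrices.

A network with ``L`` interaction layers maps an input vector ``s`` to the
output ``A(L) ... A(2) A(1) s``; entry ``A[i, j]`` of the l-th matrix is the
interaction intensity from node ``j`` in node layer ``l`` to node ``i`` in node
layer ``l + 1``.  Connections exist only between consecutive layers (no
within-layer or backward links).  All layers are allocated at full width: a
bow-tie shows up as rows/columns driven to (near) zero, never as shrunken
matrix dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .goals import GoalMatrix

__all__ = [
    "LayeredLinearNetwork",
    "propagate",
    "transfer_matrix",
    "fitness",
    "save_network",
    "save_transfer_matrix",
    "load_network",
]


@dataclass(frozen=True)
class LayeredLinearNetwork:
    """Ordered chain of interaction matrices, applied first to last."""

    matrices: tuple[np.ndarray, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mats = tuple(np.asarray(m, dtype=float) for m in self.matrices)
        if len(mats) < 1:
            raise ValueError("a network needs at least one interaction layer")
        for m in mats:
            if m.ndim != 2:
                raise ValueError("each layer must be a 2-d matrix")
        for a, b in zip(mats, mats[1:]):
            if b.shape[1] != a.shape[0]:
                raise ValueError(
                    f"dimension mismatch between consecutive layers: "
                    f"{a.shape} -> {b.shape}"
                )
        object.__setattr__(self, "matrices", mats)

    @property
    def n_layers(self) -> int:
        """Number of interaction layers L (node layers are L + 1)."""
        return len(self.matrices)

    @property
    def d_input(self) -> int:
        return self.matrices[0].shape[1]

    @property
    def d_output(self) -> int:
        return self.matrices[-1].shape[0]


def propagate(
    net: LayeredLinearNetwork,
    input: np.ndarray,
    return_intermediates: bool = False,
):
    """Propagate an input vector through the chain.

    Returns the output vector, or ``(output, [u_1, ..., u_{L+1}])`` with all
    node-layer activities when ``return_intermediates`` is true.
    """
    u = np.asarray(input, dtype=float)
    if u.shape != (net.d_input,):
        raise ValueError(f"input must have length {net.d_input}, got {u.shape}")
    layers = [u]
    for m in net.matrices:
        u = m @ u
        layers.append(u)
    if return_intermediates:
        return u, layers
    return u


def transfer_matrix(net: LayeredLinearNetwork) -> np.ndarray:
    """Total input-output relationship: the product A(L) ... A(1)."""
    p = net.matrices[0]
    for m in net.matrices[1:]:
        p = m @ p
    return p


def fitness(net: LayeredLinearNetwork, goal: GoalMatrix | np.ndarray) -> float:
    """F = -sum of squared entries of (A(L)...A(1) - G).

    Squared Frobenius norm, no square root; 0 is a perfect match, otherwise
    strictly negative.
    """
    g = goal.values if isinstance(goal, GoalMatrix) else np.asarray(goal, float)
    p = transfer_matrix(net)
    if p.shape != g.shape:
        raise ValueError(f"network product {p.shape} does not match goal {g.shape}")
    d = p - g
    return -float(np.sum(d * d))


def save_network(net: LayeredLinearNetwork, path: str | Path) -> None:
    """Serialize as JSON: a list of row-major matrices plus metadata."""
    payload = {
        "matrices": [m.tolist() for m in net.matrices],
        "metadata": net.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def save_transfer_matrix(net: LayeredLinearNetwork, path: str | Path) -> None:
    """Write the full input-output matrix of the chain as CSV."""
    np.savetxt(Path(path), transfer_matrix(net), delimiter=",")


def load_network(path: str | Path) -> LayeredLinearNetwork:
    payload = json.loads(Path(path).read_text())
    return LayeredLinearNetwork(
        matrices=tuple(np.asarray(m, float) for m in payload["matrices"]),
        metadata=payload.get("metadata", {}),
    )
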