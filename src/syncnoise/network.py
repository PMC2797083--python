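"""Coupling topologies and the diffusive coupling operator.

A network is a nonnegative weight matrix ``W`` with zero diagonal; the
entry ``W[i, j]`` is the weight of the connection *from* oscillator ``j``
*into* oscillator ``i``. Diffusive (gap-junction-like) coupling adds

    coupling_i = sum_j W[i, j] (x_j - x_i)

on the coupled components, which vanishes on the synchronization subspace
(all units equal). A network is *balanced* when each node's incoming
weight sum equals its outgoing weight sum; balance makes the coupling
terms cancel exactly in the population sum, which is the algebraic step
that lets the centre of mass follow the uncoupled dynamics. Any symmetric
network is balanced.

The all-to-all topology with identical strength ``k`` admits an exactly
equivalent *quorum-sensing star* form: each unit is damped locally with
coefficient ``n k`` and driven by ``n k`` times the population mean, so a
shared mean signal implements all-to-all coupling with n connections
instead of n^2.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .models import InvalidInputError

__all__ = [
    "CouplingGraph",
    "QuorumStar",
    "build_all_to_all",
    "build_probabilistic",
    "is_balanced",
    "coupling_term",
    "to_quorum_star",
    "graph_to_csv",
    "graph_from_csv",
]

logger = logging.getLogger(__name__)

BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class CouplingGraph:
    """Weighted directed coupling topology over ``n_nodes`` oscillators."""

    n_nodes: int
    weights: np.ndarray
    symmetric: bool = field(init=False)
    balanced: bool = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (self.n_nodes, self.n_nodes):
            raise InvalidInputError(
                f"weights must be {self.n_nodes}x{self.n_nodes}, got {W.shape}"
            )
        if np.any(W < 0):
            raise InvalidInputError("coupling weights must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise InvalidInputError("self-coupling (nonzero diagonal) is forbidden")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "symmetric", bool(np.array_equal(W, W.T)))
        object.__setattr__(self, "balanced", is_balanced(self, BALANCE_TOL))

    def coupling(self, states: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return coupling_term(self, states, mask)

    def digest(self) -> str:
        import hashlib

        return hashlib.sha1(np.ascontiguousarray(self.weights).tobytes()).hexdigest()[:12]


@dataclass(frozen=True)
class QuorumStar:
    """Mean-field (star) form of the all-to-all network with strength ``k``.

    Each node update is ``n k (mean - x_i)``: local damping ``n k`` plus a
    drive from the common mean signal; algebraically identical to the
    all-to-all diffusive sum.
    """

    n_nodes: int
    k: float
    damping: float
    mean_drive: float

    def coupling(self, states: np.ndarray, mask: np.ndarray) -> np.ndarray:
        states = np.asarray(states, dtype=float)
        if states.shape[0] != self.n_nodes:
            raise InvalidInputError(
                f"states has {states.shape[0]} rows, expected {self.n_nodes}"
            )
        out = np.zeros_like(states)
        mask = np.asarray(mask, dtype=bool)
        mean = states[:, mask].mean(axis=0)
        out[:, mask] = self.mean_drive * mean - self.damping * states[:, mask]
        return out


def build_all_to_all(n: int, k: float) -> CouplingGraph:
    """All-to-all network with identical coupling strength ``k``."""
    if n < 2:
        raise InvalidInputError("an all-to-all network needs n >= 2 nodes")
    if k <= 0:
        raise InvalidInputError("coupling strength k must be positive")
    W = np.full((n, n), float(k))
    np.fill_diagonal(W, 0.0)
    return CouplingGraph(n_nodes=n, weights=W)


def build_probabilistic(n: int, p: float, k: float, seed: int) -> CouplingGraph:
    """Probabilistic symmetric network: each unordered pair is connected
    (both directions, weight ``k``) independently with probability ``p``.

    The output is symmetric, hence balanced. Connectivity is *not*
    enforced; a disconnected draw is only logged, since disconnected
    components cannot synchronize globally.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("connection probability p must be in [0, 1]")
    if n < 2:
        raise InvalidInputError("need n >= 2 nodes")
    if k <= 0:
        raise InvalidInputError("coupling strength k must be positive")
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, 1)
    W = np.where(upper | upper.T, float(k), 0.0)
    graph = CouplingGraph(n_nodes=n, weights=W)
    if not _is_connected(W):
        logger.warning(
            "probabilistic graph (n=%d, p=%.3f, seed=%d) is disconnected", n, p, seed
        )
    return graph


def _is_connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    adj = W > 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i] | adj[:, i]):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def is_balanced(graph: CouplingGraph, tol: float = BALANCE_TOL) -> bool:
    """True iff every node's incoming weight sum equals its outgoing sum
    within ``tol`` (absolute)."""
    if tol < 0:
        raise InvalidInputError("tolerance must be nonnegative")
    W = graph.weights
    return bool(np.max(np.abs(W.sum(axis=1) - W.sum(axis=0))) <= tol)


def coupling_term(graph: CouplingGraph, states: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Diffusive coupling ``sum_j W[i,j] (x_j - x_i)`` on masked components.

    Depends only on state differences, so it is invariant under a common
    translation of all states and vanishes when all units agree.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] != graph.n_nodes:
        raise InvalidInputError(
            f"states must be ({graph.n_nodes}, dim), got {states.shape}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (states.shape[1],):
        raise InvalidInputError("coupling mask length must equal the state dimension")
    out = np.zeros_like(states)
    sub = states[:, mask]
    out[:, mask] = graph.weights @ sub - graph.weights.sum(axis=1)[:, None] * sub
    return out


def to_quorum_star(n: int, k: float) -> QuorumStar:
    """Rewrite the all-to-all network as its quorum-sensing star form."""
    if n < 2:
        raise InvalidInputError("need n >= 2 nodes")
    if k <= 0:
        raise InvalidInputError("coupling strength k must be positive")
    return QuorumStar(n_nodes=n, k=float(k), damping=n * float(k), mean_drive=n * float(k))


def graph_to_csv(graph: CouplingGraph, path) -> None:
    """Write the nonzero edges as ``source,target,weight`` rows (j -> i)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        rows, cols = np.nonzero(graph.weights)
        for i, j in zip(rows, cols):
            writer.writerow([int(j), int(i), repr(float(graph.weights[i, j]))])


def graph_from_csv(path, n_nodes: int | None = None) -> CouplingGraph:
    """Read an edge-list CSV written by :func:`graph_to_csv`."""
    edges = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            edges.append((int(row["source"]), int(row["target"]), float(row["weight"])))
    if n_nodes is None:
        n_nodes = 1 + max(max(s, t) for s, t, _ in edges) if edges else 0
    W = np.zeros((n_nodes, n_nodes))
    for s, t, w in edges:
        W[t, s] = w
    return CouplingGraph(n_nodes=n_nodes, weights=W)
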