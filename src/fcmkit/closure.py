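"""Signed fuzzy (max-min) transitive closure of a scaled map.

A *walk* is any succession of edges allowing transit between two nodes (node
revisits allowed).  Its strength is the minimum edge magnitude along it (the
bottleneck rule) and its net character is set by parity: a walk with an even
number of inhibitory edges acts excitatory, an odd number acts inhibitory.
The closure value between two nodes is the maximum walk strength over all
connecting walks, tracked separately per parity:

* ``P(i, j)`` -- strongest even-parity (net excitatory) walk i -> j,
* ``N(i, j)`` -- strongest odd-parity (net inhibitory) walk i -> j,

and the single signed value reported is ``P - N``, which lies in [-1, 1],
reduces to the plain max-min closure on all-excitatory maps, and makes the
``P == N`` stalemate an explicit zero.  Cells where both parities are
reachable (P and N both nonzero) additionally carry an ambiguity flag.

The diagonal carries no implicit self-strength of 1: ``closure(i, i)`` is
nonzero only through genuine cycles.

The fixed point is computed by repeated parity-aware max-min composition
with the one-step edge matrices.  Values are copied, never multiplied, so
there is no floating-point accumulation and two independent implementations
agree *exactly*; :func:`enumerate_walks_oracle` is that independent
implementation (pruned walk enumeration) for small maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidWalkError, MapStateError
from .model import Edge, FuzzyCognitiveMap

__all__ = [
    "InfluenceMatrix",
    "walk_strength",
    "transitive_closure",
    "enumerate_walks_oracle",
]


@dataclass
class InfluenceMatrix:
    """Transitive closure of one map: signed strengths for every node pair.

    ``values = pos - neg`` where ``pos``/``neg`` hold the strongest even- and
    odd-parity walk strengths; ``ambiguous`` flags cells where both parities
    are nonzero.  Row ``i``, column ``j`` is the influence of node ``i`` on
    node ``j``.
    """

    node_order: list[str]
    node_labels: list[str]
    pos: np.ndarray
    neg: np.ndarray
    source_map: str = ""
    values: np.ndarray = field(init=False)
    ambiguous: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.neg = np.asarray(self.neg, dtype=float)
        self.values = self.pos - self.neg
        self.ambiguous = (self.pos > 0) & (self.neg > 0)

    @property
    def n(self) -> int:
        return len(self.node_order)

    def value(self, source: str, target: str) -> float:
        i = self.node_order.index(source)
        j = self.node_order.index(target)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.node_labels, columns=self.node_labels
        )

    def write_csv(self, path: str | Path, ambiguity_sidecar: str | Path | None = None):
        """Write the signed closure as adjacency CSV, plus an optional
        sidecar CSV of per-cell ambiguity flags (same dialect)."""
        self.to_dataframe().to_csv(path)
        if ambiguity_sidecar is not None:
            pd.DataFrame(
                self.ambiguous.astype(int),
                index=self.node_labels,
                columns=self.node_labels,
            ).to_csv(ambiguity_sidecar)

    def equals(self, other: "InfluenceMatrix") -> bool:
        return (
            self.node_order == other.node_order
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.neg, other.neg)
        )


def walk_strength(fcm: FuzzyCognitiveMap, walk: Sequence[str]) -> float:
    """Signed strength of one explicit walk (sequence of node ids).

    Magnitude is the minimum edge magnitude along the walk; the sign is the
    product of the edge signs (parity rule).  A missing edge raises
    :class:`~fcmkit.errors.InvalidWalkError` naming the gap.
    """
    if len(walk) < 2:
        raise InvalidWalkError("a walk needs at least one edge (two nodes)")
    strength = np.inf
    sign = 1
    for a, b in zip(walk, walk[1:]):
        edge = fcm.edge(a, b)
        if edge is None:
            raise InvalidWalkError(f"walk has no edge ({a}->{b}) in map {fcm.name!r}")
        strength = min(strength, edge.weight)
        sign *= edge.sign
    return sign * float(strength)


def _edge_matrices(fcm: FuzzyCognitiveMap) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = fcm.factor_ids
    index = {fid: i for i, fid in enumerate(ids)}
    n = len(ids)
    pos = np.zeros((n, n))
    neg = np.zeros((n, n))
    for e in fcm.edges:
        (pos if e.sign > 0 else neg)[index[e.source], index[e.target]] = e.weight
    return ids, pos, neg


def _maxmin(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Max-min composition: out[i,j] = max_k min(a[i,k], b[k,j])."""
    if a.size == 0:
        return a.copy()
    return np.max(np.minimum(a[:, :, None], b[None, :, :]), axis=1)


def close_parity_matrices(
    pos0: np.ndarray, neg0: np.ndarray, max_steps: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of parity-aware max-min composition over one-step edge
    matrices (walks of length >= 1).  Exposed so idempotence can be checked
    directly on a closed (P, N) pair."""
    pos, neg = pos0.copy(), neg0.copy()
    n = pos.shape[0]
    limit = max_steps if max_steps is not None else max(1, 4 * n * n)
    for _ in range(limit):
        new_pos = np.maximum(pos, np.maximum(_maxmin(pos, pos0), _maxmin(neg, neg0)))
        new_neg = np.maximum(neg, np.maximum(_maxmin(pos, neg0), _maxmin(neg, pos0)))
        if np.array_equal(new_pos, pos) and np.array_equal(new_neg, neg):
            break
        pos, neg = new_pos, new_neg
    return pos, neg


def transitive_closure(fcm: FuzzyCognitiveMap) -> InfluenceMatrix:
    """Signed fuzzy transitive closure of a scaled map.

    Deterministic and independent of node order (relabelling nodes permutes
    the matrix identically); an empty map yields an empty matrix; an
    unscaled map raises :class:`~fcmkit.errors.MapStateError`.
    """
    if not fcm.scaled:
        raise MapStateError(
            f"map {fcm.name!r} must be scaled before computing the closure"
        )
    ids, pos0, neg0 = _edge_matrices(fcm)
    pos, neg = close_parity_matrices(pos0, neg0)
    return InfluenceMatrix(
        node_order=ids,
        node_labels=[fcm.factor(i).label for i in ids],
        pos=pos,
        neg=neg,
        source_map=fcm.name,
    )


def enumerate_walks_oracle(
    fcm: FuzzyCognitiveMap, max_walk_edges: int | None = None
) -> InfluenceMatrix:
    """Brute-force closure by walk enumeration, for small maps.

    Explores walks from every source node, applying the min rule and parity
    tracking edge by edge; a walk prefix is only extended while it strictly
    improves the best known strength for its (end node, parity) state, which
    prunes the (infinite) walk space without losing any max-min optimum.
    Intended as an independent test oracle for :func:`transitive_closure`
    on maps of up to ~8 nodes.

    ``max_walk_edges``, when given, additionally bounds walk length; pass a
    generous bound (>= number of nodes) or None for no bound.
    """
    if not fcm.scaled:
        raise MapStateError(f"map {fcm.name!r} must be scaled")
    if max_walk_edges is not None and max_walk_edges < 1:
        raise ValueError("max_walk_edges must be >= 1")
    ids = fcm.factor_ids
    index = {fid: i for i, fid in enumerate(ids)}
    n = len(ids)
    outgoing: dict[str, list[Edge]] = {fid: [] for fid in ids}
    for e in fcm.edges:
        outgoing[e.source].append(e)
    pos = np.zeros((n, n))
    neg = np.zeros((n, n))

    for src in ids:
        best: dict[tuple[str, int], float] = {}

        def extend(node: str, parity: int, strength: float, depth: int) -> None:
            for e in outgoing[node]:
                s2 = min(strength, e.weight)
                p2 = parity ^ (1 if e.sign < 0 else 0)
                if s2 > best.get((e.target, p2), 0.0):
                    best[(e.target, p2)] = s2
                    if max_walk_edges is None or depth < max_walk_edges:
                        extend(e.target, p2, s2, depth + 1)

        extend(src, 0, np.inf, 1)
        for (node, parity), strength in best.items():
            (pos if parity == 0 else neg)[index[src], index[node]] = strength

    return InfluenceMatrix(
        node_order=ids,
        node_labels=[fcm.factor(i).label for i in ids],
        pos=pos,
        neg=neg,
        source_map=fcm.name,
    )
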