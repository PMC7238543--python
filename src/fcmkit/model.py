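"""Domain model for stakeholder fuzzy cognitive maps.

A fuzzy cognitive map (FCM) is a signed, weighted digraph drawn by one
stakeholder group: nodes are factors elicited in a mapping session, edges are
perceived causal influences.  Edge strength is graded on an ordinal 1-5 scale
(5 = the factor almost always causes the linked outcome) and carries a sign:
+1 excitatory (source up, target up) or -1 inhibitory (source up, target
down).  Before numerical analysis the ordinal weights are rescaled into the
fuzzy unit interval by dividing by a constant (default 5), so magnitudes live
in (0, 1].

Each map also records its polarity -- whether it collects *risk* factors that
impede the outcome or *protective* factors that promote it -- and the number
of participants who drew it, used later as the map's weight when combining
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import (
    DuplicateEdgeError,
    MapStateError,
    WeightRangeError,
)

POLARITIES = ("risk", "protective")

#: Allowed raw (unscaled) edge strengths, as elicited from participants.
RAW_WEIGHTS = (1, 2, 3, 4, 5)


def normalize_label(label: str) -> str:
    """Canonical form used for factor identity: trimmed, single-spaced,
    case-folded."""
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class Factor:
    """A node of a stakeholder map.

    Parameters
    ----------
    id : str
        Short stable token, unique within a map.
    label : str
        Free-text factor name as elicited; must be non-empty.
    group : str
        Name of the stakeholder group the factor came from.
    """

    id: str
    label: str
    group: str = ""

    def __post_init__(self) -> None:
        if not str(self.label).strip():
            raise ValueError(f"factor {self.id!r} has an empty label")


@dataclass(frozen=True)
class Edge:
    """A directed causal influence between two factors.

    ``weight`` is a magnitude: an integer in 1..5 on an unscaled map, a value
    in (0, 1] on a scaled one.  ``sign`` is +1 (excitatory) or -1
    (inhibitory).
    """

    source: str
    target: str
    weight: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if self.weight <= 0:
            raise ValueError(
                f"edge ({self.source}->{self.target}) weight must be positive; "
                "encode inhibition through sign, not a negative weight"
            )

    @property
    def signed_weight(self) -> float:
        return self.sign * self.weight


class FuzzyCognitiveMap:
    """A named, signed, weighted digraph of factors from one group.

    Node order is the insertion order and is preserved by every reader and
    writer; factor ids are unique; at most one edge per ordered (source,
    target) pair, self-loops allowed.
    """

    def __init__(
        self,
        name: str = "",
        polarity: str = "risk",
        participant_count: int = 1,
        scaled: bool = False,
    ) -> None:
        if polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {polarity!r}")
        if participant_count < 1:
            raise ValueError("participant_count must be a positive integer")
        self.name = name
        self.polarity = polarity
        self.participant_count = int(participant_count)
        self.scaled = bool(scaled)
        self._factors: dict[str, Factor] = {}
        self._edges: dict[tuple[str, str], Edge] = {}

    # -- construction -------------------------------------------------

    def add_factor(self, factor: Factor | str, label: str | None = None) -> Factor:
        if not isinstance(factor, Factor):
            factor = Factor(id=str(factor), label=label or str(factor), group=self.name)
        if factor.id in self._factors:
            raise ValueError(f"duplicate factor id {factor.id!r} in map {self.name!r}")
        self._factors[factor.id] = factor
        return factor

    def _check_weight(self, edge: Edge) -> None:
        if self.scaled:
            if not 0 < edge.weight <= 1:
                raise WeightRangeError(
                    f"scaled map {self.name!r}: edge ({edge.source}->{edge.target}) "
                    f"magnitude {edge.weight} outside (0, 1]"
                )
        else:
            if edge.weight not in RAW_WEIGHTS:
                raise WeightRangeError(
                    f"unscaled map {self.name!r}: edge ({edge.source}->{edge.target}) "
                    f"weight {edge.weight} not in {{1..5}}"
                )

    def add_edge(
        self,
        source: str | Edge,
        target: str | None = None,
        weight: float | None = None,
        sign: int = 1,
    ) -> Edge:
        if isinstance(source, Edge):
            edge = source
        else:
            edge = Edge(source=str(source), target=str(target), weight=weight, sign=sign)
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._factors:
                raise ValueError(
                    f"edge endpoint {endpoint!r} is not a factor of map {self.name!r}"
                )
        key = (edge.source, edge.target)
        if key in self._edges:
            raise DuplicateEdgeError(
                f"duplicate edge ({edge.source}->{edge.target}) in map {self.name!r}"
            )
        self._check_weight(edge)
        self._edges[key] = edge
        return edge

    def set_edge(self, source: str, target: str, weight: float, sign: int = 1) -> None:
        """Add or replace the edge (source, target); used by sensitivity scans."""
        self._edges.pop((source, target), None)
        self.add_edge(source, target, weight, sign)

    def remove_edge(self, source: str, target: str) -> None:
        self._edges.pop((source, target), None)

    # -- inspection ---------------------------------------------------

    @property
    def factor_ids(self) -> list[str]:
        return list(self._factors)

    @property
    def factors(self) -> list[Factor]:
        return list(self._factors.values())

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def n_factors(self) -> int:
        return len(self._factors)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def factor(self, factor_id: str) -> Factor:
        return self._factors[factor_id]

    def has_factor(self, factor_id: str) -> bool:
        return factor_id in self._factors

    def edge(self, source: str, target: str) -> Edge | None:
        return self._edges.get((source, target))

    def labels(self) -> list[str]:
        return [f.label for f in self._factors.values()]

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def copy(self) -> "FuzzyCognitiveMap":
        out = FuzzyCognitiveMap(
            name=self.name,
            polarity=self.polarity,
            participant_count=self.participant_count,
            scaled=self.scaled,
        )
        out._factors = dict(self._factors)
        out._edges = dict(self._edges)
        return out

    def to_adjacency(self) -> tuple[list[str], np.ndarray]:
        """Signed adjacency matrix in node insertion order (row -> column)."""
        ids = self.factor_ids
        index = {fid: i for i, fid in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)))
        for e in self._edges.values():
            a[index[e.source], index[e.target]] = e.signed_weight
        return ids, a

    # -- equality (structural) ----------------------------------------

    def structurally_equal(self, other: "FuzzyCognitiveMap") -> bool:
        """Same factor labels (canonicalized), edges, weights and signs."""
        if self.n_factors != other.n_factors or self.n_edges != other.n_edges:
            return False
        mine = {f.id: normalize_label(f.label) for f in self.factors}
        theirs = {f.id: normalize_label(f.label) for f in other.factors}
        if sorted(mine.values()) != sorted(theirs.values()):
            return False
        label_to_other = {normalize_label(f.label): f.id for f in other.factors}
        for e in self.edges:
            o = other.edge(
                label_to_other[mine[e.source]], label_to_other[mine[e.target]]
            )
            if o is None or o.sign != e.sign or not np.isclose(o.weight, e.weight):
                return False
        return self.scaled == other.scaled

    def __repr__(self) -> str:
        return (
            f"FuzzyCognitiveMap(name={self.name!r}, polarity={self.polarity!r}, "
            f"factors={self.n_factors}, edges={self.n_edges}, scaled={self.scaled})"
        )


def scale_weights(fcm: FuzzyCognitiveMap, constant: float = 5.0) -> FuzzyCognitiveMap:
    """Rescale an elicited 1-5 map into fuzzy magnitudes by dividing every
    weight by ``constant`` (default 5, so 1..5 maps onto 0.2..1.0).

    Signs are untouched.  Rescaling an already scaled map is a state error,
    not a silent second division.
    """
    if fcm.scaled:
        raise MapStateError(f"map {fcm.name!r} is already scaled")
    if constant <= 0:
        raise ValueError("scaling constant must be positive")
    out = FuzzyCognitiveMap(
        name=fcm.name,
        polarity=fcm.polarity,
        participant_count=fcm.participant_count,
        scaled=True,
    )
    for f in fcm.factors:
        out.add_factor(f)
    for e in fcm.edges:
        out.add_edge(Edge(e.source, e.target, e.weight / constant, e.sign))
    return out


def iter_maps_factors(maps: Iterable[FuzzyCognitiveMap]) -> Iterator[tuple[str, Factor]]:
    for m in maps:
        for f in m.factors:
            yield m.name, f
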