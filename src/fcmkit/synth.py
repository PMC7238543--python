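"""Synthetic stakeholder maps with the statistical shape of the study maps.

The raw adjacency matrices behind the published tables were not deposited,
so factor-level pipeline behaviour is exercised on generated maps whose
shape mirrors what the study reports: risk maps of ~44 nodes with ~87
edges, protective maps of ~12-18 nodes with ~31-38 edges, integer consensus
weights 1-5, overwhelmingly excitatory edges (the study's single inhibitory
influence was the contested hospital edge), factors partitioned into
categories with one designated outcome category.

All randomness flows through a single integer seed; the same config always
yields the same map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CategoryMapping
from .model import Edge, Factor, FuzzyCognitiveMap

__all__ = ["SynthConfig", "generate_map", "generate_group_pair"]

#: Default consensus-weight distribution over {1..5}: midwives most often
#: settled on a middling strength, extremes were rarer.
DEFAULT_WEIGHT_PROBS = {1: 0.15, 2: 0.20, 3: 0.30, 4: 0.20, 5: 0.15}


@dataclass
class SynthConfig:
    """Shape parameters of one generated map (defaults mirror the study's
    risk maps: 44 nodes, 87 edges, 17 categories, rare inhibition)."""

    n_nodes: int = 44
    n_edges: int = 87
    inhibitory_prob: float = 0.02
    weight_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_PROBS)
    )
    n_categories: int = 17
    outcome_category: str = "C01"
    seed: int = 0
    name: str = "synthetic"
    polarity: str = "risk"
    participant_count: int = 1

    def validate(self) -> None:
        if self.n_nodes < 1 or self.n_edges < 0:
            raise ValueError("n_nodes must be >= 1 and n_edges >= 0")
        if self.n_edges > self.n_nodes**2:
            raise ValueError(
                f"{self.n_edges} edges infeasible for {self.n_nodes} nodes "
                "(max n^2 with self-loops)"
            )
        if not 0 <= self.inhibitory_prob <= 1:
            raise ValueError("inhibitory_prob must be in [0, 1]")
        if set(self.weight_probs) - {1, 2, 3, 4, 5}:
            raise ValueError("weight_probs keys must be raw weights 1..5")
        if not np.isclose(sum(self.weight_probs.values()), 1.0):
            raise ValueError("weight_probs must sum to 1")
        if self.n_categories < 1 or self.n_categories > self.n_nodes:
            raise ValueError("need 1 <= n_categories <= n_nodes")


def _category_ids(n: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n)]


def generate_map(config: SynthConfig) -> tuple[FuzzyCognitiveMap, CategoryMapping]:
    """Generate one map plus its factor -> category mapping.

    Exactly ``n_nodes`` factors and ``n_edges`` distinct directed edges
    (self-loops allowed); weights i.i.d. from ``weight_probs``; each edge
    inhibitory with probability ``inhibitory_prob``; every category
    non-empty (so the outcome category always has members); reproducible
    under ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fcm = FuzzyCognitiveMap(
        name=config.name,
        polarity=config.polarity,
        participant_count=config.participant_count,
        scaled=False,
    )
    n = config.n_nodes
    ids = [f"F{i + 1:03d}" for i in range(n)]
    for fid in ids:
        fcm.add_factor(Factor(fid, f"{config.name} factor {fid}", group=config.name))

    flat = rng.choice(n * n, size=config.n_edges, replace=False)
    weights = rng.choice(
        sorted(config.weight_probs),
        size=config.n_edges,
        p=[config.weight_probs[w] for w in sorted(config.weight_probs)],
    )
    signs = np.where(rng.random(config.n_edges) < config.inhibitory_prob, -1, 1)
    for pos, w, s in zip(flat, weights, signs):
        fcm.add_edge(Edge(ids[pos // n], ids[pos % n], int(w), int(s)))

    cats = _category_ids(config.n_categories)
    if config.outcome_category not in cats:
        cats[0] = config.outcome_category
    # first one node per category (all categories non-empty), rest random
    assignment = list(cats) + list(
        rng.choice(cats, size=n - len(cats), replace=True)
    )
    mapping = CategoryMapping(
        rows=[
            (fcm.factor(fid).label, config.name, cat)
            for fid, cat in zip(ids, assignment)
        ],
        categories=cats,
        outcome_category=config.outcome_category,
    )
    return fcm, mapping


def generate_group_pair(
    config: SynthConfig,
    shared_category_fraction: float,
    conflict_count: int,
) -> tuple[
    tuple[FuzzyCognitiveMap, CategoryMapping],
    tuple[FuzzyCognitiveMap, CategoryMapping],
    dict[str, str],
]:
    """Two group maps with a controlled comparison structure.

    ``config.n_categories`` non-outcome categories form the comparison
    universe; a fraction ``shared_category_fraction`` of them (rounded) is
    present in both maps, the rest split between the maps, and exactly
    ``conflict_count`` of the shared ones are given opposite-sign influence
    on the outcome (negative in map A, positive in map B).  Each category
    contributes one factor with a direct edge to the outcome factor, so
    closure preserves the constructed signs exactly.

    Returns the two (map, mapping) bundles and the ground-truth label per
    non-outcome category (``validated`` / ``non-validated`` /
    ``conflicting``).
    """
    config.validate()
    if not 0 <= shared_category_fraction <= 1:
        raise ValueError("shared_category_fraction must be in [0, 1]")
    k = config.n_categories
    n_shared = int(round(shared_category_fraction * k))
    if conflict_count < 0 or conflict_count > n_shared:
        raise ValueError(
            f"conflict_count {conflict_count} infeasible for {n_shared} shared "
            "categories"
        )
    rng = np.random.default_rng(config.seed)
    outcome = "OUT"
    cats = [f"C{i + 1:02d}" for i in range(k)]
    shared = cats[:n_shared]
    conflicting = shared[:conflict_count]
    exclusive = cats[n_shared:]
    half = (len(exclusive) + 1) // 2
    only_a, only_b = exclusive[:half], exclusive[half:]

    truth = {c: "validated" for c in shared}
    truth.update({c: "conflicting" for c in conflicting})
    truth.update({c: "non-validated" for c in exclusive})

    def build(group: str, members: list[str], negative: set[str]):
        fcm = FuzzyCognitiveMap(name=group, polarity=config.polarity)
        fcm.add_factor(Factor("OUTCOME", f"{group} outcome", group=group))
        rows = [(f"{group} outcome", group, outcome)]
        for c in members:
            fid = f"{c}_node"
            label = f"{group} factor for {c}"
            fcm.add_factor(Factor(fid, label, group=group))
            weight = int(rng.integers(1, 6))
            fcm.add_edge(Edge(fid, "OUTCOME", weight, -1 if c in negative else 1))
            rows.append((label, group, c))
        mapping = CategoryMapping(
            rows, [outcome, *members], outcome_category=outcome
        )
        return fcm, mapping

    bundle_a = build("group_a", shared + only_a, set(conflicting))
    bundle_b = build("group_b", shared + only_b, set())
    return bundle_a, bundle_b, truth
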