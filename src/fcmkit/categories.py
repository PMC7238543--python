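"""Thematic condensation: factor-level closures -> category-level maps.

Stakeholder maps from different groups rarely share factors verbatim; they
are aligned through a factor -> category mapping (the pattern-matching table
built during thematic analysis).  The cumulative weight from category C1 to
category C2 is the *sum* of the closure influences of every member factor of
C1 on every member factor of C2; influence among factors of the same
category lands on the diagonal (the self-loop of the category map).

Cumulative weights are then normalized into the cumulative net influence
(CNI) by dividing by the maximum absolute cumulative weight over a chosen
scope, so the strongest category scores 1:

* ``outcome-column`` -- normalize by the strongest influence *on the outcome
  category* (for tables of per-category influence on the health outcome);
* ``whole-matrix`` -- normalize by the strongest influence anywhere in the
  map (for full category-map exports, "1 is the highest influence in the
  map").

Group maps are combined by a weighted average of the *pre-normalization*
cumulative weights, each map weighted by the number of participants who drew
it, then re-normalized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .closure import InfluenceMatrix
from .errors import MappingError
from .model import normalize_label

__all__ = [
    "CategoryMapping",
    "CategoryInfluenceMap",
    "aggregate_to_categories",
    "normalize_cni",
    "combine_group_maps",
    "combine_closures",
]

SCOPES = ("outcome-column", "whole-matrix")


class CategoryMapping:
    """The factor -> category lookup plus the designated outcome category.

    Rows are (factor label, map name, category id); a row whose map name is
    ``"*"`` (or empty) applies to every map.  Factor labels are matched after
    whitespace trimming and case folding.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, str, str]],
        categories: Sequence[str],
        outcome_category: str,
        display_names: dict[str, str] | None = None,
    ) -> None:
        self.categories = list(dict.fromkeys(categories))
        if outcome_category not in self.categories:
            raise ValueError(
                f"outcome category {outcome_category!r} is not in the category list"
            )
        self.outcome_category = outcome_category
        self.display_names = dict(display_names or {})
        self.rows: list[tuple[str, str, str]] = []
        self._lookup: dict[tuple[str, str], str] = {}
        for label, map_name, category in rows:
            if category not in self.categories:
                raise ValueError(f"unknown category {category!r} for factor {label!r}")
            key = (str(map_name).strip() or "*", normalize_label(label))
            if key in self._lookup and self._lookup[key] != category:
                raise MappingError(
                    f"factor {label!r} in map {map_name!r} mapped to two categories"
                )
            self._lookup[key] = category
            self.rows.append((label, key[0], category))

    def category_for(self, label: str, map_name: str = "*") -> str | None:
        key = normalize_label(label)
        return self._lookup.get((map_name, key)) or self._lookup.get(("*", key))

    def display_name(self, category: str) -> str:
        return self.display_names.get(category, category)

    def factors_in(self, category: str, map_name: str = "*") -> list[str]:
        return [
            label
            for label, m, c in self.rows
            if c == category and m in (map_name, "*")
        ]

    # -- CSV plumbing (columns fixed: factor_label,map_name,category_id /
    #    category_id,display_name,is_outcome) --------------------------

    @classmethod
    def from_csv(cls, mapping_path: str | Path, categories_path: str | Path):
        cats = pd.read_csv(categories_path, dtype=str, keep_default_na=False)
        order = [str(c) for c in cats["category_id"]]
        names = dict(zip(order, cats["display_name"]))
        outcome_flags = [
            c
            for c, flag in zip(order, cats["is_outcome"])
            if str(flag).strip().lower() in ("1", "true", "yes")
        ]
        if len(outcome_flags) != 1:
            raise ValueError(
                f"{categories_path}: exactly one category must have is_outcome set, "
                f"found {len(outcome_flags)}"
            )
        rows = pd.read_csv(mapping_path, dtype=str, keep_default_na=False)
        triples = list(
            zip(rows["factor_label"], rows["map_name"], rows["category_id"])
        )
        return cls(triples, order, outcome_flags[0], names)

    def to_csv(self, mapping_path: str | Path, categories_path: str | Path) -> None:
        with open(mapping_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["factor_label", "map_name", "category_id"])
            writer.writerows(self.rows)
        with open(categories_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["category_id", "display_name", "is_outcome"])
            for c in self.categories:
                writer.writerow(
                    [c, self.display_name(c), int(c == self.outcome_category)]
                )


@dataclass
class CategoryInfluenceMap:
    """Category-level cumulative weights and normalized CNI for one group
    (or a weighted combination of groups).

    ``cumulative`` is the raw summed-closure matrix (row influences column);
    ``cni`` and ``outcome_cni`` are filled by :func:`normalize_cni` and
    record the ``scope`` used.  ``factor_counts`` says how many member
    factors each category had in the source map (0 = category absent).
    """

    category_order: list[str]
    cumulative: np.ndarray
    outcome_category: str
    factor_counts: dict[str, int] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()
    display_names: dict[str, str] = field(default_factory=dict)
    cni: np.ndarray | None = None
    outcome_cni: np.ndarray | None = None
    scope: str | None = None

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        k = len(self.category_order)
        if self.cumulative.shape != (k, k):
            raise ValueError("cumulative matrix shape does not match category order")
        if self.outcome_category not in self.category_order:
            raise ValueError(f"outcome {self.outcome_category!r} not a category")

    @property
    def outcome_index(self) -> int:
        return self.category_order.index(self.outcome_category)

    def outcome_cni_of(self, category: str) -> float:
        if self.outcome_cni is None:
            raise ValueError("map not normalized yet; call normalize_cni first")
        return float(self.outcome_cni[self.category_order.index(category)])

    def n_factors(self, category: str) -> int:
        return int(self.factor_counts.get(category, 0))

    def cni_dataframe(self) -> pd.DataFrame:
        names = [self.display_names.get(c, c) for c in self.category_order]
        return pd.DataFrame(self.cni, index=names, columns=names)

    def outcome_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category_id": self.category_order,
                "display_name": [
                    self.display_names.get(c, c) for c in self.category_order
                ],
                "n_factors": [self.n_factors(c) for c in self.category_order],
                "cumulative_weight": self.cumulative[:, self.outcome_index],
                "outcome_cni": self.outcome_cni,
            }
        )


def aggregate_to_categories(
    closure: InfluenceMatrix,
    mapping: CategoryMapping,
    *,
    map_name: str | None = None,
    scope: str = "outcome-column",
) -> CategoryInfluenceMap:
    """Condense a factor-level closure into a category-level map.

    ``cumulative(C1, C2) = sum over (a in C1, b in C2) closure(a, b)``;
    within-category influence (C1 == C2, including factor cycles) lands on
    the diagonal.  A factor with no category raises
    :class:`~fcmkit.errors.MappingError` listing every orphan.  The result
    is normalized with :func:`normalize_cni` under ``scope``.
    """
    map_name = map_name if map_name is not None else (closure.source_map or "*")
    cats = mapping.categories
    cat_index = {c: i for i, c in enumerate(cats)}
    n, k = closure.n, len(cats)
    membership = np.zeros((n, k))
    counts = {c: 0 for c in cats}
    orphans = []
    for row, label in enumerate(closure.node_labels):
        cat = mapping.category_for(label, map_name)
        if cat is None:
            orphans.append(label)
            continue
        membership[row, cat_index[cat]] = 1.0
        counts[cat] += 1
    if orphans:
        raise MappingError(
            f"map {map_name!r}: factors with no category: {orphans}"
        )
    cumulative = membership.T @ closure.values @ membership
    catmap = CategoryInfluenceMap(
        category_order=list(cats),
        cumulative=cumulative,
        outcome_category=mapping.outcome_category,
        factor_counts=counts,
        provenance=(map_name,),
        display_names=dict(mapping.display_names),
    )
    return normalize_cni(catmap, scope)


def normalize_cni(catmap: CategoryInfluenceMap, scope: str = "outcome-column"):
    """Divide every cumulative weight by the maximum absolute cumulative
    weight over ``scope``; an all-zero scope passes through unchanged (no
    division).  Idempotent and scale-invariant by construction."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    cum = catmap.cumulative
    if scope == "outcome-column":
        denom = np.max(np.abs(cum[:, catmap.outcome_index])) if cum.size else 0.0
    else:
        denom = np.max(np.abs(cum)) if cum.size else 0.0
    cni = cum / denom if denom > 0 else cum.copy()
    out = replace(catmap)
    out.cni = cni
    out.outcome_cni = cni[:, catmap.outcome_index] if cni.size else np.zeros(0)
    out.scope = scope
    return out


def combine_group_maps(
    catmaps: Sequence[CategoryInfluenceMap],
    weights: Sequence[float],
) -> CategoryInfluenceMap:
    """Weighted average of group category maps on pre-normalization
    cumulative weights; weights are the participant counts of each group.

    Category universes are merged by union (absent categories contribute 0);
    the result is re-normalized under the scope shared by the inputs.
    """
    if len(catmaps) < 2:
        raise ValueError("need at least two maps to combine")
    if len(weights) != len(catmaps):
        raise ValueError(
            f"{len(catmaps)} maps but {len(weights)} weights"
        )
    if any(w <= 0 for w in weights):
        raise ValueError("group weights must be positive")
    outcomes = {m.outcome_category for m in catmaps}
    if len(outcomes) != 1:
        raise ValueError(f"maps disagree on the outcome category: {outcomes}")
    scopes = {m.scope for m in catmaps if m.scope is not None}
    scope = scopes.pop() if len(scopes) == 1 else "outcome-column"

    union: list[str] = []
    for m in catmaps:
        for c in m.category_order:
            if c not in union:
                union.append(c)
    k = len(union)
    idx = {c: i for i, c in enumerate(union)}
    total = float(sum(weights))
    cumulative = np.zeros((k, k))
    counts = {c: 0 for c in union}
    names: dict[str, str] = {}
    for m, w in zip(catmaps, weights):
        rows = [idx[c] for c in m.category_order]
        cumulative[np.ix_(rows, rows)] += (w / total) * m.cumulative
        for c in m.category_order:
            counts[c] += m.n_factors(c)
        names.update(m.display_names)
    combined = CategoryInfluenceMap(
        category_order=union,
        cumulative=cumulative,
        outcome_category=catmaps[0].outcome_category,
        factor_counts=counts,
        provenance=tuple(p for m in catmaps for p in m.provenance),
        display_names=names,
    )
    return normalize_cni(combined, scope)


def combine_closures(
    closures: Sequence[InfluenceMatrix], weights: Sequence[float]
) -> InfluenceMatrix:
    """Factor-level alternative to :func:`combine_group_maps`: weighted
    average of closure matrices over the union of factor labels (matched
    after canonicalization; factors absent from a map contribute 0)."""
    if len(closures) < 2:
        raise ValueError("need at least two closures to combine")
    if len(weights) != len(closures) or any(w <= 0 for w in weights):
        raise ValueError("weights must align with closures and be positive")
    union_labels: list[str] = []
    keys: list[str] = []
    for c in closures:
        for label in c.node_labels:
            key = normalize_label(label)
            if key not in keys:
                keys.append(key)
                union_labels.append(label)
    idx = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    total = float(sum(weights))
    avg = np.zeros((n, n))
    for c, w in zip(closures, weights):
        rows = [idx[normalize_label(lbl)] for lbl in c.node_labels]
        avg[np.ix_(rows, rows)] += (w / total) * c.values
    pos = np.where(avg > 0, avg, 0.0)
    neg = np.where(avg < 0, -avg, 0.0)
    return InfluenceMatrix(
        node_order=[f"U{i + 1:02d}" for i in range(n)],
        node_labels=union_labels,
        pos=pos,
        neg=neg,
        source_map="+".join(c.source_map for c in closures),
    )
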