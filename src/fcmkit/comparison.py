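"""Cross-group comparison of category maps.

Two stakeholder groups' category maps are compared row by row (one row per
category in the union of the two universes):

* **validated** -- the category is present (has member factors) in both maps
  and the outcome-directed influences do not oppose in sign (a zero CNI with
  presence counts as non-opposing);
* **non-validated** -- present in exactly one map;
* **conflicting** -- present in both with strictly opposite nonzero signs.

Each row also carries the absolute CNI difference, and the table summarizes
agreement as the *average difference*: the sum of absolute differences
divided by the number of rows.  Values nearer 1 indicate less agreement
about the weight of the relationships.  Differences are computed from
full-precision CNI and printed at 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import CategoryInfluenceMap
from .errors import ScopeMismatchError

__all__ = [
    "VALIDATED",
    "NON_VALIDATED",
    "CONFLICTING",
    "ComparisonRow",
    "ComparisonTable",
    "classify_connection",
    "compare_category_maps",
    "average_difference",
]

VALIDATED = "validated"
NON_VALIDATED = "non-validated"
CONFLICTING = "conflicting"

#: Short report labels, as conventionally printed.
SHORT_LABELS = {VALIDATED: "Val.", NON_VALIDATED: "Nval.", CONFLICTING: "Con."}


def classify_connection(
    present_a: bool, present_b: bool, sign_a: int, sign_b: int
) -> str:
    """Validation label for one category given presence and CNI signs.

    Presence means the category has at least one member factor in that
    group's map; the signs are the signs of the outcome-directed CNI
    (-1, 0, +1).  A category absent from both maps has no defined row.
    """
    if not present_a and not present_b:
        raise ValueError("category absent from both maps: no comparison row exists")
    if present_a != present_b:
        return NON_VALIDATED
    if sign_a * sign_b < 0:
        return CONFLICTING
    return VALIDATED


@dataclass(frozen=True)
class ComparisonRow:
    category: str
    display_name: str
    present_a: bool
    present_b: bool
    n_factors_a: int
    n_factors_b: int
    cni_a: float
    cni_b: float
    validation: str
    difference: float


@dataclass
class ComparisonTable:
    """Per-category cross-group rows plus the average-difference summary."""

    rows: list[ComparisonRow]
    polarity: str = ""
    group_a: str = ""
    group_b: str = ""

    @property
    def average_difference(self) -> float:
        return average_difference([r.difference for r in self.rows])

    @property
    def counts(self) -> dict[str, int]:
        out = {VALIDATED: 0, NON_VALIDATED: 0, CONFLICTING: 0}
        for r in self.rows:
            out[r.validation] += 1
        return out

    def row(self, category: str) -> ComparisonRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "display_name": r.display_name,
                    "n_factors_a": r.n_factors_a,
                    "cni_a": round(r.cni_a, 2),
                    "n_factors_b": r.n_factors_b,
                    "cni_b": round(r.cni_b, 2),
                    "validation": SHORT_LABELS[r.validation],
                    "difference": round(r.difference, 2),
                }
                for r in self.rows
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        """Report CSV with a totals footer (factor totals and the average
        difference), mirroring the printed comparison tables."""
        df = self.to_dataframe()
        footer = pd.DataFrame(
            [
                {
                    "category": "TOTAL",
                    "display_name": "",
                    "n_factors_a": df["n_factors_a"].sum(),
                    "cni_a": "",
                    "n_factors_b": df["n_factors_b"].sum(),
                    "cni_b": "",
                    "validation": "",
                    "difference": round(self.average_difference, 2),
                }
            ]
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


def average_difference(differences: Sequence[float]) -> float:
    """Mean of absolute per-category CNI differences (the agreement
    statistic); empty input is a value error."""
    if len(differences) == 0:
        raise ValueError("average_difference of an empty sequence is undefined")
    return float(np.mean(np.abs(np.asarray(differences, dtype=float))))


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def compare_category_maps(
    catmap_a: CategoryInfluenceMap,
    catmap_b: CategoryInfluenceMap,
    *,
    polarity: str = "",
    include_outcome: bool = True,
) -> ComparisonTable:
    """Build the per-category comparison table for two normalized maps.

    Both maps must be normalized over the same scope.  The row order is the
    category order of map A followed by categories only in map B; categories
    with zero member factors in both maps are not tabulated.  Set
    ``include_outcome=False`` to leave out the outcome category's own row.
    """
    if catmap_a.outcome_cni is None or catmap_b.outcome_cni is None:
        raise ScopeMismatchError("both maps must be normalized before comparison")
    if catmap_a.scope != catmap_b.scope:
        raise ScopeMismatchError(
            f"normalization scopes differ: {catmap_a.scope!r} vs {catmap_b.scope!r}"
        )
    union = list(catmap_a.category_order)
    for c in catmap_b.category_order:
        if c not in union:
            union.append(c)
    rows: list[ComparisonRow] = []
    for c in union:
        if not include_outcome and c == catmap_a.outcome_category:
            continue
        n_a, n_b = catmap_a.n_factors(c), catmap_b.n_factors(c)
        present_a, present_b = n_a > 0, n_b > 0
        if not present_a and not present_b:
            continue
        cni_a = catmap_a.outcome_cni_of(c) if c in catmap_a.category_order else 0.0
        cni_b = catmap_b.outcome_cni_of(c) if c in catmap_b.category_order else 0.0
        rows.append(
            ComparisonRow(
                category=c,
                display_name=catmap_a.display_names.get(
                    c, catmap_b.display_names.get(c, c)
                ),
                present_a=present_a,
                present_b=present_b,
                n_factors_a=n_a,
                n_factors_b=n_b,
                cni_a=cni_a,
                cni_b=cni_b,
                validation=classify_connection(
                    present_a, present_b, _sign(cni_a), _sign(cni_b)
                ),
                difference=abs(cni_a - cni_b),
            )
        )
    return ComparisonTable(
        rows=rows,
        polarity=polarity,
        group_a=(catmap_a.provenance[0] if catmap_a.provenance else "A"),
        group_b=(catmap_b.provenance[0] if catmap_b.provenance else "B"),
    )
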