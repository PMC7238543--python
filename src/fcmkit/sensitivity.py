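"""Contested-edge sensitivity scan.

When participants cannot agree on the weight of one relationship (in the
study that motivated this package, the protective influence of hospitals),
the disagreement is carried into the analysis instead of being resolved by
fiat: the pipeline is re-run over a grid of raw weights for that edge --
from 0 (no effect; the edge is removed) to 5 (the strongest effect) -- and
the induced variation in each category's outcome CNI is reported.

Re-normalization inside the scan can change *other* categories' CNI even
when their cumulative weight is constant, so the scan records both the
pre-normalization cumulative weights and the normalized CNI; ranges are
reported for both.  The unmodified map is always included as a labelled
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .categories import CategoryInfluenceMap, CategoryMapping, aggregate_to_categories
from .closure import transitive_closure
from .model import FuzzyCognitiveMap, scale_weights

__all__ = ["SensitivityResult", "sensitivity_scan", "DEFAULT_GRID"]

#: Full disagreement span: no effect at all (0) up to the strongest (5).
DEFAULT_GRID = (0, 1, 2, 3, 4, 5)

BASELINE = "baseline"


@dataclass
class SensitivityResult:
    """Outcome of one single-edge scan.

    ``catmap_by_value`` maps each grid value (plus :data:`BASELINE`) to the
    normalized category map obtained with the contested edge set to that
    value.  Ranges are per category, max - min across the grid (baseline
    excluded), for both the normalized CNI and the pre-normalization
    cumulative outcome weight.
    """

    edge: tuple[str, str, str]
    grid: list[int]
    baseline_weight: int
    catmap_by_value: dict[object, CategoryInfluenceMap]

    @property
    def categories(self) -> list[str]:
        return list(self.catmap_by_value[BASELINE].category_order)

    def outcome_cni(self, value) -> dict[str, float]:
        m = self.catmap_by_value[value]
        return {c: m.outcome_cni_of(c) for c in m.category_order}

    def outcome_cumulative(self, value) -> dict[str, float]:
        m = self.catmap_by_value[value]
        col = m.cumulative[:, m.outcome_index]
        return dict(zip(m.category_order, map(float, col)))

    def _range(self, extractor) -> dict[str, float]:
        per_value = [extractor(v) for v in self.grid]
        return {
            c: max(d[c] for d in per_value) - min(d[c] for d in per_value)
            for c in self.categories
        }

    @property
    def cni_range(self) -> dict[str, float]:
        return self._range(self.outcome_cni)

    @property
    def cumulative_range(self) -> dict[str, float]:
        return self._range(self.outcome_cumulative)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form report: one row per (grid value, category)."""
        records = []
        for value in [BASELINE, *self.grid]:
            cni = self.outcome_cni(value)
            cum = self.outcome_cumulative(value)
            for c in self.categories:
                records.append(
                    {
                        "edge_value": value,
                        "category": c,
                        "cumulative_weight": cum[c],
                        "outcome_cni": cni[c],
                    }
                )
        return pd.DataFrame(records)

    def summary_dataframe(self) -> pd.DataFrame:
        cni_r, cum_r = self.cni_range, self.cumulative_range
        return pd.DataFrame(
            {
                "category": self.categories,
                "cumulative_range": [cum_r[c] for c in self.categories],
                "cni_range": [cni_r[c] for c in self.categories],
            }
        )

    def write_csv(self, scan_path: str | Path, summary_path: str | Path) -> None:
        self.to_dataframe().to_csv(scan_path, index=False)
        self.summary_dataframe().to_csv(summary_path, index=False)


def sensitivity_scan(
    fcm: FuzzyCognitiveMap,
    edge: tuple[str, str],
    values: Sequence[int],
    mapping: CategoryMapping,
    *,
    sign: int = 1,
    constant: float = 5.0,
    scope: str = "outcome-column",
) -> SensitivityResult:
    """Scan one contested edge of an *unscaled* map over raw weights.

    For each value the edge's raw weight is substituted (0 removes the
    edge; the edge may also be new, provided both endpoints exist), then the
    full chain scale -> closure -> aggregate -> normalize is re-run.
    ``sign`` applies to the substituted edge when nonzero.
    """
    source, target = edge
    if not (fcm.has_factor(source) and fcm.has_factor(target)):
        raise ValueError(
            f"edge endpoints ({source!r}, {target!r}) must both exist in the map"
        )
    if len(values) == 0:
        raise ValueError("values grid must be non-empty")
    for v in values:
        if v not in (0, 1, 2, 3, 4, 5):
            raise ValueError(f"grid value {v!r} not in {{0}} u {{1..5}}")

    def run(m: FuzzyCognitiveMap) -> CategoryInfluenceMap:
        closed = transitive_closure(scale_weights(m, constant))
        return aggregate_to_categories(
            closed, mapping, map_name=fcm.name or "*", scope=scope
        )

    existing = fcm.edge(source, target)
    baseline_weight = int(existing.weight) if existing is not None else 0
    results: dict[object, CategoryInfluenceMap] = {BASELINE: run(fcm)}
    for v in values:
        variant = fcm.copy()
        if v == 0:
            variant.remove_edge(source, target)
        else:
            variant.set_edge(source, target, v, sign)
        results[v] = run(variant)
    return SensitivityResult(
        edge=(source, target, fcm.name),
        grid=list(values),
        baseline_weight=baseline_weight,
        catmap_by_value=results,
    )
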