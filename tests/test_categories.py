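"""Category aggregation, CNI normalization and group combination."""

import numpy as np
import pytest

from fcmkit import (
    CategoryInfluenceMap,
    CategoryMapping,
    FuzzyCognitiveMap,
    aggregate_to_categories,
    combine_group_maps,
    normalize_cni,
    scale_weights,
    transitive_closure,
)
from fcmkit.errors import MappingError
from conftest import random_map


def closure_of(edges, name="m"):
    fcm = FuzzyCognitiveMap(name=name)
    for node in sorted({n for e in edges for n in e[:2]}):
        fcm.add_factor(node, node)
    for s, t, w, *sign in edges:
        fcm.add_edge(s, t, w, sign[0] if sign else 1)
    return transitive_closure(scale_weights(fcm))


def catmap_from(cumulative, order=("C1", "OUT"), outcome="OUT", counts=None):
    return CategoryInfluenceMap(
        category_order=list(order),
        cumulative=np.asarray(cumulative, dtype=float),
        outcome_category=outcome,
        factor_counts=counts or {c: 1 for c in order},
    )


class TestAggregate:
    def mapping(self, rows, cats, outcome):
        return CategoryMapping(rows, cats, outcome)

    def test_cumulative_is_sum_of_member_influences(self):
        # a -> c 0.4 and b -> c 0.6 with {a,b} in C1, {c} in C2: sum = 1.0
        closure = closure_of([("a", "c", 2), ("b", "c", 3)])
        mapping = self.mapping(
            [("a", "m", "C1"), ("b", "m", "C1"), ("c", "m", "C2")],
            ["C1", "C2"], "C2",
        )
        catmap = aggregate_to_categories(closure, mapping, map_name="m")
        i, j = catmap.category_order.index("C1"), catmap.category_order.index("C2")
        assert catmap.cumulative[i, j] == pytest.approx(1.0)

    def test_within_category_influence_lands_on_diagonal(self):
        closure = closure_of([("a", "b", 3)])  # a -> b 0.6, both in C1
        mapping = self.mapping(
            [("a", "m", "C1"), ("b", "m", "C1")], ["C1"], "C1"
        )
        catmap = aggregate_to_categories(closure, mapping, map_name="m")
        assert catmap.cumulative[0, 0] == pytest.approx(0.6)

    def test_unmapped_factor_lists_orphans(self):
        closure = closure_of([("a", "b", 3)])
        mapping = self.mapping([("a", "m", "C1")], ["C1"], "C1")
        with pytest.raises(MappingError, match="b"):
            aggregate_to_categories(closure, mapping, map_name="m")

    def test_category_with_no_members_has_zero_row_and_column(self):
        closure = closure_of([("a", "b", 3)])
        mapping = self.mapping(
            [("a", "m", "C1"), ("b", "m", "C2")], ["C1", "C2", "C3"], "C2"
        )
        catmap = aggregate_to_categories(closure, mapping, map_name="m")
        k = catmap.category_order.index("C3")
        assert catmap.n_factors("C3") == 0
        assert np.all(catmap.cumulative[k, :] == 0)
        assert np.all(catmap.cumulative[:, k] == 0)

    def test_aggregation_is_linear_in_the_closure(self):
        mapping = self.mapping(
            [("a", "m", "C1"), ("b", "m", "C1"), ("c", "m", "OUT")],
            ["C1", "OUT"], "OUT",
        )
        c1 = closure_of([("a", "c", 2)])
        c2 = closure_of([("b", "c", 4)])
        joint = closure_of([("a", "c", 2), ("b", "c", 4)])
        agg = lambda c: aggregate_to_categories(c, mapping, map_name="m").cumulative
        assert np.allclose(agg(joint), agg(c1) + agg(c2))


class TestNormalize:
    def test_outcome_column_scope_forces_max_to_one(self):
        m = catmap_from([[0.0, 2.5], [0.0, 1.0]])
        out = normalize_cni(m, "outcome-column")
        assert out.outcome_cni == pytest.approx([1.0, 0.4])

    def test_negative_dominant_weight_normalizes_by_magnitude(self):
        m = catmap_from([[0.0, -2.0], [0.0, 1.0]])
        out = normalize_cni(m, "outcome-column")
        assert out.outcome_cni == pytest.approx([-1.0, 0.5])

    def test_all_zero_map_passes_through(self):
        m = catmap_from(np.zeros((2, 2)))
        out = normalize_cni(m, "whole-matrix")
        assert np.all(out.cni == 0)

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        m = catmap_from(rng.normal(size=(4, 4)), order=list("ABCD"), outcome="D")
        once = normalize_cni(m, "whole-matrix")
        twice = normalize_cni(
            catmap_from(once.cni, order=list("ABCD"), outcome="D"), "whole-matrix"
        )
        assert np.allclose(once.cni, twice.cni)
        tripled = catmap_from(3.0 * m.cumulative, order=list("ABCD"), outcome="D")
        assert np.allclose(normalize_cni(tripled, "whole-matrix").cni, once.cni)
        assert np.max(np.abs(once.cni)) == pytest.approx(1.0)


class TestCombine:
    def test_participant_weighted_average(self):
        a = catmap_from([[0.0, 0.29], [0.0, 0.0]])
        b = catmap_from([[0.0, 1.00], [0.0, 0.0]])
        combined = combine_group_maps(
            [normalize_cni(a), normalize_cni(b)], weights=[18, 11]
        )
        # (18 * 0.29 + 11 * 1.00) / 29 before re-normalization
        assert combined.cumulative[0, 1] == pytest.approx(0.5593, abs=1e-4)

    def test_identical_maps_any_weights_combine_to_themselves(self):
        a = normalize_cni(catmap_from([[0.2, 0.8], [0.0, 0.4]]))
        combined = combine_group_maps([a, a], weights=[7, 3])
        assert np.allclose(combined.cumulative, a.cumulative)
        assert np.allclose(combined.cni, a.cni)

    def test_category_absent_from_one_group_contributes_zero(self):
        a = normalize_cni(
            catmap_from([[0.0, 0.5], [0.0, 0.0]], order=["C1", "OUT"])
        )
        b = normalize_cni(
            catmap_from([[0.0, 0.4], [0.0, 0.0]], order=["C2", "OUT"])
        )
        combined = combine_group_maps([a, b], weights=[18, 11])
        i = combined.category_order.index("C1")
        j = combined.category_order.index("OUT")
        assert combined.cumulative[i, j] == pytest.approx(18 * 0.5 / 29)

    def test_equal_weights_is_plain_mean(self):
        a = normalize_cni(catmap_from([[0.0, 0.6], [0.0, 0.0]]))
        b = normalize_cni(catmap_from([[0.0, 0.2], [0.0, 0.0]]))
        combined = combine_group_maps([a, b], weights=[1, 1])
        assert combined.cumulative[0, 1] == pytest.approx(0.4)

    def test_validation_errors(self):
        a = normalize_cni(catmap_from([[0.0, 0.6], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            combine_group_maps([a], weights=[1])
        with pytest.raises(ValueError):
            combine_group_maps([a, a], weights=[1])
        with pytest.raises(ValueError):
            combine_group_maps([a, a], weights=[1, 0])


class TestEndToEnd:
    def test_synthetic_pipeline_invariants(self):
        for seed in range(3):
            fcm, mapping = random_map(seed=seed, n_nodes=12, n_edges=30,
                                      inhibitory_prob=0.1)
            catmap = aggregate_to_categories(
                transitive_closure(fcm), mapping, map_name=fcm.name
            )
            assert np.all(np.abs(catmap.outcome_cni) <= 1 + 1e-12)
            col = np.abs(catmap.cumulative[:, catmap.outcome_index])
            if col.max() > 0:
                assert np.max(np.abs(catmap.outcome_cni)) == pytest.approx(1.0)
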