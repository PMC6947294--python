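"""Keyword-driven gene-set construction, overlaps, Ochiai and UPGMA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylostress.gene_sets import (
    AnnotationRecord,
    OntologyTerm,
    StressGeneSet,
    build_stress_gene_set,
    merge_sets,
    ochiai_distance,
    overlap_stats,
    select_terms_by_keyword,
    upgma_tree,
)


@pytest.fixture
def ontology():
    return [
        OntologyTerm("T1", "response to stress", "any disturbance response"),
        OntologyTerm("T2", "response to heat", "heat response", parents={"T1"}),
        OntologyTerm("T3", "thermal acclimation", "after heat shock", parents={"T2"}),
        OntologyTerm("T4", "seed development", "unrelated process"),
    ]


class TestTermSelection:
    def test_keyword_plus_descendant_closure(self, ontology):
        assert select_terms_by_keyword(ontology, "stress") == {"T1", "T2", "T3"}

    def test_definition_matching_is_case_insensitive(self, ontology):
        assert select_terms_by_keyword(ontology, "HEAT") == {"T2", "T3"}

    def test_no_match_gives_empty_set(self, ontology):
        assert select_terms_by_keyword(ontology, "xylem") == frozenset()

    def test_exclusions_applied_after_closure(self, ontology):
        assert select_terms_by_keyword(ontology, "stress", {"T1", "T2", "T3"}) == frozenset()
        assert select_terms_by_keyword(ontology, "stress", {"T2"}) == {"T1", "T3"}

    def test_cyclic_ontology_rejected(self):
        cyc = [
            OntologyTerm("A", "x", parents={"B"}),
            OntologyTerm("B", "y", parents={"A"}),
        ]
        with pytest.raises(ValueError, match="cycle"):
            select_terms_by_keyword(cyc, "x")


class TestBuildSet:
    def test_evidence_whitelist(self):
        ann = [
            AnnotationRecord("g1", "T2", "IDA"),
            AnnotationRecord("g2", "T2", "IEA"),  # electronic: filtered out
            AnnotationRecord("g3", "T9", "IDA"),  # unselected term
        ]
        gs = build_stress_gene_set(ann, {"T2"}, name="heat")
        assert gs.genes == {"g1"}

    def test_gene_on_two_terms_counted_once(self):
        ann = [AnnotationRecord("g1", "T1", "IMP"), AnnotationRecord("g1", "T2", "IDA")]
        assert len(build_stress_gene_set(ann, {"T1", "T2"})) == 1

    def test_empty_result_allowed(self):
        gs = build_stress_gene_set([AnnotationRecord("g", "T1", "IEA")], {"T1"})
        assert gs.genes == frozenset()


class TestMergeAndOverlap:
    def test_merge_union_semantics(self):
        # 25 water terms and 10 drought terms sharing 6 merge to 29
        water = StressGeneSet("water", {"g1"}, {f"W{i}" for i in range(25)})
        shared = {f"W{i}" for i in range(6)}
        drought = StressGeneSet("drought", {"g2"}, shared | {f"D{i}" for i in range(4)})
        merged = merge_sets(water, drought, "water stress")
        assert len(merged.terms) == 29
        assert merged.genes == {"g1", "g2"}

    def test_merge_idempotent(self):
        a = StressGeneSet("a", {"x", "y"}, {"T"})
        assert merge_sets(a, a, "a").genes == a.genes

    def test_overlap_counts_symmetric_fractions_row_normalised(self):
        a = StressGeneSet("a", {f"g{i}" for i in range(10)}, {"T"})
        b = StressGeneSet("b", {f"g{i}" for i in range(8, 28)}, {"T"})
        ov = overlap_stats([a, b])
        assert ov["counts"].loc["a", "b"] == ov["counts"].loc["b", "a"] == 2
        assert ov["fractions"].loc["a", "b"] == pytest.approx(0.2)
        assert ov["fractions"].loc["b", "a"] == pytest.approx(0.1)
        assert ov["unique"]["a"] == 8 and ov["unique"]["b"] == 18
        assert len(ov["union"].genes) == 28

    def test_identical_sets(self):
        a = StressGeneSet("a", {"x", "y"}, {"T"})
        b = StressGeneSet("b", {"x", "y"}, {"T"})
        ov = overlap_stats([a, b])
        assert ov["fractions"].loc["a", "b"] == 1.0
        assert ov["unique"].tolist() == [0, 0]

    def test_disjoint_sets(self):
        a = StressGeneSet("a", {"x"}, {"T"})
        b = StressGeneSet("b", {"y", "z"}, {"T"})
        ov = overlap_stats([a, b])
        assert ov["counts"].loc["a", "b"] == 0
        assert ov["unique"]["b"] == 2


class TestOchiai:
    def test_hand_value(self):
        assert ochiai_distance({"x", "y"}, {"y", "z"}) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        assert ochiai_distance({"a"}, {"a"}) == 0.0
        assert ochiai_distance({"a"}, {"b"}) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ochiai_distance(set(), {"a"})

    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, a, b):
        assert 0.0 <= ochiai_distance(a, b) <= 1.0


class TestUpgma:
    def test_two_leaves(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma_tree(d)
        assert tree.height == pytest.approx(0.2)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_leaf_hand_agglomeration(self):
        labels = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=labels,
            columns=labels,
        )
        tree = upgma_tree(d)
        assert tree.height == pytest.approx(0.3)  # C joins at 0.6 / 2
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(0.1)
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_equal_distances_tie_broken_lexicographically(self):
        labels = list("ABC")
        d = pd.DataFrame(0.5, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        tree = upgma_tree(d)
        first = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(first.leaves()) == ["A", "B"]

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 0.1], [0.3, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            upgma_tree(d)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(3)
        labels = [f"L{i}" for i in range(6)]
        m = rng.random((6, 6))
        d = pd.DataFrame((m + m.T) / 2, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        tree = upgma_tree(d)

        def depths(node, acc=0.0):
            if node.is_leaf:
                return [acc + node.height]
            return [
                x for c in node.children for x in depths(c, acc + node.height - c.height)
            ]

        # all leaves equidistant from the root
        leaf_depths = depths(tree)
        assert np.allclose(leaf_depths, tree.height)

    def test_matches_scipy_average_linkage_cophenetic(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        labels = [f"L{i}" for i in range(7)]
        m = rng.random((7, 7))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma_tree(pd.DataFrame(d, index=labels, columns=labels))

        mine = {}

        def collect(node):
            if node.is_leaf:
                return [node.name]
            groups = [collect(c) for c in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for x in groups[i]:
                        for y in groups[j]:
                            mine[frozenset((x, y))] = 2 * node.height
            return [x for g in groups for x in g]

        collect(tree)
        sc = squareform(cophenet(linkage(squareform(d), method="average")))
        for i in range(7):
            for j in range(i + 1, 7):
                assert mine[frozenset((labels[i], labels[j]))] == pytest.approx(sc[i, j])
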