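"""Graph structures, orientation propagation, and DAG enumeration."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cider.graph import (
    Dag,
    EnumerationBudgetError,
    GraphInconsistencyError,
    PartiallyDirectedGraph,
    dag_to_pattern,
    enumerate_consistent_dags,
    is_acyclic,
    orientation_closure,
    read_graph_tsv,
    structural_hamming_distance,
    write_graph_tsv,
)


def pdg(directed=(), undirected=(), constant=(), nodes=()):
    g = PartiallyDirectedGraph(nodes)
    for u, v in directed:
        g.add_directed(u, v)
    for u, v in constant:
        g.add_directed(u, v, constant=True)
    for u, v in undirected:
        g.add_undirected(u, v)
    return g


class TestAcyclicity:
    def test_empty_graph_is_acyclic(self):
        assert is_acyclic(PartiallyDirectedGraph())

    def test_three_cycle_detected(self):
        g = pdg(directed=[("A", "B"), ("B", "C"), ("C", "A")])
        assert not is_acyclic(g)

    def test_undirected_edges_ignored(self):
        g = pdg(directed=[("A", "B"), ("B", "C")], undirected=[("A", "C")])
        assert is_acyclic(g)

    def test_dag_constructor_rejects_cycle(self):
        with pytest.raises(GraphInconsistencyError):
            Dag("ABC", [("A", "B"), ("B", "C"), ("C", "A")])


class TestOrientationClosure:
    def test_no_new_vstructure_rule(self):
        # A -> B, B - C, A and C non-adjacent: C -> B would create a collider
        g = pdg(directed=[("A", "B")], undirected=[("B", "C")])
        out = orientation_closure(g)
        assert out.is_directed("B", "C")

    def test_no_cycle_rule(self):
        g = pdg(directed=[("A", "B"), ("B", "C")], undirected=[("A", "C")])
        out = orientation_closure(g)
        assert out.is_directed("A", "C")

    def test_single_undirected_edge_unchanged(self):
        g = pdg(undirected=[("A", "B")])
        out = orientation_closure(g)
        assert out.is_undirected("A", "B")

    def test_idempotent_and_nondestructive(self):
        g = pdg(
            directed=[("A", "B")],
            undirected=[("B", "C"), ("C", "D"), ("B", "D")],
        )
        once = orientation_closure(g)
        twice = orientation_closure(once)
        assert once == twice
        # every original directed edge survives, nothing is deleted
        assert set(g.directed_edges) <= set(once.directed_edges)
        assert once.n_edges == g.n_edges

    def test_conflict_raises(self):
        # D -> A and E -> B each force (via R1) opposite directions on A - B
        g = pdg(directed=[("D", "A"), ("E", "B")], undirected=[("A", "B")])
        with pytest.raises(GraphInconsistencyError):
            orientation_closure(g, on_conflict="raise")
        kept = orientation_closure(g, on_conflict="keep")
        assert kept.is_adjacent("A", "B")


class TestEnumeration:
    def test_chain_has_three_extensions(self):
        # frozen oracle: of the 4 orientation assignments of A-B-C, only
        # A->B<-C is rejected (new collider)
        g = pdg(undirected=[("A", "B"), ("B", "C")])
        dags = enumerate_consistent_dags(g)
        expected = {
            Dag("ABC", [("A", "B"), ("B", "C")]),
            Dag("ABC", [("B", "A"), ("B", "C")]),
            Dag("ABC", [("B", "A"), ("C", "B")]),
        }
        assert set(dags) == expected

    def test_fully_directed_graph_yields_itself(self):
        g = pdg(directed=[("A", "B"), ("B", "C")])
        dags = enumerate_consistent_dags(g)
        assert dags == [Dag("ABC", [("A", "B"), ("B", "C")])]

    def test_constant_context_restricts_orientations(self):
        # A - B with A -> C, B -> C directed: both orientations of A - B
        # are acyclic; neither creates a new collider (A, B adjacent)
        g = pdg(constant=[("A", "C")], directed=[("B", "C")], undirected=[("A", "B")])
        dags = enumerate_consistent_dags(g)
        assert len(dags) == 2
        for d in dags:
            assert ("A", "C") in d.edges and ("B", "C") in d.edges

    def test_budget_guard(self):
        g = PartiallyDirectedGraph()
        for k in range(14):
            g.add_undirected(f"n{k:02d}", f"m{k:02d}")
        with pytest.raises(EnumerationBudgetError):
            enumerate_consistent_dags(g, max_undirected=12)

    def test_extensions_preserve_skeleton_and_vstructures(self):
        g = pdg(
            directed=[("A", "C"), ("B", "C")],
            undirected=[("C", "D"), ("D", "E"), ("A", "E")],
        )
        base_v = g.v_structures()
        for dag in enumerate_consistent_dags(g):
            assert is_acyclic(dag)
            for u, v in itertools.combinations(dag.nodes, 2):
                assert dag.is_adjacent(u, v) == g.is_adjacent(u, v)
            # no collider beyond those already present
            for c in dag.nodes:
                for a, b in itertools.combinations(sorted(dag.parents(c)), 2):
                    if not dag.is_adjacent(a, b):
                        assert (a, c, b) in base_v

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_pattern_extensions_contain_source_dag(self, seed):
        """Any DAG is among the consistent extensions of its own pattern."""
        import numpy as np

        rng = np.random.default_rng(seed)
        nodes = [f"n{k}" for k in range(6)]
        order = rng.permutation(6)
        edges = [
            (nodes[order[i]], nodes[order[j]])
            for i in range(6)
            for j in range(i + 1, 6)
            if rng.random() < 0.35
        ]
        dag = Dag(nodes, edges)
        pattern = dag_to_pattern(dag)
        assert dag in enumerate_consistent_dags(pattern, max_undirected=15)


class TestPatternAndShd:
    def test_chain_pattern_is_undirected(self):
        pattern = dag_to_pattern(Dag("ABC", [("A", "B"), ("B", "C")]))
        assert pattern.undirected_edges == [("A", "B"), ("B", "C")]

    def test_collider_pattern_is_compelled(self):
        pattern = dag_to_pattern(Dag("ABC", [("A", "C"), ("B", "C")]))
        assert pattern.directed_edges == [("A", "C"), ("B", "C")]

    def test_shd_counts_mark_mismatches(self):
        a = pdg(directed=[("A", "B")], undirected=[("B", "C")])
        b = pdg(directed=[("B", "A")], nodes="ABC")
        # A-B: direction differs (1); B-C: present vs absent (1)
        assert structural_hamming_distance(a, b) == 2
        assert structural_hamming_distance(a, a) == 0


class TestSerialization:
    def test_round_trip(self, tmp_path):
        g = pdg(
            directed=[("A", "B")],
            constant=[("C", "B")],
            undirected=[("B", "D")],
        )
        path = tmp_path / "graph.tsv"
        write_graph_tsv(g, path)
        back = read_graph_tsv(path)
        assert back == g
        assert back.is_constant("C", "B")

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("from\tto\n")
        with pytest.raises(ValueError, match="header"):
            read_graph_tsv(path)
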