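"""Conditional-independence testing and structure learning."""

import numpy as np
import pytest

from cider._rng import spawn_rng
from cider.graph import PartiallyDirectedGraph
from cider.knowledge import KnowledgeRecord, KnowledgeSet
from cider.simulate import (
    NoiseSpec,
    SimulatedNetwork,
    generate_expression,
    generate_network,
    sample_knowledge,
)
from cider.structure import (
    fisher_z_ci_test,
    learn_skeleton,
    learn_structure,
    orient_vstructures,
)
from cider.graph import Dag

from conftest import make_expression


class TestFisherZ:
    def test_exactly_orthogonal_columns_independent(self, rng):
        a = rng.normal(size=500)
        a = a - a.mean()
        b = rng.normal(size=500)
        b = b - b.mean()
        b = b - a * (a @ b) / (a @ a)  # residualise: r = 0 exactly
        data = make_expression(
            {"A": a, "B": b}, {"A": "mirna", "B": "mrna"}
        )
        res = fisher_z_ci_test(data, "A", "B", alpha=0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.independent

    def test_near_identical_columns_dependent(self, rng):
        a = rng.normal(size=200)
        data = make_expression(
            {"A": a, "B": a + 1e-3 * rng.normal(size=200)},
            {"A": "mirna", "B": "mrna"},
        )
        res = fisher_z_ci_test(data, "A", "B", alpha=0.01)
        assert not res.independent

    def test_chain_middle_node_screens_off(self):
        """(A ⟂ C | B) on chain data should hold in ≈ 1 - alpha of draws."""
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(rep)
            a = rng.normal(size=5000)
            b = 0.8 * a + rng.normal(size=5000)
            c = 0.8 * b + rng.normal(size=5000)
            data = make_expression(
                {"A": a, "B": b, "C": c},
                {"A": "mirna", "B": "mrna", "C": "mrna"},
            )
            if fisher_z_ci_test(data, "A", "C", {"B"}, alpha=0.01).independent:
                hits += 1
        # expected rejection rate ≈ alpha; allow generous binomial slack
        assert hits >= 190

    def test_precondition_checks(self, chain_data):
        with pytest.raises(ValueError):
            fisher_z_ci_test(chain_data, "A", "A")
        with pytest.raises(ValueError):
            fisher_z_ci_test(chain_data, "A", "C", {"A"})


class TestLearnSkeleton:
    def test_chain_recovery_rate(self):
        """Large-sample skeleton of A -> B -> C: edges A-B, B-C, sepset {B}."""
        exact = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            a = rng.normal(size=5000)
            b = 0.6 * a + rng.normal(size=5000)
            c = 0.6 * b + rng.normal(size=5000)
            data = make_expression(
                {"A": a, "B": b, "C": c},
                {"A": "mirna", "B": "mrna", "C": "mrna"},
            )
            g = learn_skeleton(data)
            ok = (
                g.is_adjacent("A", "B")
                and g.is_adjacent("B", "C")
                and not g.is_adjacent("A", "C")
                and g.sepsets.get(frozenset(("A", "C"))) == frozenset({"B"})
            )
            exact += ok
        assert exact >= 45  # >= 90% exact recovery

    def test_constant_edge_immune_to_ci_removal(self, rng):
        # A and C independent in the data, but knowledge pins A -> C
        data = make_expression(
            {"A": rng.normal(size=1000), "C": rng.normal(size=1000)},
            {"A": "mirna", "C": "mrna"},
        )
        knowledge = KnowledgeSet([KnowledgeRecord("A", "C", "mirna_mrna")])
        g = learn_skeleton(data, constant_edges=knowledge)
        assert g.is_directed("A", "C")
        assert g.is_constant("A", "C")

    def test_empty_graph_type_i_error_calibrated(self):
        retained = 0
        pairs = 0
        for rep in range(20):
            net = generate_network(15, 0.0, rng=spawn_rng(7, "t1err", rep))
            data = generate_expression(net, 800, rng=spawn_rng(7, "t1err-x", rep))
            g = learn_skeleton(data, alpha=0.01)
            retained += g.n_edges
            pairs += 15 * 14 // 2
        assert retained / pairs < 0.03


class TestOrientVstructures:
    def test_collider_oriented(self):
        g = PartiallyDirectedGraph("ABC")
        g.add_undirected("A", "C")
        g.add_undirected("B", "C")
        g.sepsets[frozenset(("A", "B"))] = frozenset()
        out = orient_vstructures(g)
        assert out.is_directed("A", "C") and out.is_directed("B", "C")

    def test_chain_not_oriented(self):
        g = PartiallyDirectedGraph("ABC")
        g.add_undirected("A", "B")
        g.add_undirected("B", "C")
        g.sepsets[frozenset(("A", "C"))] = frozenset({"B"})
        out = orient_vstructures(g)
        assert out.is_undirected("A", "B") and out.is_undirected("B", "C")

    def test_constant_edge_untouched(self):
        g = PartiallyDirectedGraph("ABC")
        g.add_directed("A", "C", constant=True)
        g.add_undirected("B", "C")
        g.sepsets[frozenset(("A", "B"))] = frozenset()
        out = orient_vstructures(g)
        assert out.is_directed("B", "C")
        assert out.is_directed("A", "C") and out.is_constant("A", "C")

    def test_dependence_test_vetoes_weak_triples(self):
        g = PartiallyDirectedGraph("ABC")
        g.add_undirected("A", "C")
        g.add_undirected("B", "C")
        g.sepsets[frozenset(("A", "B"))] = frozenset()
        out = orient_vstructures(g, dependence_test=lambda i, k, cond: False)
        assert out.is_undirected("A", "C") and out.is_undirected("B", "C")


class TestLearnStructure:
    def test_constant_edges_orient_neighbour_edges(self):
        """Knowledge-driven orientation: the miR-200 style scenario.

        True graph: mirA -> TARGET <- mirB (both validated, supplied as
        knowledge), TARGET -> mirC, mirB -> Q.  The learner must keep both
        constant edges, orient TARGET -> mirC away from the collider, and
        stay acyclic.
        """
        edges = [
            ("mirA", "TARGET"),
            ("mirB", "TARGET"),
            ("TARGET", "mirC"),
            ("mirB", "Q"),
        ]
        net = SimulatedNetwork(
            dag=Dag(["mirA", "mirB", "mirC", "Q", "TARGET"], edges),
            roles={
                "mirA": "mirna", "mirB": "mirna", "mirC": "mirna",
                "Q": "mrna", "TARGET": "mrna",
            },
            weights={e: 0.8 for e in edges},
            intercepts={n: 0.0 for n in ["mirA", "mirB", "mirC", "Q", "TARGET"]},
            noise=NoiseSpec(),
        )
        data = generate_expression(net, 4000, seed=11)
        knowledge = KnowledgeSet(
            [
                KnowledgeRecord("mirA", "TARGET", "mirna_mrna"),
                KnowledgeRecord("mirB", "TARGET", "mirna_mrna"),
            ]
        )
        g = learn_structure(data, knowledge=knowledge)
        assert g.is_directed("mirA", "TARGET") and g.is_constant("mirA", "TARGET")
        assert g.is_directed("mirB", "TARGET") and g.is_constant("mirB", "TARGET")
        assert g.is_directed("TARGET", "mirC")  # forced: no new collider
        from cider.graph import is_acyclic

        assert is_acyclic(g)

    def test_independent_data_gives_near_empty_graph(self):
        net = generate_network(12, 0.0, seed=5)
        data = generate_expression(net, 1000, seed=5)
        g = learn_structure(data)
        assert g.n_edges <= 2

    def test_full_knowledge_guarantees_true_edges(self):
        net = generate_network(30, 0.15, seed=9)
        data = generate_expression(net, 200, seed=9)
        knowledge = sample_knowledge(net, 1.0, seed=9)
        g = learn_structure(data, knowledge=knowledge)
        for rec in knowledge:
            assert g.is_directed(rec.regulator, rec.target)

    def test_order_independence(self):
        """Permuting gene columns leaves the learned graph unchanged."""
        net = generate_network(25, 0.15, seed=13)
        data = generate_expression(net, 400, seed=13)
        g1 = learn_structure(data)
        permuted = data.values[list(np.random.default_rng(0).permutation(data.genes))]
        data2 = make_expression(
            {c: permuted[c].to_numpy() for c in permuted.columns}, data.roles
        )
        g2 = learn_structure(data2)
        assert g1 == g2

    def test_adding_knowledge_never_drops_constant_edges(self):
        net = generate_network(30, 0.15, seed=21)
        data = generate_expression(net, 250, seed=21)
        small = sample_knowledge(net, 0.2, seed=4)
        large = sample_knowledge(net, 0.6, seed=4)
        assert small.pairs <= large.pairs  # nested by construction
        g = learn_structure(data, knowledge=large)
        for rec in small:
            assert g.is_directed(rec.regulator, rec.target)
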