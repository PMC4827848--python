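"""Causal-effect estimation: regression form, zero branch, lower bounds."""

import numpy as np
import pytest

from cider._rng import spawn_rng
from cider.effects import (
    causal_effect_bound,
    causal_effect_in_dag,
    effects_matrix,
    valid_parent_sets,
)
from cider.graph import (
    Dag,
    PartiallyDirectedGraph,
    dag_to_pattern,
    enumerate_consistent_dags,
)
from cider.simulate import NoiseSpec, SimulatedNetwork, generate_expression, generate_network
from cider.structure import learn_structure

from conftest import make_expression


def two_node_data(rng, w=0.7, n=5000):
    x = rng.normal(size=n)
    y = w * x + rng.normal(size=n)
    return make_expression({"X": x, "Y": y}, {"X": "mirna", "Y": "mrna"})


class TestEffectInDag:
    def test_zero_when_effect_is_parent_of_cause(self, rng):
        data = two_node_data(rng)
        dag = Dag(["X", "Y"], [("Y", "X")])
        assert causal_effect_in_dag(data, dag, "X", "Y") == 0.0

    def test_recovers_edge_weight(self):
        estimates = [
            causal_effect_in_dag(
                two_node_data(np.random.default_rng(rep)),
                Dag(["X", "Y"], [("X", "Y")]),
                "X",
                "Y",
            )
            for rep in range(10)
        ]
        assert np.mean(estimates) == pytest.approx(0.7, abs=0.02)
        assert all(abs(e - 0.7) < 0.05 for e in estimates)

    def test_adjustment_removes_confounding(self, rng):
        # Z -> X, Z -> Y, X -> Y with weights (1, 1, 0.5).  Closed-form SEM
        # analysis: adjusted coefficient = 0.5, marginal = 1.0.
        n = 10000
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + 0.5 * x + rng.normal(size=n)
        data = make_expression(
            {"X": x, "Y": y, "Z": z},
            {"X": "mirna", "Y": "mrna", "Z": "mrna"},
        )
        dag = Dag(["X", "Y", "Z"], [("Z", "X"), ("Z", "Y"), ("X", "Y")])
        adjusted = causal_effect_in_dag(data, dag, "X", "Y")
        marginal = np.polyfit(x, y, 1)[0]
        assert adjusted == pytest.approx(0.5, abs=0.05)
        assert marginal == pytest.approx(1.0, abs=0.05)

    def test_collinear_design_raises(self, rng):
        x = rng.normal(size=100)
        data = make_expression(
            {"X": x, "X2": 2 * x, "Y": rng.normal(size=100)},
            {"X": "mirna", "X2": "mrna", "Y": "mrna"},
        )
        dag = Dag(["X", "X2", "Y"], [("X2", "X"), ("X", "Y")])
        with pytest.raises(ValueError, match="rank-deficient"):
            causal_effect_in_dag(data, dag, "X", "Y")


class TestParentSets:
    def test_no_undirected_neighbours_single_set(self):
        g = PartiallyDirectedGraph("ABC")
        g.add_directed("B", "A", constant=True)
        g.add_directed("A", "C")
        assert valid_parent_sets(g, "A") == [("B",)]

    def test_new_collider_subsets_rejected(self):
        # A - B, A - C with B, C non-adjacent: {B, C} would collide at A
        g = PartiallyDirectedGraph("ABC")
        g.add_undirected("A", "B")
        g.add_undirected("A", "C")
        assert valid_parent_sets(g, "A") == [(), ("B",), ("C",)]


class TestEffectBound:
    def test_fully_directed_graph_matches_single_dag(self, rng):
        data = two_node_data(rng)
        g = PartiallyDirectedGraph(["X", "Y"])
        g.add_directed("X", "Y")
        dag = Dag(["X", "Y"], [("X", "Y")])
        assert causal_effect_bound(data, g, "X", "Y") == pytest.approx(
            causal_effect_in_dag(data, dag, "X", "Y")
        )

    def test_undirected_edge_gives_zero_bound(self, rng):
        # one consistent orientation makes Y a parent of X, so the minimum
        # absolute effect is the zero branch
        data = two_node_data(rng)
        g = PartiallyDirectedGraph(["X", "Y"])
        g.add_undirected("X", "Y")
        assert causal_effect_bound(data, g, "X", "Y") == 0.0

    def test_matches_global_enumeration_oracle(self):
        """Local parent-set enumeration equals min-|effect| over all
        consistent DAG extensions on small random patterns."""
        checked = 0
        attempt = 0
        while checked < 10:
            rng = spawn_rng(42, "oracle-unit", attempt)
            attempt += 1
            net = generate_network(
                int(rng.integers(4, 8)), 0.4, rng=rng, restrict_roles=False
            )
            pattern = dag_to_pattern(net.dag)
            if len(pattern.undirected_edges) > 6:
                continue
            checked += 1
            data = generate_expression(net, 150, rng=rng)
            dags = enumerate_consistent_dags(pattern)
            for cause in pattern.nodes:
                for effect in pattern.nodes:
                    if cause == effect:
                        continue
                    bound = causal_effect_bound(data, pattern, cause, effect)
                    oracle = min(
                        abs(causal_effect_in_dag(data, d, cause, effect))
                        for d in dags
                    )
                    assert abs(bound) == pytest.approx(oracle, abs=1e-8)


class TestEffectsMatrix:
    def test_shape_and_near_zero_for_empty_graph(self):
        net = generate_network(10, 0.0, seed=3)
        data = generate_expression(net, 500, seed=3)
        g = learn_structure(data)
        eff = effects_matrix(data, g)
        assert eff.shape == (len(data.mirnas), len(data.mrnas))
        assert np.abs(eff.to_numpy()).max() < 0.2

    def test_true_edges_score_higher_than_non_edges(self):
        gaps = []
        for rep in range(5):
            net = generate_network(20, 0.25, rng=spawn_rng(3, "sep", rep))
            data = generate_expression(net, 1000, rng=spawn_rng(3, "sep-x", rep))
            g = learn_structure(data)
            eff = effects_matrix(data, g).abs()
            truth = set(net.edges_of_type("mirna_mrna"))
            if not truth:
                continue
            on = [eff.loc[u, v] for u, v in truth]
            off = [
                eff.loc[u, v]
                for u in eff.index
                for v in eff.columns
                if (u, v) not in truth
            ]
            gaps.append(np.mean(on) - np.mean(off))
        assert np.mean(gaps) > 0.1

    def test_scale_equivariance(self, rng):
        data = two_node_data(rng)
        g = PartiallyDirectedGraph(["X", "Y"])
        g.add_directed("X", "Y")
        base = effects_matrix(data, g).loc["X", "Y"]
        scaled = make_expression(
            {"X": data.column("X"), "Y": 3.0 * data.column("Y")},
            data.roles,
        )
        assert effects_matrix(scaled, g).loc["X", "Y"] == pytest.approx(3 * base)
        scaled_cause = make_expression(
            {"X": 2.0 * data.column("X"), "Y": data.column("Y")},
            data.roles,
        )
        assert effects_matrix(scaled_cause, g).loc["X", "Y"] == pytest.approx(base / 2)
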