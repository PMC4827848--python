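"""Reproducible validation experiments.

Each function runs one self-contained study — oracle equivalence of the
local effect-bound enumeration, the constant-edge guarantee, parameter
recovery, conditional-independence calibration, skeleton consistency,
and the knowledge-sweep / baseline comparison — and returns its summary
statistics as a plain dict.  They are used both by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from ._rng import spawn_rng
from .baselines import lasso_scores, pearson_scores, zscore_scores
from .data import ExpressionMatrix
from .effects import causal_effect_bound, causal_effect_in_dag
from .evaluate import (
    SweepConfig,
    f_score,
    knowledge_sweep,
    summarize_sweep,
    top_n_global,
)
from .graph import (
    Dag,
    dag_to_pattern,
    enumerate_consistent_dags,
    structural_hamming_distance,
)
from .simulate import (
    NoiseSpec,
    SimulatedNetwork,
    generate_expression,
    generate_network,
    sample_knowledge,
)
from .structure import learn_skeleton, learn_structure

__all__ = [
    "oracle_equivalence",
    "constant_edge_retention",
    "two_node_effect_recovery",
    "ci_test_calibration",
    "skeleton_consistency",
    "sweep_with_baselines",
]


def _random_pattern(rng: np.random.Generator, n_nodes: int, edge_prob: float):
    """A random DAG and its pattern (CPDAG)."""
    net = generate_network(
        n_nodes, edge_prob, rng=rng, restrict_roles=False
    )
    return net, dag_to_pattern(net.dag)


def oracle_equivalence(
    n_graphs: int = 50,
    seed: int = 1,
    n_samples: int = 200,
    max_undirected: int = 5,
) -> dict:
    """Local effect-bound enumeration vs. exhaustive DAG enumeration.

    On random patterns of <= 7 nodes with <= ``max_undirected`` undirected
    edges, the lower-bound effect must match the minimum |effect| over all
    consistent DAG extensions for every ordered gene pair.
    """
    max_diff = 0.0
    n_pairs = 0
    produced = 0
    attempt = 0
    while produced < n_graphs:
        rng = spawn_rng(seed, "oracle-graph", attempt)
        attempt += 1
        n_nodes = int(rng.integers(4, 8))
        net, pattern = _random_pattern(rng, n_nodes, edge_prob=0.4)
        if len(pattern.undirected_edges) > max_undirected:
            continue
        produced += 1
        data = generate_expression(net, n_samples, rng=rng)
        dags = enumerate_consistent_dags(pattern)
        genes = pattern.nodes
        for cause in genes:
            for effect in genes:
                if cause == effect:
                    continue
                bound = causal_effect_bound(data, pattern, cause, effect)
                oracle = min(
                    abs(causal_effect_in_dag(data, d, cause, effect))
                    for d in dags
                )
                max_diff = max(max_diff, abs(abs(bound) - oracle))
                n_pairs += 1
    return {"max_abs_diff": max_diff, "n_pairs": n_pairs, "n_graphs": produced}


def constant_edge_retention(
    n_networks: int = 20,
    n_nodes: int = 100,
    n_samples: int = 250,
    edge_prob: float = 0.2,
    fraction: float = 0.25,
    seed: int = 1,
) -> dict:
    """Fraction of supplied knowledge edges present and correctly directed
    in the learned structure (must be every single one)."""
    n_known = 0
    n_retained = 0
    for rep in range(n_networks):
        net = generate_network(
            n_nodes, edge_prob, rng=spawn_rng(seed, "retention-net", rep)
        )
        data = generate_expression(
            net, n_samples, rng=spawn_rng(seed, "retention-data", rep)
        )
        knowledge = sample_knowledge(net, fraction, seed=seed + rep)
        graph = learn_structure(data, knowledge=knowledge)
        for rec in knowledge:
            n_known += 1
            if graph.is_directed(rec.regulator, rec.target) and graph.is_constant(
                rec.regulator, rec.target
            ):
                n_retained += 1
    pct = 100.0 * n_retained / n_known if n_known else float("nan")
    return {"retention_pct": pct, "n_knowledge_edges": n_known}


def two_node_effect_recovery(
    n_seeds: int = 100,
    n_samples: int = 5000,
    weight: float = 0.7,
    seed: int = 1,
    tolerance: float = 0.05,
) -> dict:
    """Estimate the X -> Y effect on data from a two-node model with the
    true DAG fixed; reports the mean estimate and per-seed hit rate."""
    dag = Dag(["X", "Y"], [("X", "Y")])
    net = SimulatedNetwork(
        dag=dag,
        roles={"X": "mirna", "Y": "mrna"},
        weights={("X", "Y"): weight},
        intercepts={"X": 0.0, "Y": 0.0},
        noise=NoiseSpec(),
    )
    estimates = []
    for rep in range(n_seeds):
        data = generate_expression(
            net, n_samples, rng=spawn_rng(seed, "two-node", rep)
        )
        estimates.append(causal_effect_in_dag(data, dag, "X", "Y"))
    estimates = np.asarray(estimates)
    within = int(np.sum(np.abs(estimates - weight) <= tolerance))
    return {
        "mean_estimate": float(estimates.mean()),
        "n_within_tolerance": within,
        "n_seeds": n_seeds,
        "true_weight": weight,
    }


def ci_test_calibration(
    n_nodes: int = 20,
    n_samples: int = 1000,
    alpha: float = 0.01,
    n_replicates: int = 200,
    seed: int = 1,
) -> dict:
    """Edge-retention rate of skeleton learning on data from the empty
    graph (mutually independent genes); should sit near ``alpha``."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    retained = 0
    for rep in range(n_replicates):
        net = generate_network(
            n_nodes, edge_prob=0.0, rng=spawn_rng(seed, "calib-net", rep)
        )
        data = generate_expression(
            net, n_samples, rng=spawn_rng(seed, "calib-data", rep)
        )
        skel = learn_skeleton(data, alpha=alpha)
        retained += skel.n_edges
    rate = retained / (n_pairs * n_replicates)
    return {
        "retention_rate": rate,
        "alpha": alpha,
        "n_tests": n_pairs * n_replicates,
    }


def skeleton_consistency(
    n_seeds: int = 20,
    n_nodes: int = 10,
    n_samples: int = 10000,
    edge_prob: float = 0.22,
    seed: int = 1,
) -> dict:
    """Structural Hamming distance between the learned structure and the
    true pattern on sparse random DAGs at large sample size."""
    distances = []
    for rep in range(n_seeds):
        rng = spawn_rng(seed, "shd", rep)
        net = generate_network(
            n_nodes, edge_prob, rng=rng, restrict_roles=False
        )
        data = generate_expression(net, n_samples, rng=rng)
        learned = learn_structure(data)
        truth = dag_to_pattern(net.dag)
        distances.append(structural_hamming_distance(learned, truth))
    return {
        "median_shd": float(np.median(distances)),
        "distances": distances,
        "n_seeds": n_seeds,
    }


def sweep_with_baselines(
    n_networks: int = 10,
    n_nodes: int = 100,
    n_samples: int = 250,
    edge_prob: float = 0.2,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5),
    seed: int = 1,
    lasso_random_state: int = 0,
) -> dict:
    """Knowledge sweep plus baseline F-scores on the same replicates.

    Returns the per-cell sweep table (as records), the per-(type, fraction)
    summary, and mean F of the three baselines computed with the same
    global top-N rule (N = number of true miRNA->mRNA edges).
    """
    config = SweepConfig(
        n_networks=n_networks,
        n_nodes=n_nodes,
        n_samples=n_samples,
        edge_prob=edge_prob,
        fractions=fractions,
        seed=seed,
    )
    results = knowledge_sweep(config)
    summary = summarize_sweep(results)

    baseline_f: dict[str, list[float]] = {"pearson": [], "lasso": [], "zscore": []}
    for rep in range(n_networks):
        net = generate_network(
            n_nodes,
            edge_prob,
            rng=spawn_rng(seed, "sweep-network", rep),
        )
        data = generate_expression(
            net, n_samples, rng=spawn_rng(seed, "sweep-data", rep)
        )
        truth = set(net.edges_of_type("mirna_mrna"))
        if not truth:
            continue
        scorers = {
            "pearson": pearson_scores(data),
            "lasso": lasso_scores(data, random_state=lasso_random_state),
            "zscore": zscore_scores(data),
        }
        for name, scores in scorers.items():
            predicted = top_n_global(scores, len(truth))
            baseline_f[name].append(f_score(predicted, truth).f_score)

    return {
        "sweep": results,
        "summary": summary,
        "baseline_mean_f": {
            k: float(np.mean(v)) for k, v in baseline_f.items()
        },
        "baseline_se_f": {
            k: float(np.std(v, ddof=1) / np.sqrt(len(v)))
            for k, v in baseline_f.items()
        },
    }
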