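"""Prediction extraction, precision/recall/F-score, and the knowledge sweep.

The sweep experiment mirrors the simulation study design: for each
replicate network, knowledge of a given type (transcriptional TF->miRNA,
post-transcriptional miRNA->mRNA, or both combined) is sampled at a grid
of fractions of the true edges, the structure is re-learned with that
knowledge, and the ranked causal-effect matrix is scored against the true
miRNA->mRNA edge set.

Score matrices become edge predictions by taking the top-N pairs
*globally* with N equal to the number of true miRNA->mRNA edges, which
makes precision = recall = F and removes the arbitrary cut-off from
method comparisons.  (Per-miRNA top-k extraction is also provided for
real-data use, where N is unknown.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .data import ExpressionMatrix
from .effects import effects_matrix
from .knowledge import KnowledgeSet
from .simulate import (
    DEFAULT_ROLE_FRACTIONS,
    NoiseSpec,
    SimulatedNetwork,
    generate_expression,
    generate_network,
    sample_knowledge,
)
from .structure import learn_structure

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "SweepConfig",
    "top_k_targets",
    "top_n_global",
    "f_score",
    "count_validated",
    "knowledge_sweep",
]

KNOWLEDGE_TYPES = ("tf_mirna", "mirna_mrna", "combined")


@dataclass(frozen=True)
class EvaluationResult:
    """Precision / recall / F of a predicted edge set against a truth set."""

    precision: float
    recall: float
    f_score: float
    n_predicted: int
    n_true: int
    n_hits: int


def top_k_targets(scores: pd.DataFrame, k: int) -> set[tuple[str, str]]:
    """For each miRNA (row), its k mRNAs of largest |score|.

    Ties break toward the lexicographically first mRNA identifier.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set[tuple[str, str]] = set()
    cols = np.array(scores.columns)
    order_cols = np.argsort(cols, kind="stable")
    for mirna, row in scores.abs().iterrows():
        vals = row.to_numpy()[order_cols]
        ranked = np.argsort(-vals, kind="stable")[:k]
        out.update((mirna, cols[order_cols[j]]) for j in ranked)
    return out


def top_n_global(scores: pd.DataFrame, n: int) -> set[tuple[str, str]]:
    """The n (miRNA, mRNA) pairs of largest |score| over the whole matrix.

    Ties break lexicographically on (miRNA, mRNA).
    """
    long = scores.abs().stack().reset_index()
    long.columns = ["mirna", "mrna", "score"]
    long = long.sort_values(
        by=["score", "mirna", "mrna"], ascending=[False, True, True]
    )
    return set(
        map(tuple, long.iloc[:n][["mirna", "mrna"]].itertuples(index=False))
    )


def f_score(
    predicted: set[tuple[str, str]], truth: set[tuple[str, str]]
) -> EvaluationResult:
    """Precision, recall, and their harmonic mean F = 2pr/(p+r)."""
    truth = set(truth)
    predicted = set(predicted)
    if not truth:
        raise ValueError("ground-truth set is empty; recall undefined")
    hits = len(predicted & truth)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(truth)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationResult(
        precision=precision,
        recall=recall,
        f_score=f,
        n_predicted=len(predicted),
        n_true=len(truth),
        n_hits=hits,
    )


def count_validated(
    predicted: set[tuple[str, str]], database: KnowledgeSet
) -> int:
    """How many predicted pairs appear in a validation database (the
    metric used on real datasets, where full ground truth is unknown)."""
    return len(set(predicted) & database.pairs)


# ---------------------------------------------------------------------------
# knowledge sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepConfig:
    """Parameters of the knowledge-sweep simulation experiment."""

    n_networks: int = 50
    n_nodes: int = 1000
    n_samples: int = 250
    edge_prob: float = 0.2
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0, 0.51, 0.05), 2))
    types: tuple[str, ...] = KNOWLEDGE_TYPES
    role_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_FRACTIONS))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    alpha: float = 0.01
    max_cond_size: int = 3
    seed: int = 1


def _sweep_knowledge(
    network: SimulatedNetwork, fraction: float, ktype: str, seed: int
) -> KnowledgeSet:
    types = (
        ("tf_mirna", "mirna_mrna") if ktype == "combined" else (ktype,)
    )
    return sample_knowledge(network, fraction, types=types, seed=seed)


def _cider_f(
    data: ExpressionMatrix,
    knowledge: KnowledgeSet | None,
    truth: set[tuple[str, str]],
    config: SweepConfig,
) -> EvaluationResult:
    graph = learn_structure(
        data,
        knowledge=knowledge,
        alpha=config.alpha,
        max_cond_size=config.max_cond_size,
    )
    effects = effects_matrix(data, graph)
    predicted = top_n_global(effects, len(truth))
    return f_score(predicted, truth)


def knowledge_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the sweep; one row per (fraction, knowledge type, replicate).

    For every replicate a fresh network and expression matrix are drawn;
    knowledge at each fraction of the requested type is sampled (nested
    across fractions), the structure re-learned, effects estimated, and
    the global top-N prediction scored against the true miRNA->mRNA edge
    set (N = number of true edges).  At fraction 0 no knowledge is used,
    so the result is computed once per replicate and shared by all types.
    """
    rows = []
    for rep in range(config.n_networks):
        network = generate_network(
            config.n_nodes,
            config.edge_prob,
            role_fractions=config.role_fractions,
            rng=spawn_rng(config.seed, "sweep-network", rep),
            noise=config.noise,
        )
        data = generate_expression(
            network,
            config.n_samples,
            rng=spawn_rng(config.seed, "sweep-data", rep),
        )
        truth = set(network.edges_of_type("mirna_mrna"))
        if not truth:
            logger.warning("replicate %d has no true miRNA->mRNA edge; skipped", rep)
            continue
        baseline_result = None
        for ktype in config.types:
            for fraction in config.fractions:
                if fraction == 0:
                    if baseline_result is None:
                        baseline_result = _cider_f(data, None, truth, config)
                    result = baseline_result
                else:
                    knowledge = _sweep_knowledge(
                        network, fraction, ktype, seed=config.seed + rep
                    )
                    result = _cider_f(data, knowledge, truth, config)
                rows.append(
                    {
                        "fraction": fraction,
                        "type": ktype,
                        "replicate": rep,
                        "precision": result.precision,
                        "recall": result.recall,
                        "f_score": result.f_score,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and Monte-Carlo SE of F per (type, fraction) cell."""
    grouped = results.groupby(["type", "fraction"])["f_score"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out
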