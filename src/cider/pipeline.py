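"""End-to-end run orchestration and reproducibility plumbing."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import read_expression
from .effects import effects_matrix, ranked_edges
from .evaluate import f_score, top_n_global
from .graph import write_graph_tsv
from .knowledge import (
    KnowledgeSet,
    read_interactions,
    read_pairs,
    restrict_to_universe,
)
from .structure import learn_structure

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs of one end-to-end run.

    ``knowledge`` maps interaction type (or ``"typed"`` for a file with a
    type column) to a TSV path.  ``truth`` optionally points to a typed
    interaction table used for evaluation only.
    """

    expression: str
    roles: str
    output_dir: str
    knowledge: dict[str, str] = field(default_factory=dict)
    truth: str | None = None
    alpha: float = 0.01
    max_cond_size: int = 3
    top_k: int = 100
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        paths = [self.expression, self.roles, *self.knowledge.values()]
        if self.truth:
            paths.append(self.truth)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _load_knowledge(config: RunConfig) -> KnowledgeSet | None:
    if not config.knowledge:
        return None
    merged = KnowledgeSet()
    for itype, path in sorted(config.knowledge.items()):
        ks = read_interactions(
            path, interaction_type=None if itype == "typed" else itype
        )
        merged = merged.union(ks)
    return merged


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Knowledge -> structure -> effects -> ranking (-> evaluation).

    Writes graph, effects matrix, ranked predictions, optional evaluation
    and a run manifest into ``config.output_dir``; identical configs give
    byte-identical numeric outputs.  Returns the artifact paths.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    data = _stage("load-expression", read_expression, config.expression, config.roles)
    knowledge = _stage("load-knowledge", _load_knowledge, config)
    if knowledge is not None:
        knowledge = restrict_to_universe(knowledge, data.genes)

    graph = _stage(
        "structure-learning",
        learn_structure,
        data,
        knowledge=knowledge,
        alpha=config.alpha,
        max_cond_size=config.max_cond_size,
    )
    effects = _stage("effect-estimation", effects_matrix, data, graph)
    ranking = ranked_edges(effects)

    artifacts = {
        "graph": str(outdir / "graph.tsv"),
        "effects": str(outdir / "effects.tsv"),
        "predictions": str(outdir / "predictions.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_graph_tsv(graph, artifacts["graph"])
    effects.to_csv(artifacts["effects"], sep="\t", index_label="mirna")
    ranking.to_csv(artifacts["predictions"], sep="\t", index=False)

    if config.truth:
        truth_pairs = _stage("load-truth", read_pairs, config.truth)
        predicted = top_n_global(effects, len(truth_pairs)) if truth_pairs else set()
        result = f_score(predicted, truth_pairs)
        artifacts["evaluation"] = str(outdir / "evaluation.tsv")
        pd.DataFrame([result.__dict__]).to_csv(
            artifacts["evaluation"], sep="\t", index=False
        )

    manifest = {
        "config": {
            k: v for k, v in config.__dict__.items()
        },
        "cider_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_samples": data.n_samples,
        "n_genes": len(data.genes),
        "n_knowledge_edges": 0 if knowledge is None else len(knowledge),
        "n_graph_edges": graph.n_edges,
    }
    with open(artifacts["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; artifacts in %s", outdir)
    return artifacts
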