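"""Estimator-style front end.

The learners follow the scikit-learn estimator contract: parameters are
set in ``__init__`` and echoed by ``get_params``; ``fit`` consumes a
samples x genes table and stores its results in trailing-underscore
attributes; fitted state is checked before any query.  ``X`` may be an
:class:`~cider.data.ExpressionMatrix` or a :class:`pandas.DataFrame`
accompanied by a ``roles`` mapping.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import baselines
from .data import ExpressionMatrix
from .effects import effects_matrix, ranked_edges
from .evaluate import top_k_targets, top_n_global
from .knowledge import KnowledgeSet
from .structure import learn_structure

__all__ = ["Cider", "PearsonScorer", "LassoScorer", "ZScoreScorer"]


def _as_expression_matrix(X, roles) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        if roles is None:
            raise ValueError(
                "roles mapping is required when X is a plain DataFrame"
            )
        return ExpressionMatrix(values=X, roles=dict(roles))
    raise TypeError(
        "X must be an ExpressionMatrix or a pandas DataFrame, "
        f"got {type(X).__name__}"
    )


class _ScoreMatrixMixin:
    """Shared queries over a fitted miRNA x mRNA score matrix."""

    def top_targets(self, k: int) -> set[tuple[str, str]]:
        """Per-miRNA top-k target pairs by score magnitude."""
        check_is_fitted(self, "scores_")
        return top_k_targets(self.scores_, k)

    def top_pairs(self, n: int) -> set[tuple[str, str]]:
        """Global top-n (miRNA, mRNA) pairs by score magnitude."""
        check_is_fitted(self, "scores_")
        return top_n_global(self.scores_, n)


class Cider(BaseEstimator, _ScoreMatrixMixin):
    """Causal miRNA target ranker.

    Fitting learns a knowledge-constrained causal structure from the
    expression matrix, then fills the causal-effect matrix with
    lower-bound intervention effects of every miRNA on every mRNA.

    Parameters
    ----------
    alpha : significance level of the conditional-independence tests.
    max_cond_size : largest conditioning-set size in the deletion phase.
    knowledge : validated interactions enforced as constant edges, or None.
    max_parent_sets : budget on the per-miRNA parent-set enumeration.

    Attributes (after ``fit``)
    --------------------------
    graph_ : the learned partially directed structure.
    effects_ : DataFrame of lower-bound causal effects (miRNA x mRNA).
    scores_ : alias of ``effects_`` for the shared ranking interface.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        max_cond_size: int = 3,
        knowledge: KnowledgeSet | None = None,
        max_parent_sets: int = 4096,
    ) -> None:
        self.alpha = alpha
        self.max_cond_size = max_cond_size
        self.knowledge = knowledge
        self.max_parent_sets = max_parent_sets

    def fit(self, X, y=None, roles=None) -> "Cider":
        data = _as_expression_matrix(X, roles)
        self.graph_ = learn_structure(
            data,
            knowledge=self.knowledge,
            alpha=self.alpha,
            max_cond_size=self.max_cond_size,
        )
        self.effects_ = effects_matrix(
            data, self.graph_, max_parent_sets=self.max_parent_sets
        )
        self.scores_ = self.effects_
        self.mirna_ids_ = list(self.effects_.index)
        self.mrna_ids_ = list(self.effects_.columns)
        self.n_features_in_ = len(data.genes)
        return self

    def ranked_edges(self) -> pd.DataFrame:
        """Long-format ranking of all pairs by |causal effect|."""
        check_is_fitted(self, "effects_")
        return ranked_edges(self.effects_)


class _BaselineScorer(BaseEstimator, _ScoreMatrixMixin):
    def fit(self, X, y=None, roles=None):
        data = _as_expression_matrix(X, roles)
        self.scores_ = self._compute(data)
        self.mirna_ids_ = list(self.scores_.index)
        self.mrna_ids_ = list(self.scores_.columns)
        self.n_features_in_ = len(data.genes)
        return self

    def _compute(self, data: ExpressionMatrix) -> pd.DataFrame:
        raise NotImplementedError


class PearsonScorer(_BaselineScorer):
    """Ranks targets by |Pearson correlation| with each miRNA."""

    def _compute(self, data):
        return baselines.pearson_scores(data)


class LassoScorer(_BaselineScorer):
    """Ranks targets by |L1-penalised coefficient|, penalty by seeded CV."""

    def __init__(self, cv: int = 5, random_state: int = 0, alphas=None) -> None:
        self.cv = cv
        self.random_state = random_state
        self.alphas = alphas

    def _compute(self, data):
        return baselines.lasso_scores(
            data, cv=self.cv, random_state=self.random_state, alphas=self.alphas
        )


class ZScoreScorer(_BaselineScorer):
    """Ranks targets by the pseudo-knock-out z-score heuristic."""

    def _compute(self, data):
        return baselines.zscore_scores(data)
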