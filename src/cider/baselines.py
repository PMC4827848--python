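"""Comparison methods: Pearson correlation, Lasso, and Z-score knock-out.

Each baseline turns an expression matrix into a miRNA x mRNA score
matrix with the same shape semantics as the causal-effect matrix, so the
same ranking / F-score machinery applies to all methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .data import ExpressionMatrix

__all__ = ["pearson_scores", "lasso_scores", "zscore_scores"]


def _score_frame(data: ExpressionMatrix):
    mirnas, mrnas = data.mirnas, data.mrnas
    if not mirnas or not mrnas:
        raise ValueError("need at least one miRNA and one mRNA")
    return mirnas, mrnas


def pearson_scores(data: ExpressionMatrix) -> pd.DataFrame:
    """|Pearson correlation| between every miRNA and every mRNA column."""
    mirnas, mrnas = _score_frame(data)
    x = data.matrix(mirnas)
    y = data.matrix(mrnas)
    corr = np.corrcoef(x, y, rowvar=False)[: len(mirnas), len(mirnas):]
    return pd.DataFrame(np.abs(corr), index=mirnas, columns=mrnas)


def lasso_scores(
    data: ExpressionMatrix,
    cv: int = 5,
    random_state: int = 0,
    alphas=None,
) -> pd.DataFrame:
    """|L1-penalised regression coefficient| of each miRNA per mRNA.

    Each mRNA column is regressed on *all* miRNA columns; the penalty is
    chosen by seeded k-fold cross-validation unless an explicit ``alphas``
    grid of length one pins it.
    """
    mirnas, mrnas = _score_frame(data)
    if len(mirnas) < 2:
        raise ValueError("lasso baseline needs at least 2 miRNAs")
    x = data.matrix(mirnas)
    folds = KFold(n_splits=cv, shuffle=True, random_state=random_state)
    scores = np.zeros((len(mirnas), len(mrnas)))
    for j, mrna in enumerate(mrnas):
        model = LassoCV(
            cv=folds, max_iter=5000,
            **({} if alphas is None else {"alphas": alphas}),
        )
        model.fit(x, data.column(mrna))
        scores[:, j] = np.abs(model.coef_)
    return pd.DataFrame(scores, index=mirnas, columns=mrnas)


def zscore_scores(data: ExpressionMatrix) -> pd.DataFrame:
    """Pseudo-knock-out z-scores.

    Observational stand-in for a knock-out design: for each miRNA the
    sample where it is lowest plays the knock-out sample; the score for an
    mRNA is the magnitude of that mRNA's z-score in that sample.
    """
    mirnas, mrnas = _score_frame(data)
    y = data.matrix(mrnas)
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [mrnas[k] for k in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance mRNA columns {bad[:5]}")
    scores = np.zeros((len(mirnas), len(mrnas)))
    for i, mi in enumerate(mirnas):
        knockout = int(np.argmin(data.column(mi)))  # ties -> first sample
        scores[i] = np.abs(y[knockout] - mean) / sd
    return pd.DataFrame(scores, index=mirnas, columns=mrnas)
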