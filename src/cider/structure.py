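"""Knowledge-constrained constraint-based causal structure learning.

The learner is PC-style: start from the complete undirected graph over
all genes, delete edges that a Fisher-z partial-correlation test declares
conditionally independent (conditioning sets drawn from current
neighbourhoods, size growing from 0 to ``max_cond_size``), then orient
v-structures from the recorded separating sets and complete the
orientation with the standard propagation rules.

Two departures from textbook PC implement the knowledge integration:

* every validated interaction becomes a *constant edge* — inserted
  directed regulator -> target, never tested for removal, never
  re-oriented, but fully eligible as a member of conditioning sets (which
  is exactly how a known edge can expose a spurious one);
* the deletion phase is the order-independent ("stable") variant, so the
  result does not depend on gene ordering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionMatrix
from .graph import (
    Dag,
    GraphInconsistencyError,
    PartiallyDirectedGraph,
    is_acyclic,
    orientation_closure,
)
from .knowledge import KnowledgeSet, restrict_to_universe

logger = logging.getLogger(__name__)

__all__ = [
    "CiTestResult",
    "CollinearityError",
    "fisher_z_ci_test",
    "learn_skeleton",
    "orient_vstructures",
    "learn_structure",
]


class CollinearityError(ValueError):
    """A correlation submatrix is singular (collinear gene set)."""


@dataclass(frozen=True)
class CiTestResult:
    """Outcome of one conditional-independence test."""

    pair: tuple[str, str]
    conditioning_set: frozenset
    statistic: float
    p_value: float
    independent: bool


# ---------------------------------------------------------------------------
# Fisher-z partial-correlation testing
# ---------------------------------------------------------------------------

_R_CLIP = 1.0 - 1e-12


def _fisher_z_stat(r: np.ndarray, n: int, cond_size: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    stat = np.sqrt(n - cond_size - 3.0) * np.abs(z)
    p = 2.0 * stats.norm.sf(stat)
    return stat, p


class _FisherZTester:
    """Partial-correlation tests against a precomputed correlation matrix."""

    def __init__(self, corr: np.ndarray, n_samples: int, genes: list[str]):
        self.corr = corr
        self.n = n_samples
        self.genes = genes

    def partial_corr(self, i: int, j: int, cond: tuple[int, ...]) -> float:
        c = self.corr
        if len(cond) == 0:
            return float(c[i, j])
        if len(cond) == 1:
            k = cond[0]
            den = (1.0 - c[i, k] ** 2) * (1.0 - c[j, k] ** 2)
            if den <= 0:
                raise CollinearityError(
                    f"singular correlation among "
                    f"{[self.genes[x] for x in (i, j, k)]}"
                )
            return float((c[i, j] - c[i, k] * c[j, k]) / np.sqrt(den))
        idx = np.array((i, j) + cond)
        sub = c[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                f"singular correlation among "
                f"{[self.genes[x] for x in idx]}"
            ) from exc
        den = prec[0, 0] * prec[1, 1]
        if den <= 0:
            raise CollinearityError(
                f"singular correlation among {[self.genes[x] for x in idx]}"
            )
        return float(-prec[0, 1] / np.sqrt(den))

    def partial_corr_batch(
        self, i: int, j: int, subsets: list[tuple[int, ...]]
    ) -> np.ndarray:
        """Partial correlations of (i, j) given each subset (equal sizes)."""
        size = len(subsets[0])
        c = self.corr
        if size == 1:
            ks = np.array([s[0] for s in subsets])
            den = (1.0 - c[i, ks] ** 2) * (1.0 - c[j, ks] ** 2)
            den = np.where(den <= 0, np.nan, den)
            return (c[i, j] - c[i, ks] * c[j, ks]) / np.sqrt(den)
        idx = np.array([(i, j) + s for s in subsets])  # (k, m)
        subs = c[idx[:, :, None], idx[:, None, :]]  # (k, m, m)
        try:
            prec = np.linalg.inv(subs)
        except np.linalg.LinAlgError:
            # fall back to per-subset computation so the offending set is named
            return np.array(
                [self.partial_corr(i, j, s) for s in subsets]
            )
        den = prec[:, 0, 0] * prec[:, 1, 1]
        den = np.where(den <= 0, np.nan, den)
        return -prec[:, 0, 1] / np.sqrt(den)

    def test(self, i: int, j: int, cond: tuple[int, ...], alpha: float):
        r = self.partial_corr(i, j, cond)
        stat, p = _fisher_z_stat(np.array(r), self.n, len(cond))
        return float(stat), float(p), bool(p > alpha)


def fisher_z_ci_test(
    data: ExpressionMatrix,
    i: str,
    j: str,
    conditioning: set[str] | frozenset | tuple = (),
    alpha: float = 0.01,
) -> CiTestResult:
    """Test whether genes ``i`` and ``j`` are conditionally independent
    given ``conditioning``, under the joint-Gaussian assumption.

    The partial correlation r of i and j given S is Fisher-z transformed,
    z = arctanh(r); the statistic sqrt(n - |S| - 3) * |z| is referred to
    the standard normal (two-sided).  ``independent`` is ``p > alpha``.
    """
    cond = sorted(set(conditioning))
    if i == j:
        raise ValueError("i and j must differ")
    if i in cond or j in cond:
        raise ValueError("i and j must not be in the conditioning set")
    if data.n_samples <= len(cond) + 3:
        raise ValueError(
            f"need more than |S| + 3 = {len(cond) + 3} samples, "
            f"got {data.n_samples}"
        )
    genes = [i, j] + cond
    x = data.matrix(genes)
    corr = np.corrcoef(x, rowvar=False)
    tester = _FisherZTester(np.atleast_2d(corr), data.n_samples, genes)
    stat, p, indep = tester.test(0, 1, tuple(range(2, 2 + len(cond))), alpha)
    return CiTestResult(
        pair=(i, j),
        conditioning_set=frozenset(cond),
        statistic=stat,
        p_value=p,
        independent=indep,
    )


# ---------------------------------------------------------------------------
# skeleton learning (stable deletion phase)
# ---------------------------------------------------------------------------


def _constant_pairs(constant_edges: KnowledgeSet | None):
    """Directed constant pairs; raises on two-way (contradictory) knowledge."""
    if constant_edges is None:
        return {}
    directed: dict[frozenset, tuple[str, str]] = {}
    for rec in constant_edges:
        key = frozenset(rec.pair)
        if key in directed and directed[key] != rec.pair:
            raise GraphInconsistencyError(
                f"knowledge asserts both directions between {rec.regulator!r} "
                f"and {rec.target!r}"
            )
        directed[key] = rec.pair
    return directed


def learn_skeleton(
    data: ExpressionMatrix,
    constant_edges: KnowledgeSet | None = None,
    alpha: float = 0.01,
    max_cond_size: int = 3,
) -> PartiallyDirectedGraph:
    """Order-independent PC-style edge deletion with constant edges.

    Starts from the complete graph over all genes; constant edges are
    inserted directed regulator -> target and are never tested for
    removal, but do appear in conditioning sets.  The separating set of
    every removed edge is recorded in ``graph.sepsets``.
    """
    genes = sorted(data.genes)
    index = {g: k for k, g in enumerate(genes)}
    x = data.matrix(genes)
    n = x.shape[0]
    corr = np.corrcoef(x, rowvar=False)
    tester = _FisherZTester(corr, n, genes)

    if constant_edges is not None:
        constant_edges = restrict_to_universe(constant_edges, genes)
    constants = _constant_pairs(constant_edges)
    const_idx = {
        frozenset((index[u], index[v])) for u, v in (p for p in constants.values())
    }

    m = len(genes)
    adj: list[set[int]] = [set(range(m)) - {k} for k in range(m)]
    sepsets: dict[frozenset, frozenset] = {}

    # level 0: fully vectorised marginal test
    _, pvals = _fisher_z_stat(corr, n, 0)
    for i in range(m):
        for j in range(i + 1, m):
            if frozenset((i, j)) in const_idx:
                continue
            if pvals[i, j] > alpha:
                adj[i].discard(j)
                adj[j].discard(i)
                sepsets[frozenset((i, j))] = frozenset()

    # levels >= 1: conditioning sets from neighbourhood snapshots
    for level in range(1, max_cond_size + 1):
        snapshot = [frozenset(a) for a in adj]
        if not any(len(a) - 1 >= level for a in snapshot):
            break
        for i in range(m):
            for j in sorted(adj[i]):
                if j < i or frozenset((i, j)) in const_idx:
                    continue
                if _deletes_edge(
                    tester, i, j, snapshot, level, alpha, sepsets
                ):
                    adj[i].discard(j)
                    adj[j].discard(i)

    graph = PartiallyDirectedGraph(genes)
    done = set()
    for u, v in constants.values():
        graph.add_directed(u, v, constant=True)
        done.add(frozenset((index[u], index[v])))
    for i in range(m):
        for j in adj[i]:
            key = frozenset((i, j))
            if i < j and key not in done:
                graph.add_undirected(genes[i], genes[j])
    for key, sep in sepsets.items():
        i, j = sorted(key)
        graph.sepsets[frozenset((genes[i], genes[j]))] = frozenset(
            genes[k] for k in sep
        )
    return graph


def _deletes_edge(tester, i, j, snapshot, level, alpha, sepsets) -> bool:
    """Try all size-``level`` conditioning sets from either neighbourhood."""
    tried: set[tuple[int, ...]] = set()
    for base, other in ((i, j), (j, i)):
        cands = sorted(snapshot[base] - {other})
        if len(cands) < level:
            continue
        subsets = [
            s for s in itertools.combinations(cands, level) if s not in tried
        ]
        if not subsets:
            continue
        tried.update(subsets)
        r = tester.partial_corr_batch(i, j, subsets)
        r = np.asarray(r, dtype=float)
        _, p = _fisher_z_stat(np.nan_to_num(r, nan=1.0), tester.n, level)
        hits = np.nonzero(p > alpha)[0]
        if hits.size:
            sepsets[frozenset((i, j))] = frozenset(subsets[int(hits[0])])
            return True
    return False


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def orient_vstructures(
    graph: PartiallyDirectedGraph, dependence_test=None
) -> PartiallyDirectedGraph:
    """Orient unshielded triples i - j - k (i, k non-adjacent) as the
    collider i -> j <- k when j did not separate i and k.

    The base criterion is the separating set recorded during deletion:
    j not in sepset(i, k).  When ``dependence_test`` is given — a callable
    ``(i, k, cond)`` returning a truthy value when i and k are *dependent*
    given ``cond`` and False otherwise — a triple must additionally test
    dependent given {j} before being oriented.  The direct test is the
    definitional form of a v-structure ("i and k not independent
    conditioned on j") and guards against false colliders arising from
    empty separating sets of weakly correlated co-targets;
    :func:`learn_structure` always supplies it.

    Constant-edge directions are never overridden: a v-structure demanding
    the reversal of a constant edge is logged and loses.  Orientations that
    would close a directed cycle, or reverse an earlier v-structure
    orientation, are likewise skipped (first orientation wins, in
    deterministic lexicographic order).
    """
    g = graph.copy()
    for j in g.nodes:
        for i, k in itertools.combinations(sorted(g.adjacency(j)), 2):
            if g.is_adjacent(i, k):
                continue
            sep = g.sepsets.get(frozenset((i, k)))
            if sep is None or j in sep:
                continue
            if dependence_test is not None and not dependence_test(i, k, (j,)):
                continue
            for tail in (i, k):
                _orient_collider_edge(g, tail, j)
    return g


def _orient_collider_edge(g: PartiallyDirectedGraph, tail: str, head: str) -> None:
    if g.is_directed(tail, head):
        return
    if g.is_directed(head, tail):
        if g.is_constant(head, tail):
            logger.warning(
                "v-structure wants %s->%s but constant edge %s->%s wins",
                tail, head, head, tail,
            )
        else:
            logger.debug(
                "v-structure wants %s->%s but prior orientation %s->%s wins",
                tail, head, head, tail,
            )
        return
    if g.has_directed_path(head, tail):
        logger.debug(
            "v-structure orientation %s->%s skipped: would close a cycle",
            tail, head,
        )
        return
    g.orient(tail, head)


def learn_structure(
    data: ExpressionMatrix,
    knowledge: KnowledgeSet | None = None,
    alpha: float = 0.01,
    max_cond_size: int = 3,
) -> PartiallyDirectedGraph:
    """Full structure construction: skeleton with constant edges, then
    v-structure orientation, then orientation closure.

    Every knowledge record whose genes survive restriction to the data's
    gene universe is guaranteed to appear in the output as a directed
    constant edge regulator -> target.
    """
    if knowledge is not None:
        knowledge = restrict_to_universe(knowledge, data.genes)
        _check_knowledge_acyclic(knowledge)
    skeleton = learn_skeleton(
        data, constant_edges=knowledge, alpha=alpha, max_cond_size=max_cond_size
    )
    genes = sorted(data.genes)
    index = {g: k for k, g in enumerate(genes)}
    tester = _FisherZTester(
        np.corrcoef(data.matrix(genes), rowvar=False), data.n_samples, genes
    )

    def dependent(i: str, k: str, cond: tuple[str, ...]):
        """p-value when i, k are dependent given cond, else False."""
        _, p, indep = tester.test(
            index[i], index[k], tuple(index[c] for c in cond), alpha
        )
        return False if indep else p

    oriented = orient_vstructures(skeleton, dependence_test=dependent)
    result = orientation_closure(oriented, on_conflict="keep")
    if not is_acyclic(result):
        raise GraphInconsistencyError(
            "learned structure contains a directed cycle"
        )
    return result


def _check_knowledge_acyclic(knowledge: KnowledgeSet) -> None:
    try:
        Dag(knowledge.genes(), [r.pair for r in knowledge])
    except GraphInconsistencyError as exc:
        raise GraphInconsistencyError(
            "regulatory knowledge edges form a directed cycle"
        ) from exc
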