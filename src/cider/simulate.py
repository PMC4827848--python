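"""Linear structural-equation simulation of miRNA/mRNA regulatory networks.

A ground-truth DAG is drawn by fixing a random topological order and
adding each forward pair independently with probability ``edge_prob``,
keeping only role-admissible regulations (TF-coding mRNA may regulate
miRNAs and mRNAs; a miRNA may repress mRNAs, TF-coding ones included).
Each edge carries a regulatory weight w ~ U([-1, -0.1] ∪ [0.1, 1]);
expression then follows

    x_i = b_i + sum_{j in pa(i)} w_{j->i} * x_j + eps_i

with intercepts b_i ~ N(0, 1) and non-Gaussian noise eps (uniform by
default; Laplace and Student-t available).  Graded knowledge subsets for
the sweep experiment are drawn nested: the knowledge at a smaller
fraction is always a subset of the knowledge at a larger one under the
same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import spawn_rng
from .data import ExpressionMatrix
from .graph import Dag
from .knowledge import KnowledgeRecord, KnowledgeSet

import pandas as pd

__all__ = [
    "NoiseSpec",
    "SimulatedNetwork",
    "DEFAULT_ROLE_FRACTIONS",
    "sample_weight",
    "generate_network",
    "generate_expression",
    "sample_knowledge",
]

DEFAULT_ROLE_FRACTIONS = {"mirna": 0.10, "tf_mrna": 0.10, "mrna": 0.80}

#: regulator role -> roles it may regulate
_ADMISSIBLE = {
    "tf_mrna": {"mirna", "mrna", "tf_mrna"},
    "mirna": {"mrna", "tf_mrna"},
    "mrna": set(),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Error-term distribution for the structural equations."""

    kind: str = "uniform"
    params: tuple = ()

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            low, high = self.params or (-1.0, 1.0)
            return rng.uniform(low, high, size)
        if self.kind == "laplace":
            (scale,) = self.params or (1.0,)
            return rng.laplace(0.0, scale, size)
        if self.kind == "student_t":
            (df,) = self.params or (5.0,)
            return rng.standard_t(df, size)
        raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class SimulatedNetwork:
    """Ground-truth DAG with roles, edge weights, intercepts and noise."""

    dag: Dag
    roles: dict[str, str]
    weights: dict[tuple[str, str], float]
    intercepts: dict[str, float]
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        for (u, v), w in self.weights.items():
            if not 0.1 <= abs(w) <= 1.0:
                raise ValueError(
                    f"weight {w} on edge ({u}, {v}) outside [0.1, 1] magnitude"
                )

    def edges_of_type(self, interaction_type: str) -> list[tuple[str, str]]:
        """True edges matching a knowledge interaction class."""
        if interaction_type == "tf_mirna":
            keep = lambda u, v: (
                self.roles[u] == "tf_mrna" and self.roles[v] == "mirna"
            )
        elif interaction_type == "mirna_mrna":
            keep = lambda u, v: (
                self.roles[u] == "mirna" and self.roles[v] != "mirna"
            )
        else:
            raise ValueError(f"unknown interaction type {interaction_type!r}")
        return [(u, v) for u, v in self.dag.edges if keep(u, v)]


def sample_weight(rng: np.random.Generator, size: int | None = None):
    """Regulatory weight(s) uniform over [-1, -0.1] ∪ [0.1, 1]."""
    magnitude = rng.uniform(0.1, 1.0, size)
    sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
    out = magnitude * sign
    return float(out) if size is None else out


def _role_counts(n_nodes: int, fractions: dict[str, float]) -> dict[str, int]:
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("role fractions must sum to 1")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("role fractions must be non-negative")
    counts = {r: int(np.floor(f * n_nodes)) for r, f in fractions.items()}
    # largest-remainder allocation of the leftover nodes, deterministic order
    leftover = n_nodes - sum(counts.values())
    remainders = sorted(
        fractions,
        key=lambda r: (-(fractions[r] * n_nodes - counts[r]), r),
    )
    for r in remainders[:leftover]:
        counts[r] += 1
    return counts


def generate_network(
    n_nodes: int,
    edge_prob: float,
    role_fractions: dict[str, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: NoiseSpec | None = None,
    restrict_roles: bool = True,
) -> SimulatedNetwork:
    """Random ground-truth regulatory network.

    A topological order is drawn uniformly; every forward pair is added
    with probability ``edge_prob`` and kept if role-admissible (unless
    ``restrict_roles`` is False, in which case all forward edges are
    eligible — useful for generic structure-recovery studies).
    Deterministic given ``seed``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    if rng is None:
        rng = spawn_rng(0 if seed is None else seed, "network")
    fractions = dict(role_fractions or DEFAULT_ROLE_FRACTIONS)
    counts = _role_counts(n_nodes, fractions)

    names: list[str] = []
    roles: dict[str, str] = {}
    prefixes = {"mirna": "mir", "tf_mrna": "tf", "mrna": "g"}
    for role in sorted(counts):
        for k in range(counts[role]):
            name = f"{prefixes[role]}{k:04d}"
            names.append(name)
            roles[name] = role
    order = [names[k] for k in rng.permutation(n_nodes)]

    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            u, v = order[a], order[b]
            draw = rng.random()
            if draw >= edge_prob:
                continue
            if restrict_roles and roles[v] not in _ADMISSIBLE[roles[u]]:
                continue
            edges.append((u, v))
    for e in sorted(edges):
        weights[e] = sample_weight(rng)
    intercepts = {n: float(rng.normal(0.0, 1.0)) for n in sorted(names)}
    return SimulatedNetwork(
        dag=Dag(names, edges),
        roles=roles,
        weights=weights,
        intercepts=intercepts,
        noise=noise or NoiseSpec(),
    )


def generate_expression(
    network: SimulatedNetwork,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Draw expression profiles from the structural equations."""
    if rng is None:
        rng = spawn_rng(0 if seed is None else seed, "expression")
    order = network.dag.topological_order()
    cols: dict[str, np.ndarray] = {}
    for node in order:
        x = np.full(n_samples, network.intercepts[node])
        for p in sorted(network.dag.parents(node)):
            x = x + network.weights[(p, node)] * cols[p]
        x = x + network.noise.draw(rng, n_samples)
        cols[node] = x
    genes = sorted(network.dag.nodes)
    values = pd.DataFrame(
        {g: cols[g] for g in genes},
        index=[f"s{k:04d}" for k in range(n_samples)],
    )
    return ExpressionMatrix(values=values, roles=dict(network.roles))


def sample_knowledge(
    network: SimulatedNetwork,
    fraction: float,
    types: tuple[str, ...] = ("tf_mirna", "mirna_mrna"),
    seed: int = 0,
) -> KnowledgeSet:
    """Sample a fraction of the true edges of each requested type as
    knowledge.

    Uses a per-type permutation keyed only by ``seed`` and the type, so
    subsets are *nested* across fractions: the knowledge at fraction f1 <
    f2 (same seed) is a subset of the knowledge at f2.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = KnowledgeSet()
    for itype in types:
        edges = sorted(network.edges_of_type(itype))
        if not edges:
            continue
        rng = spawn_rng(seed, "knowledge", itype)
        perm = rng.permutation(len(edges))
        n_keep = int(np.floor(fraction * len(edges)))
        for k in perm[:n_keep]:
            u, v = edges[int(k)]
            out.add(KnowledgeRecord(u, v, itype, source_tag="simulated"))
    return out
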