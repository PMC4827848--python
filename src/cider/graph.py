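"""Partially directed graphs for constraint-based causal discovery.

A :class:`PartiallyDirectedGraph` holds the mixed graph produced by
skeleton learning and edge orientation: undirected edges (direction not
yet identified), directed edges (compelled by v-structures, propagation
rules, or regulatory knowledge), *constant* edges (fixed by experimentally
validated knowledge, never removed or re-oriented), and the separating
sets recorded while deleting edges.

The module also provides the standard pattern-completion machinery:
:func:`orientation_closure` (Meek's rules), :func:`enumerate_consistent_dags`
(exhaustive extension of a partially directed graph to DAGs, used as the
exactness oracle for causal-effect bounds), and :func:`dag_to_pattern`
(the CPDAG of a DAG, for evaluating learned structures).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PartiallyDirectedGraph",
    "Dag",
    "GraphInconsistencyError",
    "EnumerationBudgetError",
    "is_acyclic",
    "orientation_closure",
    "enumerate_consistent_dags",
    "dag_to_pattern",
    "structural_hamming_distance",
    "read_graph_tsv",
    "write_graph_tsv",
]


class GraphInconsistencyError(ValueError):
    """Orientation rules (or knowledge) force both directions on one edge."""


class EnumerationBudgetError(RuntimeError):
    """Too many undirected edges to enumerate consistent DAG extensions."""


class PartiallyDirectedGraph:
    """Mixed graph with undirected / directed edges and constant-edge flags.

    Nodes are string gene identifiers.  Iteration order is lexicographic
    everywhere it matters, so identical inputs yield identical outputs
    regardless of insertion order.
    """

    def __init__(self, nodes: Iterable[str] = ()) -> None:
        self._adj: dict[str, set[str]] = {}
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        # constant edges stored as directed (regulator, target) pairs
        self._constant: set[tuple[str, str]] = set()
        #: unordered pair (frozenset) -> separating set (frozenset of nodes)
        self.sepsets: dict[frozenset, frozenset] = {}
        for n in nodes:
            self.add_node(n)

    # -- nodes ------------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def add_node(self, node: str) -> None:
        if node not in self._adj:
            self._adj[node] = set()
            self._parents[node] = set()
            self._children[node] = set()

    # -- edge predicates ---------------------------------------------------

    def is_adjacent(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def is_directed(self, u: str, v: str) -> bool:
        """True iff the edge u -> v is present and directed."""
        return v in self._children.get(u, ())

    def is_undirected(self, u: str, v: str) -> bool:
        return self.is_adjacent(u, v) and not (
            self.is_directed(u, v) or self.is_directed(v, u)
        )

    def is_constant(self, u: str, v: str) -> bool:
        return (u, v) in self._constant or (v, u) in self._constant

    # -- neighbourhoods ----------------------------------------------------

    def adjacency(self, node: str) -> set[str]:
        return set(self._adj[node])

    def parents(self, node: str) -> set[str]:
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        return set(self._children[node])

    def undirected_neighbors(self, node: str) -> set[str]:
        return self._adj[node] - self._parents[node] - self._children[node]

    # -- edge mutation -----------------------------------------------------

    def add_undirected(self, u: str, v: str) -> None:
        self._check_new_edge(u, v)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def add_directed(self, u: str, v: str, constant: bool = False) -> None:
        self._check_new_edge(u, v)
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._children[u].add(v)
        self._parents[v].add(u)
        if constant:
            self._constant.add((u, v))

    def _check_new_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        self.add_node(u)
        self.add_node(v)
        if self.is_adjacent(u, v):
            raise ValueError(f"edge between {u!r} and {v!r} already present")

    def orient(self, u: str, v: str) -> None:
        """Turn the undirected edge u - v into u -> v."""
        if not self.is_undirected(u, v):
            raise ValueError(f"no undirected edge between {u!r} and {v!r}")
        self._children[u].add(v)
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.is_adjacent(u, v):
            raise ValueError(f"no edge between {u!r} and {v!r}")
        if self.is_constant(u, v):
            raise ValueError(f"constant edge {u!r}, {v!r} cannot be removed")
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._children[u].discard(v)
        self._children[v].discard(u)
        self._parents[u].discard(v)
        self._parents[v].discard(u)

    # -- edge views ----------------------------------------------------------

    @property
    def directed_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u in self._children for v in self._children[u]
        )

    @property
    def undirected_edges(self) -> list[tuple[str, str]]:
        out = []
        for u in self._adj:
            for v in self._adj[u]:
                if u < v and self.is_undirected(u, v):
                    out.append((u, v))
        return sorted(out)

    @property
    def constant_edges(self) -> list[tuple[str, str]]:
        return sorted(self._constant)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    # -- structure queries ---------------------------------------------------

    def has_directed_path(self, u: str, v: str) -> bool:
        """True iff a (non-empty) path of directed edges leads from u to v."""
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for c in self._children[x]:
                if c == v:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Colliders a -> c <- b with a, b non-adjacent, as (a, c, b), a < b."""
        out = set()
        for c in self._parents:
            ps = sorted(self._parents[c])
            for a, b in itertools.combinations(ps, 2):
                if not self.is_adjacent(a, b):
                    out.add((a, c, b))
        return out

    def copy(self) -> "PartiallyDirectedGraph":
        g = PartiallyDirectedGraph(self._adj)
        for n in self._adj:
            g._adj[n] = set(self._adj[n])
            g._parents[n] = set(self._parents[n])
            g._children[n] = set(self._children[n])
        g._constant = set(self._constant)
        g.sepsets = dict(self.sepsets)
        return g

    def to_dag(self) -> "Dag":
        if self.undirected_edges:
            raise ValueError("graph still has undirected edges")
        return Dag(self.nodes, self.directed_edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartiallyDirectedGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed_edges == other.directed_edges
            and self.undirected_edges == other.undirected_edges
            and self._constant == other._constant
        )

    def __repr__(self) -> str:
        return (
            f"PartiallyDirectedGraph({len(self._adj)} nodes, "
            f"{len(self.directed_edges)} directed, "
            f"{len(self.undirected_edges)} undirected edges)"
        )


class Dag:
    """Directed acyclic graph over gene identifiers."""

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        validate: bool = True,
    ) -> None:
        self._nodes = sorted(set(nodes))
        self._edges = set()
        self._parents: dict[str, set[str]] = {n: set() for n in self._nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self._nodes}
        for u, v in edges:
            if u not in self._parents or v not in self._parents:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            self._edges.add((u, v))
            self._parents[v].add(u)
            self._children[u].add(v)
        if validate and not is_acyclic(self):
            raise GraphInconsistencyError("directed edges form a cycle")

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._edges)

    def parents(self, node: str) -> set[str]:
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        return set(self._children[node])

    def is_adjacent(self, u: str, v: str) -> bool:
        return (u, v) in self._edges or (v, u) in self._edges

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        # lexicographic tie-break for determinism
        return list(nx.lexicographical_topological_sort(g))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((tuple(self._nodes), tuple(sorted(self._edges))))

    def __repr__(self) -> str:
        return f"Dag({len(self._nodes)} nodes, {len(self._edges)} edges)"


def is_acyclic(graph: PartiallyDirectedGraph | Dag) -> bool:
    """True iff the directed edges of ``graph`` form no cycle.

    Undirected edges are ignored.
    """
    if isinstance(graph, Dag):
        edges = graph.edges
        nodes = graph.nodes
    else:
        edges = graph.directed_edges
        nodes = graph.nodes
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(g)


# ---------------------------------------------------------------------------
# orientation propagation (Meek's rules)
# ---------------------------------------------------------------------------


def _try_orient(
    g: PartiallyDirectedGraph, u: str, v: str, rule: str, on_conflict: str
) -> bool:
    """Apply a forced orientation u -> v; returns True if the graph changed."""
    if g.is_directed(u, v):
        return False
    conflict = None
    if g.is_directed(v, u):
        conflict = f"rule {rule} forces {u}->{v} but {v}->{u} is already directed"
    elif g.has_directed_path(v, u):
        conflict = f"rule {rule} forces {u}->{v} but that closes a directed cycle"
    if conflict is not None:
        if g.is_constant(u, v) or on_conflict == "raise":
            raise GraphInconsistencyError(conflict)
        logger.debug("orientation conflict ignored: %s", conflict)
        return False
    g.orient(u, v)
    return True


def _closure_pass(g: PartiallyDirectedGraph, on_conflict: str) -> bool:
    changed = False
    for a, b in g.undirected_edges:
        if not g.is_undirected(a, b):
            continue  # oriented earlier in this pass
        r_fwd = _rule_applies(g, a, b)
        r_rev = _rule_applies(g, b, a)
        if r_fwd and r_rev:
            msg = (
                f"rules {r_fwd}/{r_rev} force both directions on edge "
                f"{a!r} - {b!r}"
            )
            if on_conflict == "raise" or g.is_constant(a, b):
                raise GraphInconsistencyError(msg)
            logger.debug("orientation conflict, keeping %s->%s: %s", a, b, msg)
            changed |= _try_orient(g, a, b, r_fwd, on_conflict)
        elif r_fwd:
            changed |= _try_orient(g, a, b, r_fwd, on_conflict)
        elif r_rev:
            changed |= _try_orient(g, b, a, r_rev, on_conflict)
    return changed


def _rule_applies(g: PartiallyDirectedGraph, x: str, y: str) -> str | None:
    """Name of the first Meek rule forcing x -> y, or None."""
    adj_y = g.adjacency(y)
    # R1: c -> x, x - y, c and y non-adjacent  =>  x -> y
    for c in sorted(g.parents(x)):
        if c not in adj_y and c != y:
            return "R1"
    # R2: x -> c -> y with x - y  =>  x -> y
    for c in sorted(g.children(x)):
        if g.is_directed(c, y):
            return "R2"
    # R3: x - c, x - d, c -> y, d -> y, c and d non-adjacent  =>  x -> y
    und_x = sorted(g.undirected_neighbors(x))
    into_y = [c for c in und_x if g.is_directed(c, y)]
    for c, d in itertools.combinations(into_y, 2):
        if not g.is_adjacent(c, d):
            return "R3"
    # R4: c -> d, d -> y, x adjacent to both c and d, c and y non-adjacent
    adj_x = g.adjacency(x)
    for d in sorted(adj_x):
        if not g.is_directed(d, y):
            continue
        for c in sorted(g.parents(d)):
            if c in adj_x and c not in adj_y and c != y:
                return "R4"
    return None


def orientation_closure(
    graph: PartiallyDirectedGraph, on_conflict: str = "raise"
) -> PartiallyDirectedGraph:
    """Direct every undirected edge whose orientation is forced.

    Repeatedly applies the four standard pattern-completion rules (no new
    v-structure, no directed cycle) until a fixpoint; edges whose direction
    is not forced stay undirected.  Idempotent.

    Parameters
    ----------
    on_conflict : {"raise", "keep"}
        What to do when propagation forces both directions on one edge
        (contradictory knowledge or conditional-independence results):
        ``"raise"`` signals :class:`GraphInconsistencyError`, ``"keep"``
        keeps the existing direction and logs a warning.  A conflict on a
        constant edge always raises.
    """
    if on_conflict not in ("raise", "keep"):
        raise ValueError("on_conflict must be 'raise' or 'keep'")
    g = graph.copy()
    while _closure_pass(g, on_conflict):
        pass
    return g


# ---------------------------------------------------------------------------
# exhaustive DAG extension
# ---------------------------------------------------------------------------


def enumerate_consistent_dags(
    graph: PartiallyDirectedGraph, max_undirected: int = 12
) -> list[Dag]:
    """Every orientation of the undirected edges that yields a DAG with no
    v-structure absent from ``graph``.

    Directed (and constant) edges are kept verbatim.  Exhaustive over the
    2^k orientation assignments, so guarded by ``max_undirected``; intended
    as the exactness oracle for small graphs / components.
    """
    und = graph.undirected_edges
    if len(und) > max_undirected:
        raise EnumerationBudgetError(
            f"{len(und)} undirected edges exceed the enumeration budget "
            f"of {max_undirected}"
        )
    nodes = graph.nodes
    base = graph.directed_edges
    known_v = graph.v_structures()
    adjacent = graph.is_adjacent
    out: list[Dag] = []
    for bits in itertools.product((0, 1), repeat=len(und)):
        edges = list(base)
        for (a, b), bit in zip(und, bits):
            edges.append((a, b) if bit == 0 else (b, a))
        try:
            dag = Dag(nodes, edges)
        except GraphInconsistencyError:
            continue
        if _new_v_structure(dag, known_v, adjacent):
            continue
        out.append(dag)
    return out


def _new_v_structure(dag: Dag, known_v, adjacent) -> bool:
    for c in dag.nodes:
        ps = sorted(dag.parents(c))
        for a, b in itertools.combinations(ps, 2):
            if not adjacent(a, b) and (a, c, b) not in known_v:
                return True
    return False


def dag_to_pattern(dag: Dag) -> PartiallyDirectedGraph:
    """The pattern (CPDAG) of a DAG: v-structure edges directed, the rest
    undirected, then orientation closure."""
    g = PartiallyDirectedGraph(dag.nodes)
    compelled: set[tuple[str, str]] = set()
    for c in dag.nodes:
        ps = sorted(dag.parents(c))
        for a, b in itertools.combinations(ps, 2):
            if not dag.is_adjacent(a, b):
                compelled.add((a, c))
                compelled.add((b, c))
    for u, v in dag.edges:
        if (u, v) in compelled:
            g.add_directed(u, v)
        else:
            g.add_undirected(u, v)
    return orientation_closure(g)


def structural_hamming_distance(
    a: PartiallyDirectedGraph, b: PartiallyDirectedGraph
) -> int:
    """Number of node pairs whose edge mark differs between the two graphs.

    Marks compared per unordered pair: absent, undirected, or directed with
    a given direction; each mismatch counts 1.
    """
    if a.nodes != b.nodes:
        raise ValueError("graphs must share the same node set")

    def mark(g: PartiallyDirectedGraph, u: str, v: str):
        if not g.is_adjacent(u, v):
            return "none"
        if g.is_directed(u, v):
            return ">"
        if g.is_directed(v, u):
            return "<"
        return "-"

    nodes = a.nodes
    return sum(
        mark(a, u, v) != mark(b, u, v)
        for u, v in itertools.combinations(nodes, 2)
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_HEADER = "source\ttarget\tmark\tconstant"


def write_graph_tsv(graph: PartiallyDirectedGraph, path) -> None:
    """Tab-separated edge list: source, target, mark, constant flag."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for u, v in graph.directed_edges:
            fh.write(f"{u}\t{v}\tdirected\t{int(graph.is_constant(u, v))}\n")
        for u, v in graph.undirected_edges:
            fh.write(f"{u}\t{v}\tundirected\t0\n")


def read_graph_tsv(path, nodes: Sequence[str] | None = None) -> PartiallyDirectedGraph:
    g = PartiallyDirectedGraph(nodes or ())
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t")[:3] != ["source", "target", "mark"]:
            raise ValueError(f"{path}: unexpected header {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            u, v, mark, const = fields[:4]
            if mark == "directed":
                g.add_directed(u, v, constant=const == "1")
            elif mark == "undirected":
                g.add_undirected(u, v)
            else:
                raise ValueError(f"{path}:{lineno}: unknown mark {mark!r}")
    return g
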