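"""Graph containers and Markov-equivalence machinery.

Causal structure learners operate on three kinds of objects: directed
acyclic graphs (the ground-truth and estimated networks), partially
directed graphs (essential graphs / CPDAGs, which represent Markov
equivalence classes), and intervention families (which samples were
collected under which gene knockouts).

The equivalence machinery here follows the classical characterisations:
two DAGs are Markov equivalent iff they share skeleton and v-structures,
and with hard interventions the class is refined further because every
edge incident to an intervened node becomes identifiable.  Essential
graphs are computed by orienting v-structures (plus intervention-forced
edges) and closing under Meek's orientation rules; a brute-force
enumeration oracle over tiny graphs is provided for testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "DirectedGraph",
    "PartiallyDirectedGraph",
    "InterventionFamily",
    "InconsistentPDAGError",
    "is_acyclic",
    "skeleton_of",
    "essential_graph",
    "i_essential_graph",
    "meek_closure",
    "pdag_to_dag",
    "enumerate_mec",
    "count_oriented",
    "vstructures",
]


def _default_labels(n: int) -> list[str]:
    return [f"G{i}" for i in range(n)]


@dataclass
class DirectedGraph:
    """A directed graph over ``n`` labelled nodes as a binary adjacency matrix.

    ``adjacency[i, j] == 1`` means there is an edge ``i -> j``.  Node
    identity is positional; labels are decorative metadata.
    """

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.node_labels:
            self.node_labels = _default_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def from_edges(cls, n_nodes: int, edges, node_labels=None) -> "DirectedGraph":
        adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            adj[i, j] = 1
        return cls(adj, list(node_labels) if node_labels else [])

    @classmethod
    def empty(cls, n_nodes: int, node_labels=None) -> "DirectedGraph":
        return cls.from_edges(n_nodes, [], node_labels)

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in np.argwhere(self.adjacency == 1)]

    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def parents(self, node: int) -> list[int]:
        return list(np.flatnonzero(self.adjacency[:, node]))

    def children(self, node: int) -> list[int]:
        return list(np.flatnonzero(self.adjacency[node, :]))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g

    def copy(self) -> "DirectedGraph":
        return DirectedGraph(self.adjacency.copy(), list(self.node_labels))


@dataclass
class PartiallyDirectedGraph:
    """A graph with both directed and undirected edges (PDAG / CPDAG).

    Every unordered pair carries at most one edge, either directed
    (``directed[i, j] == 1`` for ``i -> j``) or undirected
    (``undirected[i, j] == undirected[j, i] == 1``).
    """

    directed: np.ndarray
    undirected: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.directed = np.asarray(self.directed, dtype=np.int8)
        self.undirected = np.asarray(self.undirected, dtype=np.int8)
        if self.directed.shape != self.undirected.shape:
            raise ValueError("matrix shapes differ")
        if np.any(np.diag(self.directed)) or np.any(np.diag(self.undirected)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(self.undirected, self.undirected.T):
            raise ValueError("undirected matrix must be symmetric")
        both = (self.directed + self.directed.T) * self.undirected
        if np.any(both):
            raise ValueError("a pair cannot be both directed and undirected")
        if not self.node_labels:
            self.node_labels = _default_labels(self.n_nodes)

    @property
    def n_nodes(self) -> int:
        return self.directed.shape[0]

    @classmethod
    def empty(cls, n_nodes: int, node_labels=None) -> "PartiallyDirectedGraph":
        z = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        return cls(z, z.copy(), list(node_labels) if node_labels else [])

    @classmethod
    def from_undirected_edges(cls, n_nodes: int, edges, node_labels=None) -> "PartiallyDirectedGraph":
        und = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            und[i, j] = und[j, i] = 1
        return cls(np.zeros_like(und), und, list(node_labels) if node_labels else [])

    def skeleton_adjacency(self) -> np.ndarray:
        """Symmetric 0/1 matrix of all adjacencies regardless of type."""
        sk = self.undirected + self.directed + self.directed.T
        return (sk > 0).astype(np.int8)

    def directed_edges(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in np.argwhere(self.directed == 1)]

    def undirected_edges(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in np.argwhere(np.triu(self.undirected) == 1)]

    def n_edges(self) -> int:
        return int(self.directed.sum() + np.triu(self.undirected).sum())

    def is_fully_undirected(self) -> bool:
        return not self.directed.any()

    def copy(self) -> "PartiallyDirectedGraph":
        return PartiallyDirectedGraph(
            self.directed.copy(), self.undirected.copy(), list(self.node_labels)
        )


@dataclass
class InterventionFamily:
    """Per-sample intervention targets: one set of clamped nodes per data row.

    The empty set marks an observational row.  Equivalence computations
    depend only on which *distinct* target sets exist, not on how many
    samples carry each, so :meth:`distinct_targets` deduplicates.
    """

    targets: list[frozenset[int]]

    def __post_init__(self) -> None:
        self.targets = [frozenset(t) for t in self.targets]

    @classmethod
    def observational(cls, n_samples: int) -> "InterventionFamily":
        return cls([frozenset()] * n_samples)

    def __len__(self) -> int:
        return len(self.targets)

    def validate(self, n_nodes: int) -> None:
        for t in self.targets:
            for i in t:
                if not 0 <= i < n_nodes:
                    raise ValueError(f"intervention target {i} out of range")

    def distinct_targets(self, include_observational: bool = True) -> list[frozenset[int]]:
        seen: set[frozenset[int]] = set(self.targets)
        if include_observational:
            seen.add(frozenset())
        return sorted(seen, key=lambda s: (len(s), sorted(s)))

    def is_observational_row(self) -> np.ndarray:
        return np.array([len(t) == 0 for t in self.targets], dtype=bool)


class InconsistentPDAGError(ValueError):
    """Raised when orientation rules force both directions on one edge."""


# ---------------------------------------------------------------------------
# basic operations


def is_acyclic(g: DirectedGraph) -> bool:
    """True iff ``g`` admits a topological order."""
    return nx.is_directed_acyclic_graph(g.to_networkx())


def skeleton_of(g: DirectedGraph) -> PartiallyDirectedGraph:
    """Undirected graph of adjacencies underlying ``g``."""
    und = ((g.adjacency + g.adjacency.T) > 0).astype(np.int8)
    return PartiallyDirectedGraph(np.zeros_like(und), und, list(g.node_labels))


def count_oriented(p: PartiallyDirectedGraph) -> int:
    """Number of directed edges of a partially directed graph."""
    return int(p.directed.sum())


def vstructures(adjacency: np.ndarray) -> set[tuple[int, int, int]]:
    """Colliders ``i -> k <- j`` with ``i``, ``j`` nonadjacent, as (i, j, k), i<j."""
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    sk = (adj + adj.T) > 0
    out: set[tuple[int, int, int]] = set()
    for k in range(n):
        pa = np.flatnonzero(adj[:, k])
        for i, j in itertools.combinations(pa, 2):
            if not sk[i, j]:
                out.add((min(i, j), max(i, j), k))
    return out


# ---------------------------------------------------------------------------
# Meek orientation rules


def _apply_meek_rules(directed: np.ndarray, undirected: np.ndarray) -> bool:
    """One sweep of Meek's four rules in place; returns True if anything changed.

    Raises :class:`InconsistentPDAGError` if a rule would orient an edge
    against an existing orientation.
    """
    n = directed.shape[0]
    sk = ((directed + directed.T + undirected) > 0).astype(np.int8)
    changed = False

    def orient(a: int, b: int) -> None:
        nonlocal changed
        if directed[b, a]:
            raise InconsistentPDAGError(f"rules force both directions on {a}-{b}")
        undirected[a, b] = undirected[b, a] = 0
        directed[a, b] = 1
        changed = True

    for a, b in np.argwhere(undirected == 1):
        if not undirected[a, b]:  # may have been oriented earlier this sweep
            continue
        # R1: c -> a, a - b, c and b nonadjacent  =>  a -> b
        if any(directed[c, a] and not sk[c, b] for c in range(n)):
            orient(a, b)
            continue
        # R2: a -> c -> b with a - b  =>  a -> b
        if any(directed[a, c] and directed[c, b] for c in range(n)):
            orient(a, b)
            continue
        # R3: a - c, a - d, c -> b, d -> b, c and d nonadjacent  =>  a -> b
        cand = [c for c in range(n) if undirected[a, c] and directed[c, b]]
        if any(not sk[c, d] for c, d in itertools.combinations(cand, 2)):
            orient(a, b)
            continue
        # R4: a - d, c -> d ... canonical form: a - b, a - c, c -> d, d -> b,
        # with b and c nonadjacent and a adjacent to d  =>  a -> b
        done = False
        for c in range(n):
            if done:
                break
            if not (undirected[a, c] and not sk[c, b]):
                continue
            for d in range(n):
                if directed[c, d] and directed[d, b] and sk[a, d]:
                    orient(a, b)
                    done = True
                    break
    return changed


def pdag_to_dag(p: PartiallyDirectedGraph) -> DirectedGraph:
    """A consistent DAG extension of a PDAG (Dor–Tarsi algorithm).

    Repeatedly finds a potential sink — a node with no outgoing directed
    edges whose undirected neighbours are adjacent to all its other
    neighbours — orients its undirected edges inward, and removes it.
    Raises :class:`InconsistentPDAGError` when no extension exists.
    """
    n = p.n_nodes
    directed = p.directed.copy()
    undirected = p.undirected.copy()
    out = directed.copy()
    alive = np.ones(n, dtype=bool)
    sk = ((directed + directed.T + undirected) > 0).astype(bool)
    while alive.any():
        found = False
        for x in np.flatnonzero(alive):
            if directed[x, alive].any():
                continue
            und_nbrs = np.flatnonzero(undirected[x] & alive)
            nbrs = np.flatnonzero(sk[x] & alive)
            if all(sk[u, w] for u in und_nbrs for w in nbrs if w != u):
                for u in und_nbrs:
                    out[u, x] = 1
                alive[x] = False
                directed[x, :] = directed[:, x] = 0
                undirected[x, :] = undirected[:, x] = 0
                sk[x, :] = sk[:, x] = False
                found = True
                break
        if not found:
            raise InconsistentPDAGError("PDAG admits no consistent DAG extension")
    return DirectedGraph(out, list(p.node_labels))


def meek_closure(p: PartiallyDirectedGraph, check_consistency: bool = True) -> PartiallyDirectedGraph:
    """Close a PDAG under Meek's four orientation rules.

    Skeleton-preserving and idempotent.  With ``check_consistency`` the
    closed graph is verified to admit a consistent DAG extension
    (Dor–Tarsi) and :class:`InconsistentPDAGError` is raised otherwise.
    """
    directed = p.directed.copy()
    undirected = p.undirected.copy()
    while _apply_meek_rules(directed, undirected):
        pass
    closed = PartiallyDirectedGraph(directed, undirected, list(p.node_labels))
    if check_consistency:
        pdag_to_dag(closed)
    return closed


# ---------------------------------------------------------------------------
# essential graphs


def _require_dag(g: DirectedGraph) -> None:
    if not is_acyclic(g):
        raise ValueError("input graph must be a DAG")


def essential_graph(g: DirectedGraph) -> PartiallyDirectedGraph:
    """CPDAG of the Markov equivalence class of a DAG.

    Edges participating in a v-structure keep their orientation, all
    other edges start undirected, and Meek's rules propagate the forced
    orientations.
    """
    _require_dag(g)
    return i_essential_graph(g, InterventionFamily([]))


def i_essential_graph(g: DirectedGraph, family: InterventionFamily) -> PartiallyDirectedGraph:
    """Interventional essential graph of a DAG under a family of hard targets.

    A hard intervention on target set ``I`` severs the incoming edges of
    every node in ``I``, so any edge with exactly one endpoint in some
    target set is identifiable from the corresponding interventional
    distribution and keeps its orientation from ``g``; v-structure edges
    are identifiable observationally; Meek closure propagates the rest.
    """
    _require_dag(g)
    family.validate(g.n_nodes)
    adj = g.adjacency
    n = g.n_nodes
    directed = np.zeros((n, n), dtype=np.int8)
    for i, j, k in vstructures(adj):
        directed[i, k] = 1
        directed[j, k] = 1
    for target in family.distinct_targets(include_observational=False):
        for i, j in np.argwhere(adj == 1):
            if (i in target) != (j in target):
                directed[i, j] = 1
    undirected = (((adj + adj.T) > 0).astype(np.int8)) * (1 - ((directed + directed.T) > 0))
    pdag = PartiallyDirectedGraph(directed, undirected, list(g.node_labels))
    # consistent by construction (orientations come from the DAG itself)
    return meek_closure(pdag, check_consistency=False)


# ---------------------------------------------------------------------------
# brute-force enumeration oracle (testing aid)


def _cut_adjacency(adj: np.ndarray, target: frozenset[int]) -> np.ndarray:
    """Adjacency after a hard intervention: incoming edges of targets removed."""
    cut = adj.copy()
    for t in target:
        cut[:, t] = 0
    return cut


def _i_equivalent(adj_a: np.ndarray, adj_b: np.ndarray, targets) -> bool:
    """Interventional Markov equivalence of two DAG adjacencies.

    Two DAGs are equivalent under a family of hard interventions iff for
    every target set (including the empty, observational one) the
    intervention-severed graphs share skeleton and v-structures.
    """
    for target in targets:
        ca, cb = _cut_adjacency(adj_a, target), _cut_adjacency(adj_b, target)
        if not np.array_equal((ca + ca.T) > 0, (cb + cb.T) > 0):
            return False
        if vstructures(ca) != vstructures(cb):
            return False
    return True


def enumerate_mec(g: DirectedGraph, family: InterventionFamily | None = None) -> list[DirectedGraph]:
    """All DAGs in the (interventional) Markov equivalence class of ``g``.

    Exhaustive over the ``2^|E|`` orientations of the skeleton; refuses
    graphs with more than 6 nodes.  Intended as a testing oracle, not a
    production path.
    """
    if g.n_nodes > 6:
        raise ValueError("enumeration oracle limited to 6 nodes")
    _require_dag(g)
    family = family or InterventionFamily([])
    family.validate(g.n_nodes)
    targets = family.distinct_targets(include_observational=True)
    edges = [(int(i), int(j)) for i, j in np.argwhere(np.triu((g.adjacency + g.adjacency.T) > 0))]
    members: list[DirectedGraph] = []
    for bits in itertools.product([0, 1], repeat=len(edges)):
        adj = np.zeros_like(g.adjacency)
        for (i, j), b in zip(edges, bits):
            if b:
                adj[i, j] = 1
            else:
                adj[j, i] = 1
        cand = DirectedGraph(adj, list(g.node_labels))
        if not is_acyclic(cand):
            continue
        if _i_equivalent(g.adjacency, adj, targets):
            members.append(cand)
    return members


def essential_from_enumeration(
    g: DirectedGraph, family: InterventionFamily | None = None
) -> PartiallyDirectedGraph:
    """(I-)essential graph computed directly from the enumeration oracle.

    An edge is directed iff it has the same orientation in every member
    of the enumerated class.  Testing aid mirroring the definition.
    """
    members = enumerate_mec(g, family)
    stack = np.stack([m.adjacency for m in members])
    always = stack.min(axis=0)  # edge present in every member with this orientation
    skeleton = ((g.adjacency + g.adjacency.T) > 0).astype(np.int8)
    directed = always.astype(np.int8)
    undirected = skeleton * (1 - ((directed + directed.T) > 0))
    return PartiallyDirectedGraph(directed, undirected, list(g.node_labels))
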