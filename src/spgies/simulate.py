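"""Synthetic benchmark: random topologies, linear-Gaussian SEMs, knockouts.

The benchmark emulates gene-regulatory-network recovery studies: an
undirected random topology (Erdős–Rényi, Barabási–Albert scale-free, or
Watts–Strogatz small-world) is oriented into a DAG, equipped with a
linear-Gaussian structural equation model, and sampled — 100
observational rows plus one hard-knockout row per gene by default.  A
knockout clamps the gene's expression to 0, severing its incoming
regulatory edges.

All randomness flows from a single integer seed; stage-specific
substreams are spawned deterministically via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import DirectedGraph, InterventionFamily, PartiallyDirectedGraph, is_acyclic

__all__ = [
    "GaussianSEM",
    "SampleSet",
    "KNOCKOUT_VALUE",
    "random_topology",
    "orient_random",
    "random_sem",
    "sample_observational",
    "sample_intervention",
    "make_benchmark",
]

#: Clamp value used for hard knockout interventions (expression silenced).
KNOCKOUT_VALUE = 0.0


@dataclass
class GaussianSEM:
    """Linear-Gaussian structural equation model on a DAG.

    ``weights[i, j]`` is the coefficient of gene ``i`` in gene ``j``'s
    structural equation; nonzero only where ``graph.adjacency`` has an
    edge.  Each node adds independent Gaussian noise with variance
    ``noise_vars``.
    """

    graph: DirectedGraph
    weights: np.ndarray
    noise_vars: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.noise_vars = np.asarray(self.noise_vars, dtype=float)
        if self.weights.shape != self.graph.adjacency.shape:
            raise ValueError("weight matrix shape mismatch")
        if np.any((self.weights != 0) & (self.graph.adjacency == 0)):
            raise ValueError("weights outside adjacency support")
        if np.any(self.noise_vars <= 0):
            raise ValueError("noise variances must be positive")
        if not is_acyclic(self.graph):
            raise ValueError("SEM graph must be a DAG")

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    def observational_covariance(self) -> np.ndarray:
        """Closed-form covariance (I - W)^-T diag(sigma^2) (I - W)^-1."""
        n = self.n_nodes
        m = np.linalg.inv(np.eye(n) - self.weights)
        return m.T @ np.diag(self.noise_vars) @ m

    def topological_order(self) -> list[int]:
        return list(nx.topological_sort(self.graph.to_networkx()))


@dataclass
class SampleSet:
    """Expression matrix (samples x genes) with row-aligned intervention targets."""

    data: np.ndarray
    family: InterventionFamily
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if len(self.family) != self.data.shape[0]:
            raise ValueError("family length must equal number of rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if not self.node_labels:
            self.node_labels = [f"G{i}" for i in range(self.n_nodes)]
        self.family.validate(self.n_nodes)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def observational(self) -> "SampleSet":
        """Subset of observational rows only."""
        mask = self.family.is_observational_row()
        return SampleSet(
            self.data[mask],
            InterventionFamily([t for t, m in zip(self.family.targets, mask) if m]),
            list(self.node_labels),
        )

    def concat(self, other: "SampleSet") -> "SampleSet":
        if other.n_nodes != self.n_nodes:
            raise ValueError("node count mismatch")
        return SampleSet(
            np.vstack([self.data, other.data]),
            InterventionFamily(self.family.targets + other.family.targets),
            list(self.node_labels),
        )


def _rng(seed, *spawn_key: int) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    if spawn_key:
        ss = np.random.SeedSequence(ss.entropy, spawn_key=tuple(ss.spawn_key) + spawn_key)
    return np.random.default_rng(ss)


def random_topology(
    kind: str, n_nodes: int, params: dict | None = None, seed=0
) -> PartiallyDirectedGraph:
    """Random undirected simple graph from one of three topology families.

    kind
        ``erdos_renyi`` (param ``p``: edge probability), ``scale_free``
        (param ``k``: attachment count, Barabási–Albert ``m``), or
        ``small_world`` (params ``k``: ring degree, ``p``: rewiring
        probability, Watts–Strogatz).
    """
    params = dict(params or {})
    rng = _rng(seed, 0)
    nx_seed = int(rng.integers(2**31))
    if kind == "erdos_renyi":
        p = params["p"]
        if not 0 <= p <= 1:
            raise ValueError("edge probability must be in [0, 1]")
        g = nx.gnp_random_graph(n_nodes, p, seed=nx_seed)
    elif kind == "scale_free":
        k = params["k"]
        if not 1 <= k < n_nodes:
            raise ValueError("attachment count k must satisfy 1 <= k < n")
        g = nx.barabasi_albert_graph(n_nodes, k, seed=nx_seed)
    elif kind == "small_world":
        k, p = params["k"], params["p"]
        if not 0 <= p <= 1:
            raise ValueError("rewiring probability must be in [0, 1]")
        if k >= n_nodes:
            raise ValueError("ring degree k must be < n")
        g = nx.watts_strogatz_graph(n_nodes, k, p, seed=nx_seed)
    else:
        raise ValueError(f"unknown topology kind: {kind!r}")
    return PartiallyDirectedGraph.from_undirected_edges(n_nodes, g.edges())


def orient_random(u: PartiallyDirectedGraph, seed=0) -> DirectedGraph:
    """Orient an undirected graph into a DAG via a uniform random node order.

    Each edge points from the earlier to the later node of a uniformly
    random permutation, which forbids cycles by construction.
    """
    if not u.is_fully_undirected():
        raise ValueError("input must be fully undirected")
    rng = _rng(seed, 1)
    order = rng.permutation(u.n_nodes)
    rank = np.empty(u.n_nodes, dtype=int)
    rank[order] = np.arange(u.n_nodes)
    adj = np.zeros_like(u.undirected)
    for i, j in u.undirected_edges():
        if rank[i] < rank[j]:
            adj[i, j] = 1
        else:
            adj[j, i] = 1
    return DirectedGraph(adj, list(u.node_labels))


def random_sem(
    g: DirectedGraph,
    seed=0,
    weight_range: tuple[float, float] = (0.25, 1.0),
    noise_var: float = 1.0,
) -> GaussianSEM:
    """Random edge weights on a DAG: |w| uniform in ``weight_range``, random sign.

    The lower magnitude bound keeps effects away from unfaithful
    near-zero cancellations; noise variance is homoscedastic.
    """
    if not is_acyclic(g):
        raise ValueError("graph must be a DAG")
    rng = _rng(seed, 2)
    lo, hi = weight_range
    w = np.zeros(g.adjacency.shape, dtype=float)
    idx = np.argwhere(g.adjacency == 1)
    if len(idx):
        mags = rng.uniform(lo, hi, size=len(idx))
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        w[idx[:, 0], idx[:, 1]] = mags * signs
    return GaussianSEM(g, w, np.full(g.n_nodes, noise_var))


def _sample_rows(sem: GaussianSEM, n: int, rng: np.random.Generator, clamp: dict[int, float]) -> np.ndarray:
    """Draw ``n`` rows in topological order, clamping ``clamp`` nodes."""
    x = np.zeros((n, sem.n_nodes))
    eps = rng.normal(0.0, np.sqrt(sem.noise_vars), size=(n, sem.n_nodes))
    for j in sem.topological_order():
        if j in clamp:
            x[:, j] = clamp[j]
        else:
            x[:, j] = x @ sem.weights[:, j] + eps[:, j]
    return x


def sample_observational(sem: GaussianSEM, n: int, seed=0) -> SampleSet:
    """``n`` iid draws from the SEM's observational joint distribution."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = _rng(seed, 3)
    data = _sample_rows(sem, n, rng, {})
    return SampleSet(data, InterventionFamily.observational(n), list(sem.graph.node_labels))


def sample_intervention(sem: GaussianSEM, target: int, value: float, n: int, seed=0) -> SampleSet:
    """``n`` draws under the hard intervention do(X_target = value).

    The target column is constant; non-descendants keep their
    observational law, descendants respond through the truncated
    factorization.
    """
    if not 0 <= target < sem.n_nodes:
        raise ValueError(f"invalid node index {target}")
    rng = _rng(seed, 4, target)
    data = _sample_rows(sem, n, rng, {target: value})
    fam = InterventionFamily([frozenset({target})] * n)
    return SampleSet(data, fam, list(sem.graph.node_labels))


def make_benchmark(
    kind: str,
    n_nodes: int,
    params: dict | None = None,
    n_obs: int = 100,
    seed=0,
) -> tuple[DirectedGraph, GaussianSEM, SampleSet]:
    """Full benchmark instance: truth DAG, SEM, and its sampled dataset.

    The dataset has ``n_obs`` observational rows followed by one
    hard-knockout row (clamp value 0) per node, in node order.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    topo = random_topology(kind, n_nodes, params, seed=ss)
    dag = orient_random(topo, seed=ss)
    sem = random_sem(dag, seed=ss)
    samples = sample_observational(sem, n_obs, seed=ss)
    for node in range(n_nodes):
        samples = samples.concat(sample_intervention(sem, node, KNOCKOUT_VALUE, 1, seed=ss))
    return dag, sem, samples
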