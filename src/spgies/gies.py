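"""Greedy interventional equivalence search (GIES) and its skeleton-primed form.

The learner maximises a decomposable Gaussian BIC over DAGs by greedy
single-edge moves — forward (insertions), backward (deletions), and
turning (reversals) — each phase run to a local optimum and the phases
cycled until no move improves the score.  Interventional rows enter the
score through the truncated factorization of hard interventions: a row
that clamps gene ``i`` carries no information about ``i``'s structural
equation, so ``i``'s local score is computed over the rows whose target
set excludes ``i``.

SP-GIES first estimates an undirected skeleton from observational rows
(PC, CLR or ARACNE) and restricts the greedy search's candidate edge set
to the skeleton's pairs, shrinking the combinatorial search space.

The public surface follows the model/results idiom: build a
:class:`GIES` or :class:`SPGIES` model from a :class:`~spgies.simulate.SampleSet`,
call ``fit()``, and read the estimates off the returned
:class:`StructureResults`.  ``fit_gies`` / ``sp_gies`` are functional
shorthands for the same thing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graphs import DirectedGraph, PartiallyDirectedGraph, i_essential_graph
from .simulate import SampleSet
from .skeletons import estimate_skeleton

__all__ = [
    "InterventionalScoreCache",
    "local_score",
    "StructureResults",
    "GIES",
    "SPGIES",
    "fit_gies",
    "sp_gies",
    "null_result",
]

NEG_INF = float("-inf")
#: minimum score improvement for a greedy move to be accepted
_GAIN_TOL = 1e-9


class InterventionalScoreCache:
    """Memoised Gaussian BIC local scores over intervention-aware row subsets.

    For each node the usable rows are those whose intervention target set
    does not contain the node; their Gram matrix ``X^T X`` is
    precomputed once so a local score is a small linear solve.
    """

    def __init__(self, samples: SampleSet):
        self.samples = samples
        self.n_nodes = samples.n_nodes
        data = samples.data
        targets = samples.family.targets
        self._rows: list[np.ndarray] = []
        self._gram: list[np.ndarray] = []
        self._m: list[int] = []
        distinct = {}
        for i in range(self.n_nodes):
            rows = np.array([r for r, t in enumerate(targets) if i not in t], dtype=int)
            key = rows.tobytes()
            if key not in distinct:
                x = data[rows]
                distinct[key] = (rows, x.T @ x)
            rows, gram = distinct[key]
            self._rows.append(rows)
            self._gram.append(gram)
            self._m.append(len(rows))
        self._memo: dict[tuple[int, frozenset[int]], float] = {}

    def usable_rows(self, node: int) -> np.ndarray:
        return self._rows[node]

    def local_score(self, node: int, parents) -> float:
        """BIC local score of regressing ``node`` on ``parents``.

        ``-(m/2)(1 + log(2 pi sigma^2)) - (log m / 2)(|parents| + 1)``
        with ``m`` usable rows and ``sigma^2`` the ML residual variance.
        Returns ``-inf`` for degenerate designs (rank deficiency, zero
        residual variance, or fewer than ``|parents| + 2`` usable rows).
        """
        parents = frozenset(parents)
        key = (node, parents)
        if key in self._memo:
            return self._memo[key]
        m = self._m[node]
        p = sorted(parents)
        if m < len(p) + 2:
            score = NEG_INF
        else:
            gram = self._gram[node]
            syy = gram[node, node]
            if p:
                spp = gram[np.ix_(p, p)]
                spy = gram[p, node]
                try:
                    coef = np.linalg.solve(spp, spy)
                except np.linalg.LinAlgError:
                    self._memo[key] = NEG_INF
                    return NEG_INF
                rss = syy - spy @ coef
            else:
                rss = syy
            sigma2 = rss / m
            if not np.isfinite(sigma2) or sigma2 <= 1e-12:
                score = NEG_INF
            else:
                score = -(m / 2) * (1 + math.log(2 * math.pi * sigma2)) \
                        - (math.log(m) / 2) * (len(p) + 1)
        self._memo[key] = score
        return score

    def total_score(self, adjacency: np.ndarray) -> float:
        return sum(
            self.local_score(j, np.flatnonzero(adjacency[:, j]))
            for j in range(self.n_nodes)
        )


def local_score(node: int, parents, samples: SampleSet) -> float:
    """Standalone BIC local score (see :meth:`InterventionalScoreCache.local_score`)."""
    return InterventionalScoreCache(samples).local_score(node, parents)


@dataclass
class StructureResults:
    """Fitted structure-learning result.

    Attributes
    ----------
    graph : PartiallyDirectedGraph
        The I-essential graph of the fitted class.
    member_dag : DirectedGraph
        A member DAG of the class (the greedy search's final state).
    score : float
        Total BIC score of the member DAG.
    method, params, seed
        Provenance of the run.
    score_trace : list of float
        Total score after each accepted move (strictly increasing).
    """

    graph: PartiallyDirectedGraph
    member_dag: DirectedGraph
    score: float
    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    score_trace: list = field(default_factory=list)

    def n_edges(self) -> int:
        return self.graph.n_edges()

    def summary(self) -> str:
        lines = [
            f"{'Structure learning results':^58}",
            "=" * 58,
            f"{'Method:':<24}{self.method}",
            f"{'Nodes:':<24}{self.graph.n_nodes}",
            f"{'Edges (essential):':<24}{self.graph.n_edges()}",
            f"{'  directed:':<24}{int(self.graph.directed.sum())}",
            f"{'  undirected:':<24}{len(self.graph.undirected_edges())}",
            f"{'BIC score:':<24}{self.score:.4f}",
            f"{'Accepted moves:':<24}{max(len(self.score_trace) - 1, 0)}",
        ]
        if self.seed is not None:
            lines.append(f"{'Seed:':<24}{self.seed}")
        for k, v in self.params.items():
            lines.append(f"{'  ' + k + ':':<24}{v}")
        lines.append("=" * 58)
        return "\n".join(lines)


def _reachability(adjacency: np.ndarray) -> np.ndarray:
    """Boolean matrix R with R[i, j] = directed path i ~> j exists (i != j).

    Transitive closure by repeated squaring in float32 (BLAS-backed).
    """
    reach = adjacency.astype(np.float32)
    nnz = np.count_nonzero(reach)
    while True:
        reach = np.minimum(reach + reach @ reach, 1.0)
        new_nnz = np.count_nonzero(reach)
        if new_nnz == nnz:
            return reach.astype(bool)
        nnz = new_nnz


def _has_alternative_path(adj: np.ndarray, u: int, v: int) -> bool:
    """Directed path u ~> v avoiding the edge (u, v) itself."""
    work = adj.copy()
    work[u, v] = 0
    return bool(_reachability(work)[u, v])


class GIES:
    """Greedy interventional equivalence search model.

    Parameters
    ----------
    samples : SampleSet
        Mixed observational/interventional expression data.
    allowed : PartiallyDirectedGraph, optional
        Undirected restriction of the candidate edge set; only pairs
        adjacent in ``allowed`` may ever carry an edge.  ``None`` means
        unrestricted.
    phases : tuple of str
        Which greedy phases to cycle: subset of
        ``("forward", "backward", "turning")``.
    refine : bool
        After the phase cycle converges, run an edge-reversal
        perturbation stage (iterated local search): each current edge is
        tentatively reversed and the phases re-run; the compound move is
        kept only when it strictly improves the total score.  Escapes the
        orientation-trap local optima that pure single-edge hill
        climbing is prone to on weakly informative interventional data.
    """

    def __init__(
        self,
        samples: SampleSet,
        allowed: PartiallyDirectedGraph | None = None,
        phases: tuple[str, ...] = ("forward", "backward", "turning"),
        refine: bool = True,
        max_refine_rounds: int = 5,
    ):
        self.samples = samples
        self.phases = tuple(phases)
        self.refine = refine
        self.max_refine_rounds = max_refine_rounds
        bad = set(self.phases) - {"forward", "backward", "turning"}
        if bad:
            raise ValueError(f"unknown phase(s): {sorted(bad)}")
        n = samples.n_nodes
        if allowed is None:
            self.allowed_pairs = np.ones((n, n), dtype=bool)
            np.fill_diagonal(self.allowed_pairs, False)
        else:
            if allowed.n_nodes != n:
                raise ValueError("allowed graph node count mismatch")
            self.allowed_pairs = allowed.skeleton_adjacency().astype(bool)
        self.cache = InterventionalScoreCache(samples)

    @classmethod
    def from_dataframe(cls, frame, intervention_column: str = "intervention", **kwargs) -> "GIES":
        """Build from a samples-by-genes DataFrame with an intervention column.

        The intervention column holds comma-separated clamped gene labels
        (empty string for observational rows).
        """
        from .io import sampleset_from_dataframe

        return cls(sampleset_from_dataframe(frame, intervention_column), **kwargs)

    # -- greedy phases ------------------------------------------------------
    #
    # The engine maintains one delta table D: for a non-parent u of v,
    # D[u, v] is the score gain of adding u -> v; for a parent u of v it
    # is the gain of deleting u -> v.  A single-edge move touches the
    # parent sets of at most two nodes, so only those columns are
    # recomputed after a move; feasibility (acyclicity, allowed pairs)
    # is masked in at selection time.

    def _delta_column(self, adj, v: int) -> np.ndarray:
        ls = self.cache.local_score
        n = adj.shape[0]
        pa = frozenset(int(x) for x in np.flatnonzero(adj[:, v]))
        base = ls(v, pa)
        col = np.full(n, -np.inf)
        for u in range(n):
            if u == v:
                continue
            if adj[u, v]:
                col[u] = ls(v, pa - {u}) - base
            elif self.allowed_pairs[u, v]:
                col[u] = ls(v, pa | {u}) - base
        return col

    def _init_delta(self, adj) -> np.ndarray:
        n = adj.shape[0]
        return np.column_stack([self._delta_column(adj, v) for v in range(n)])

    def _best_pair(self, gains: np.ndarray):
        """Highest gain with lexicographic (u, v) tie-break, or None."""
        flat = np.argmax(gains)  # first maximum in row-major = lex smallest
        u, v = divmod(int(flat), gains.shape[1])
        if gains[u, v] <= _GAIN_TOL:
            return None
        return u, v

    def _candidate_gains(self, phase, adj, delta) -> np.ndarray:
        n = adj.shape[0]
        edge = adj.astype(bool)
        gains = np.full((n, n), -np.inf)
        if phase == "forward":
            free = self.allowed_pairs & ~edge & ~edge.T
            np.fill_diagonal(free, False)
            reach = _reachability(adj)
            free &= ~reach.T  # u -> v closes a cycle iff v ~> u
            gains[free] = delta[free]
        elif phase == "backward":
            gains[edge] = delta[edge]
        else:  # turning: reverse u -> v; feasible iff no alternative u ~> v path
            # in a DAG, a path u ~> v avoiding the edge (u, v) exists iff
            # some other child w of u reaches v, and such a path can never
            # route through (u, v) (that would close a cycle at u)
            reach = _reachability(adj)
            alt = (edge.astype(np.float32) @ reach.astype(np.float32)) > 0
            feasible = edge & ~alt
            gains[feasible] = delta[feasible] + delta.T[feasible]
        return gains

    def _run_phase(self, phase, adj, trace, delta) -> bool:
        moved = False
        while True:
            gains = self._candidate_gains(phase, adj, delta)
            best = self._best_pair(gains)
            if best is None:
                return moved
            u, v = best
            gain = gains[u, v]
            if phase == "forward":
                adj[u, v] = 1
                touched = (v,)
            elif phase == "backward":
                adj[u, v] = 0
                touched = (v,)
            else:
                adj[u, v] = 0
                adj[v, u] = 1
                touched = (u, v)
            for t in touched:
                delta[:, t] = self._delta_column(adj, t)
            trace.append(trace[-1] + gain)
            moved = True

    def _cycle_phases(self, adj, trace, delta) -> None:
        while True:
            any_move = False
            for phase in self.phases:
                any_move |= self._run_phase(phase, adj, trace, delta)
            if not any_move:
                break

    def _refine(self, adj, trace, delta) -> None:
        """Edge-reversal perturbations, each kept only on strict improvement."""
        for _ in range(self.max_refine_rounds):
            improved = False
            for u, v in sorted((int(a), int(b)) for a, b in np.argwhere(adj == 1)):
                if not adj[u, v] or _has_alternative_path(adj, u, v):
                    continue
                work = adj.copy()
                work[u, v] = 0
                work[v, u] = 1
                wdelta = delta.copy()
                wdelta[:, u] = self._delta_column(work, u)
                wdelta[:, v] = self._delta_column(work, v)
                sub = [trace[-1] + delta[u, v] + delta[v, u]]
                self._cycle_phases(work, sub, wdelta)
                if sub[-1] > trace[-1] + _GAIN_TOL:
                    adj[:] = work
                    delta[:] = wdelta
                    trace.append(sub[-1])
                    improved = True
            if not improved:
                return

    def fit(self, method: str = "gies", params: dict | None = None, seed=None) -> StructureResults:
        """Run the greedy search and return the fitted results object."""
        n = self.samples.n_nodes
        adj = np.zeros((n, n), dtype=np.int8)
        trace = [self.cache.total_score(adj)]
        delta = self._init_delta(adj)
        self._cycle_phases(adj, trace, delta)
        if self.refine:
            self._refine(adj, trace, delta)
        dag = DirectedGraph(adj, list(self.samples.node_labels))
        assert np.all(((adj + adj.T) > 0) <= self.allowed_pairs), \
            "estimated edge outside the allowed set"
        ess = i_essential_graph(dag, self.samples.family)
        exact = self.cache.total_score(adj)
        run_params = {"phases": list(self.phases),
                      "restricted": not self.allowed_pairs.all(where=~np.eye(n, dtype=bool))}
        run_params.update(params or {})
        return StructureResults(
            graph=ess, member_dag=dag, score=exact, method=method,
            params=run_params, seed=seed, score_trace=trace,
        )


class SPGIES(GIES):
    """Skeleton-primed GIES: estimate a skeleton, then restrict the search.

    Step (1) runs the named observational skeleton estimator (``pc``,
    ``clr``, ``aracne`` or ``none``) on the observational rows; step (2)
    runs GIES on all rows with the candidate edge set restricted to the
    skeleton's adjacencies.  When PC supplies a CPDAG only its skeleton
    restricts the search — PC's orientations are not forced.
    """

    def __init__(
        self,
        samples: SampleSet,
        skeleton_method: str = "pc",
        skeleton_params: dict | None = None,
        phases: tuple[str, ...] = ("forward", "backward", "turning"),
    ):
        self.skeleton_method = skeleton_method
        self.skeleton_params = dict(skeleton_params or {})
        skel = estimate_skeleton(samples, skeleton_method, self.skeleton_params)
        self.skeleton = skel
        super().__init__(samples, allowed=skel, phases=phases)

    def fit(self, params: dict | None = None, seed=None) -> StructureResults:
        run_params = {"skeleton_method": self.skeleton_method,
                      "skeleton_params": dict(self.skeleton_params)}
        run_params.update(params or {})
        return super().fit(method="sp-gies", params=run_params, seed=seed)


def fit_gies(
    samples: SampleSet,
    allowed: PartiallyDirectedGraph | None = None,
    phases: tuple[str, ...] = ("forward", "backward", "turning"),
    seed=None,
) -> StructureResults:
    """Fit GIES on mixed data, optionally restricted to an allowed edge set."""
    return GIES(samples, allowed=allowed, phases=phases).fit(seed=seed)


def sp_gies(
    samples: SampleSet,
    skeleton_method: str = "pc",
    skeleton_params: dict | None = None,
    phases: tuple[str, ...] = ("forward", "backward", "turning"),
    seed=None,
) -> StructureResults:
    """Two-step SP-GIES: skeleton estimation, then restricted GIES."""
    return SPGIES(samples, skeleton_method, skeleton_params, phases=phases).fit(seed=seed)


def null_result(n_nodes: int, node_labels=None) -> StructureResults:
    """Edge-free baseline network ("NULL")."""
    labels = list(node_labels) if node_labels else []
    return StructureResults(
        graph=PartiallyDirectedGraph.empty(n_nodes, labels or None),
        member_dag=DirectedGraph.empty(n_nodes, labels or None),
        score=float("nan"),
        method="null",
    )
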