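"""Evaluation metrics for estimated networks: SHD, SID, AUC-PR.

SHD is taken literally as the L1 distance between binary adjacency
matrices, so a reversed edge costs 2 (both entries differ); undirected
edges of a partially directed estimate are expanded to both ordered
entries before comparison.  SID counts ordered node pairs whose
post-intervention distribution would be inferred incorrectly when the
estimate's parent sets are used for covariate adjustment, via the
graphical adjustment criterion (forbidden set + d-separation in the
proper back-door graph).  AUC-PR is the area under the precision-recall
curve of ordered-pair edge predictions (scikit-learn average precision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score

from .graphs import DirectedGraph, PartiallyDirectedGraph

__all__ = ["EvaluationReport", "shd", "sid", "aucpr", "evaluate"]


def _estimate_adjacency(estimate) -> np.ndarray:
    """Binary ordered-pair adjacency with undirected edges in both directions."""
    if isinstance(estimate, DirectedGraph):
        return estimate.adjacency.astype(np.int8)
    if isinstance(estimate, PartiallyDirectedGraph):
        return (estimate.directed + estimate.undirected).astype(np.int8)
    # results object carrying .graph
    graph = getattr(estimate, "graph", None)
    if graph is not None:
        return _estimate_adjacency(graph)
    raise TypeError(f"cannot interpret estimate of type {type(estimate)!r}")


def shd(truth: DirectedGraph, estimate) -> int:
    """Structural Hamming distance: L1 error between adjacency matrices."""
    est = _estimate_adjacency(estimate)
    if est.shape != truth.adjacency.shape:
        raise ValueError("node-count mismatch between truth and estimate")
    return int(np.abs(truth.adjacency.astype(int) - est.astype(int)).sum())


def _valid_adjustment(g: nx.DiGraph, reach: np.ndarray, i: int, j: int, z: frozenset[int]) -> bool:
    """Adjustment criterion: is Z valid for the effect of i on j in g?

    Z must avoid the forbidden set (descendants of nodes on proper
    causal paths i -> ... -> j, including those nodes) and d-separate i
    from j in the proper back-door graph (g minus the first edge of
    every proper causal path).
    """
    n = reach.shape[0]
    # nodes (other than i) lying on a proper causal path from i to j
    cn = {w for w in range(n)
          if w != i and reach[i, w] and (w == j or reach[w, j])}
    forb = set(cn)
    for w in cn:
        forb.update(v for v in range(n) if reach[w, v])
    if z & forb:
        return False
    pbd = g.copy()
    for w in list(g.successors(i)):
        if w in cn:
            pbd.remove_edge(i, w)
    return nx.is_d_separator(pbd, {i}, {j}, set(z))


def sid(truth: DirectedGraph, estimate: DirectedGraph) -> int:
    """Structural intervention distance between two DAGs.

    For each ordered pair (i, j) the estimate's parent set Pa(i) is used
    as the adjustment set for the effect of i on j; the pair counts as a
    mistake when that adjustment is invalid in the truth, or when j is
    declared a parent of i (null effect) while being a true descendant
    of i.
    """
    for name, g in (("truth", truth), ("estimate", estimate)):
        if not nx.is_directed_acyclic_graph(g.to_networkx()):
            raise ValueError(f"{name} must be a DAG")
    n = truth.n_nodes
    if estimate.n_nodes != n:
        raise ValueError("node-count mismatch")
    if n > 2000:
        warnings.warn("SID on graphs this large is quadratic-to-cubic in n")
    g = truth.to_networkx()
    reach = _nx_reachability(truth.adjacency)
    true_pa = [frozenset(truth.parents(i)) for i in range(n)]
    mistakes = 0
    for i in range(n):
        z = frozenset(estimate.parents(i))
        if z == true_pa[i]:
            continue  # the true parents are always a valid adjustment set
        for j in range(n):
            if j == i:
                continue
            if j in z:
                if reach[i, j]:
                    mistakes += 1
            elif not _valid_adjustment(g, reach, i, j, z):
                mistakes += 1
    return mistakes


def _nx_reachability(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    reach = np.zeros((n, n), dtype=bool)
    children = [np.flatnonzero(adjacency[i]) for i in range(n)]
    for i in range(n):
        stack = list(children[i])
        seen = set(stack)
        while stack:
            v = stack.pop()
            reach[i, v] = True
            for w in children[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
    return reach


def sid_linear_sem_oracle(truth: DirectedGraph, estimate: DirectedGraph, seed: int = 0,
                          n_draws: int = 3, tol: float = 1e-7) -> int:
    """Numeric SID oracle via generic linear SEMs (testing aid).

    Draws generic edge weights on the truth, computes the true total
    causal effect of i on j (from (I - W)^-1) and the parent-adjustment
    estimand (partial regression coefficient of i in the regression of j
    on {i} union Pa_est(i), from the model covariance).  A pair is a
    mistake if the two disagree on any weight draw; multiple draws guard
    against accidental cancellations.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_nodes
    mistakes = np.zeros((n, n), dtype=bool)
    for _ in range(n_draws):
        w = truth.adjacency * rng.uniform(0.5, 1.5, size=(n, n)) \
            * rng.choice([-1.0, 1.0], size=(n, n))
        minv = np.linalg.inv(np.eye(n) - w)
        cov = minv.T @ minv  # unit noise
        total = minv  # total[i, j] = causal effect of i on j
        for i in range(n):
            z = sorted(estimate.parents(i))
            cols = [i] + z
            s_xx = cov[np.ix_(cols, cols)]
            for j in range(n):
                if j == i:
                    continue
                true_eff = total[i, j]
                if j in z:
                    est_eff = 0.0
                else:
                    beta = np.linalg.solve(s_xx, cov[cols, j])
                    est_eff = beta[0]
                if abs(est_eff - true_eff) > tol:
                    mistakes[i, j] = True
    return int(mistakes.sum())


def aucpr(truth: DirectedGraph, estimate) -> float:
    """Area under the precision-recall curve of ordered-pair edge scores.

    ``estimate`` may be a score matrix (symmetric scores count for both
    directions), a graph (edge indicator as a two-level score), or a
    results object carrying either.
    """
    n = truth.n_nodes
    if isinstance(estimate, np.ndarray):
        scores = np.asarray(estimate, dtype=float)
    else:
        graph = getattr(estimate, "graph", estimate)
        scores = _estimate_adjacency(graph).astype(float)
    if scores.shape != (n, n):
        raise ValueError("score matrix shape mismatch")
    off = ~np.eye(n, dtype=bool)
    y_true = truth.adjacency[off].astype(int)
    y_score = scores[off]
    if y_true.sum() == 0:
        raise ValueError("truth has no edges; AUC-PR undefined")
    return float(average_precision_score(y_true, y_score))


@dataclass
class EvaluationReport:
    """SHD / SID / AUC-PR of one estimate against one ground truth."""

    shd: int
    sid: int | None
    aucpr: float
    mode: str = "directed"

    def __post_init__(self) -> None:
        if not 0 <= self.aucpr <= 1:
            raise ValueError("aucpr out of [0, 1]")

    def as_dict(self) -> dict:
        return {"shd": self.shd, "sid": self.sid, "aucpr": self.aucpr, "mode": self.mode}


def evaluate(truth: DirectedGraph, estimate, scores: np.ndarray | None = None,
             compute_sid: bool = True) -> EvaluationReport:
    """Full evaluation of an estimate (graph or results object) vs the truth."""
    shd_val = shd(truth, estimate)
    sid_val = None
    if compute_sid:
        member = getattr(estimate, "member_dag", estimate)
        if isinstance(member, PartiallyDirectedGraph):
            sid_val = None  # SID needs a DAG representative
        else:
            sid_val = sid(truth, member)
    auc = aucpr(truth, scores if scores is not None else estimate)
    mode = "directed" if isinstance(estimate, DirectedGraph) else "partially-directed"
    return EvaluationReport(shd_val, sid_val, auc, mode)
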