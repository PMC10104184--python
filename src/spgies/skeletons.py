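"""Observational skeleton estimators: PC, CLR, ARACNE, deviation matrix.

These supply step (1) of skeleton-primed GIES: an undirected adjacency
estimate computed from observational rows only, which then restricts the
greedy interventional search's candidate edge set.

PC is the order-independent ("stable") constraint-based search with the
Fisher-z partial-correlation test; CLR and ARACNE score pairs by mutual
information, with CLR standardising each entry against its row
backgrounds and ARACNE pruning the weakest edge of every triangle via
the data-processing inequality.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats

from .graphs import PartiallyDirectedGraph, meek_closure
from .simulate import SampleSet

__all__ = [
    "fisher_z_ci_test",
    "pc_estimate",
    "mutual_information_matrix",
    "clr_scores",
    "threshold_top_fraction",
    "aracne_prune",
    "mi_null_threshold",
    "deviation_matrix",
]


def fisher_z_ci_test(data, i: int, j: int, cond, alpha: float = 0.01):
    """Gaussian conditional-independence test for X_i vs X_j given X_cond.

    Returns ``(statistic, p_value, independent)``: the Fisher
    z-transformed partial correlation scaled by ``sqrt(n - |cond| - 3)``,
    its two-sided normal p-value, and the decision ``p >= alpha``.
    A singular conditioning covariance is flagged as dependent.
    """
    data = np.asarray(data, dtype=float)
    cond = sorted(cond)
    n = data.shape[0]
    if len(cond) >= n - 3:
        raise ValueError("conditioning set too large for the sample size")
    cols = [i, j] + list(cond)
    sub = data[:, cols]
    cov = np.cov(sub, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return np.inf, 0.0, False
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        return np.inf, 0.0, False
    r = -prec[0, 1] / np.sqrt(denom)
    r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    z = 0.5 * np.log((1 + r) / (1 - r))
    stat = np.sqrt(n - len(cond) - 3) * abs(z)
    p = 2 * stats.norm.sf(stat)
    return float(stat), float(p), bool(p >= alpha)


def pc_estimate(
    samples: SampleSet,
    alpha: float = 0.01,
    max_cond_size: int | None = None,
) -> PartiallyDirectedGraph:
    """Stable PC algorithm on the observational rows of ``samples``.

    Adjacency search with conditioning sets of growing size (adjacency
    sets frozen within each level for order independence), then
    v-structure orientation from separating sets and Meek closure.
    Returns a CPDAG.
    """
    obs = samples.observational()
    data = obs.data
    n_samples, n = data.shape
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    sepsets: dict[tuple[int, int], frozenset[int]] = {}

    level = 0
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        if level >= n_samples - 3:
            warnings.warn(
                "sample size too small for conditioning sets of size "
                f"{level}; stopping the adjacency search early"
            )
            break
        frozen = adj.copy()  # stable variant: neighbourhoods fixed per level
        any_testable = False
        for i in range(n):
            for j in range(i + 1, n):
                if not adj[i, j]:
                    continue
                removed = False
                for a, b in ((i, j), (j, i)):
                    nbrs = [k for k in np.flatnonzero(frozen[a]) if k != b]
                    if len(nbrs) < level:
                        continue
                    any_testable = True
                    for cond in itertools.combinations(nbrs, level):
                        _, _, indep = fisher_z_ci_test(data, a, b, cond, alpha)
                        if indep:
                            adj[i, j] = adj[j, i] = False
                            sepsets[(i, j)] = sepsets[(j, i)] = frozenset(cond)
                            removed = True
                            break
                    if removed:
                        break
        if not any_testable:
            break
        level += 1

    directed = np.zeros((n, n), dtype=np.int8)
    undirected = adj.astype(np.int8)
    # v-structures: i - k - j with i, j nonadjacent and k outside sepset(i, j)
    for k in range(n):
        nbrs = np.flatnonzero(adj[k])
        for i, j in itertools.combinations(nbrs, 2):
            if adj[i, j]:
                continue
            if k not in sepsets.get((i, j), frozenset()):
                if not (directed[k, i] or directed[k, j]):
                    directed[i, k] = directed[j, k] = 1
                    undirected[i, k] = undirected[k, i] = 0
                    undirected[j, k] = undirected[k, j] = 0
    undirected *= 1 - ((directed + directed.T) > 0)
    pdag = PartiallyDirectedGraph(directed, undirected, list(samples.node_labels))
    try:
        return meek_closure(pdag)
    except Exception:
        # conflicting v-structures on finite samples: fall back to the
        # unclosed PDAG, whose skeleton is what SP-GIES consumes
        return pdag


def _gaussian_mi(data: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1 + 1e-12, 1 - 1e-12)
    mi = -0.5 * np.log(1 - corr**2)
    np.fill_diagonal(mi, 0.0)
    return mi


def _histogram_mi(data: np.ndarray, bins: int = 8) -> np.ndarray:
    n_samples, n = data.shape
    # equal-width bin index per column
    digitized = np.empty_like(data, dtype=int)
    for j in range(n):
        col = data[:, j]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            digitized[:, j] = 0
        else:
            digitized[:, j] = np.clip(((col - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = np.zeros((bins, bins))
            np.add.at(joint, (digitized[:, i], digitized[:, j]), 1.0)
            joint /= n_samples
            pi = joint.sum(axis=1, keepdims=True)
            pj = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log(joint / (pi * pj))
            mi[i, j] = mi[j, i] = np.nansum(term)
    return mi


def mutual_information_matrix(samples: SampleSet, estimator: str = "gaussian") -> np.ndarray:
    """Symmetric pairwise mutual-information matrix over observational rows.

    ``gaussian`` uses the closed form -0.5 log(1 - rho^2); ``histogram``
    uses an 8-bin equal-width joint histogram.  Zero-variance columns
    yield MI 0 with a warning.
    """
    obs = samples.observational()
    if obs.n_samples < 3:
        raise ValueError("need at least 3 observational samples")
    data = obs.data
    stds = data.std(axis=0)
    if np.any(stds == 0):
        warnings.warn("zero-variance column(s); their MI set to 0")
    if estimator == "gaussian":
        mi = _gaussian_mi(data)
    elif estimator == "histogram":
        mi = _histogram_mi(data)
    else:
        raise ValueError(f"unknown MI estimator: {estimator!r}")
    mi[stds == 0, :] = 0.0
    mi[:, stds == 0] = 0.0
    np.fill_diagonal(mi, 0.0)
    return mi


def clr_scores(mi: np.ndarray) -> np.ndarray:
    """Context-likelihood-of-relatedness background correction.

    Each MI entry is z-scored against the off-diagonal background of its
    row; the CLR score is ``sqrt(max(z_i, 0)^2 + max(z_j, 0)^2)``.
    Rows with zero background spread contribute 0.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    means = np.array([mi[i, off[i]].mean() for i in range(n)])
    sds = np.array([mi[i, off[i]].std() for i in range(n)])
    z = np.zeros_like(mi)
    ok = sds > 0
    z[ok, :] = (mi[ok, :] - means[ok, None]) / sds[ok, None]
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return scores


def threshold_top_fraction(scores: np.ndarray, fraction: float, node_labels=None) -> PartiallyDirectedGraph:
    """Keep the ceil(fraction * n(n-1)/2) highest-scoring pairs as edges.

    Symmetric scores are read from the upper triangle; ties break by
    (i, j) index order, so the kept count depends only on ``n`` and
    ``fraction``, never on the score scale.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    k = int(np.ceil(fraction * len(pairs)))
    ranked = sorted(pairs, key=lambda ij: (-scores[ij[0], ij[1]], ij[0], ij[1]))
    return PartiallyDirectedGraph.from_undirected_edges(n, ranked[:k], node_labels)


def aracne_prune(
    mi: np.ndarray,
    mi_threshold: float,
    dpi_tolerance: float = 0.0,
    node_labels=None,
) -> PartiallyDirectedGraph:
    """ARACNE: MI thresholding plus data-processing-inequality pruning.

    Entries below ``mi_threshold`` are dropped; then for every surviving
    triangle the edge (i, j) is removed when
    ``MI(i, j) < min(MI(i, k), MI(j, k)) * (1 - dpi_tolerance)`` —
    the weakest leg of a triangle is taken to be an indirect
    interaction.  Removals are marked on a scan of all triangles and
    applied simultaneously.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    keep = (mi >= mi_threshold).astype(bool)
    np.fill_diagonal(keep, False)
    keep &= keep.T
    remove = np.zeros_like(keep)
    for i, j, k in itertools.combinations(range(n), 3):
        if keep[i, j] and keep[i, k] and keep[j, k]:
            for (a, b), (c, d), (e, f) in (
                ((i, j), (i, k), (j, k)),
                ((i, k), (i, j), (j, k)),
                ((j, k), (i, j), (i, k)),
            ):
                if mi[a, b] < min(mi[c, d], mi[e, f]) * (1 - dpi_tolerance):
                    remove[a, b] = remove[b, a] = True
    keep &= ~remove
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if keep[i, j]]
    return PartiallyDirectedGraph.from_undirected_edges(n, edges, node_labels)


def mi_null_threshold(
    samples: SampleSet,
    p_value: float = 1e-8,
    n_permutations: int = 1000,
    seed=0,
    estimator: str = "gaussian",
) -> float:
    """MI cutoff whose permutation-null exceedance probability is ~``p_value``.

    Null MI values are generated by permuting one column of random pairs,
    destroying dependence while preserving marginals.  Because useful
    p-values (e.g. 1e-8) are far beyond any feasible permutation count,
    the tail beyond the 90th percentile is fitted with an exponential
    (peaks-over-threshold) model and the cutoff extrapolated from it;
    p-values resolvable by the empirical sample use the empirical
    quantile directly.
    """
    if not 0 < p_value < 1:
        raise ValueError("p_value must be in (0, 1)")
    obs = samples.observational()
    data = obs.data
    if data.std(axis=0).max() == 0:
        raise ValueError("degenerate data: all columns constant")
    rng = np.random.default_rng(np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed)
    n_samples, n = data.shape
    nulls = np.empty(n_permutations)
    for b in range(n_permutations):
        i, j = rng.choice(n, size=2, replace=False)
        x = data[:, i]
        y = data[rng.permutation(n_samples), j]
        if estimator == "gaussian":
            r = np.corrcoef(x, y)[0, 1]
            r = np.clip(np.nan_to_num(r), -1 + 1e-12, 1 - 1e-12)
            nulls[b] = -0.5 * np.log(1 - r**2)
        else:
            nulls[b] = _histogram_mi(np.column_stack([x, y]))[0, 1]
    nulls.sort()
    if p_value >= 10.0 / n_permutations:
        return float(np.quantile(nulls, 1 - p_value))
    tail_q = 0.9
    u = float(np.quantile(nulls, tail_q))
    exceed = nulls[nulls > u] - u
    beta = float(exceed.mean()) if len(exceed) else 1e-12
    # P(MI > t) = (1 - tail_q) * exp(-(t - u) / beta) = p_value
    return u + beta * np.log((1 - tail_q) / p_value)


def deviation_matrix(samples: SampleSet) -> np.ndarray:
    """Directed knockout-response scores from paired obs/knockout data.

    ``score[i, j]`` is the absolute deviation of gene ``j``'s expression
    in the knockout of gene ``i`` from its observational mean, in units
    of its observational standard deviation.  Requires exactly one
    single-node knockout row per node.
    """
    n = samples.n_nodes
    obs = samples.observational()
    if obs.n_samples == 0:
        raise ValueError("no observational rows")
    ko_rows: dict[int, np.ndarray] = {}
    for row, target in zip(samples.data, samples.family.targets):
        if len(target) == 1:
            (t,) = target
            ko_rows.setdefault(t, row)
    missing = [i for i in range(n) if i not in ko_rows]
    if missing:
        raise ValueError(f"missing knockout sample for node(s) {missing}")
    mean = obs.data.mean(axis=0)
    std = obs.data.std(axis=0)
    std[std == 0] = 1.0
    scores = np.zeros((n, n))
    for i in range(n):
        scores[i] = np.abs(ko_rows[i] - mean) / std
    np.fill_diagonal(scores, 0.0)
    return scores


def estimate_skeleton(
    samples: SampleSet,
    method: str,
    params: dict | None = None,
) -> PartiallyDirectedGraph | None:
    """Dispatch a named skeleton estimator; ``None`` means unrestricted.

    Methods: ``pc`` (param ``alpha``), ``clr`` (``estimator``,
    ``top_fraction``), ``aracne`` (``estimator``, ``p_value``,
    ``n_permutations``, ``dpi_tolerance``, ``seed`` or explicit
    ``mi_threshold``), ``none``.
    """
    params = dict(params or {})
    if method == "none":
        return None
    if method == "pc":
        return pc_estimate(samples, alpha=params.get("alpha", 0.01),
                           max_cond_size=params.get("max_cond_size"))
    if method == "clr":
        mi = mutual_information_matrix(samples, params.get("estimator", "gaussian"))
        scores = clr_scores(mi)
        return threshold_top_fraction(scores, params.get("top_fraction", 0.10),
                                      samples.node_labels)
    if method == "aracne":
        mi = mutual_information_matrix(samples, params.get("estimator", "gaussian"))
        thr = params.get("mi_threshold")
        if thr is None:
            thr = mi_null_threshold(
                samples,
                p_value=params.get("p_value", 1e-8),
                n_permutations=params.get("n_permutations", 1000),
                seed=params.get("seed", 0),
                estimator=params.get("estimator", "gaussian"),
            )
        return aracne_prune(mi, thr, params.get("dpi_tolerance", 0.0), samples.node_labels)
    raise ValueError(f"unknown skeleton method: {method!r}")
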