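"""Optimal experimental design: choosing the next gene to knock out.

The loop maintains a bootstrap approximation of the posterior over DAGs
(resample the data within observational/interventional strata, refit the
learner), scores every candidate knockout with a utility — the expected
number of newly oriented edges, or an information-gain surrogate over
edge states — picks the argmax (or a uniform draw for the random
baseline), draws one new interventional sample from the true system,
appends it, refits, and records recovery metrics round by round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log

import numpy as np

from .graphs import DirectedGraph, InterventionFamily, count_oriented, i_essential_graph
from .metrics import aucpr, shd
from .simulate import KNOCKOUT_VALUE, GaussianSEM, SampleSet, sample_intervention

__all__ = [
    "PosteriorSample",
    "OEDState",
    "bootstrap_posterior",
    "utility_edge_orientation",
    "utility_information_gain",
    "select_intervention",
    "run_oed_loop",
]


@dataclass
class PosteriorSample:
    """Weighted collection of bootstrap-fitted member DAGs."""

    graphs: list[DirectedGraph]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.graphs) != len(self.weights):
            raise ValueError("graphs and weights length mismatch")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")


@dataclass
class OEDState:
    """Evolving state of the acquisition loop."""

    samples: SampleSet
    candidate_targets: list[int]
    history: list[dict] = field(default_factory=list)


def bootstrap_posterior(samples: SampleSet, learner, B: int = 20, seed=0,
                        resample: bool = True) -> PosteriorSample:
    """Bootstrap posterior: refit ``learner`` on B stratified resamples.

    Observational and interventional rows are resampled with replacement
    within their own strata so every replicate keeps the design's
    composition.  ``learner`` is a callable ``SampleSet -> StructureResults``.
    Failed replicates are dropped with a warning and weights renormalised.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(samples.family.is_observational_row())
    int_idx = np.flatnonzero(~samples.family.is_observational_row())
    graphs: list[DirectedGraph] = []
    for _ in range(B):
        if resample:
            rows = np.concatenate([
                rng.choice(obs_idx, size=len(obs_idx), replace=True) if len(obs_idx) else [],
                rng.choice(int_idx, size=len(int_idx), replace=True) if len(int_idx) else [],
            ]).astype(int)
            rep = SampleSet(
                samples.data[rows],
                InterventionFamily([samples.family.targets[r] for r in rows]),
                list(samples.node_labels),
            )
        else:
            rep = samples
        try:
            graphs.append(learner(rep).member_dag)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"bootstrap replicate failed and was dropped: {exc}")
    if not graphs:
        raise RuntimeError("every bootstrap replicate failed")
    w = np.full(len(graphs), 1.0 / len(graphs))
    return PosteriorSample(graphs, w)


def _as_family(existing_targets) -> list[frozenset[int]]:
    return [frozenset(t) for t in existing_targets]


def utility_edge_orientation(posterior: PosteriorSample, existing_targets, candidate: int) -> float:
    """Expected number of edges newly oriented by knocking out ``candidate``.

    For each posterior DAG, the gain is the directed-edge count of its
    I-essential graph under the enlarged target family minus that under
    the existing family; the utility is the posterior-weighted mean.
    """
    existing = _as_family(existing_targets)
    enlarged = existing + [frozenset({candidate})]
    total = 0.0
    for g, w in zip(posterior.graphs, posterior.weights):
        before = count_oriented(i_essential_graph(g, InterventionFamily(existing)))
        after = count_oriented(i_essential_graph(g, InterventionFamily(enlarged)))
        total += w * (after - before)
    return total


def _edge_state_entropy(graphs: list[DirectedGraph], weights: np.ndarray) -> float:
    """Sum over node pairs of the entropy of DAG edge states (absent/fwd/rev)."""
    n = graphs[0].n_nodes
    h = 0.0
    stack = np.stack([g.adjacency for g in graphs])
    for i in range(n):
        for j in range(i + 1, n):
            p_fwd = float(weights[stack[:, i, j] == 1].sum())
            p_rev = float(weights[stack[:, j, i] == 1].sum())
            p_abs = max(1.0 - p_fwd - p_rev, 0.0)
            for p in (p_fwd, p_rev, p_abs):
                if p > 0:
                    h -= p * log(p)
    return h


def utility_information_gain(posterior: PosteriorSample, existing_targets, candidate: int) -> float:
    """Expected decrease in edge-state entropy from knocking out ``candidate``.

    Current entropy sums, over node pairs, the Shannon entropy of the
    bootstrap frequencies of the three edge states (absent, i->j, j->i).
    The experiment's expected outcome partitions the posterior by the
    I-essential graph each DAG induces under the enlarged family —
    indistinguishable DAGs stay together — and the expected posterior
    entropy is the weighted average of within-group entropies.
    Nonnegative by concavity of entropy.
    """
    if len(posterior.graphs) < 2:
        return 0.0
    existing = _as_family(existing_targets)
    enlarged = InterventionFamily(existing + [frozenset({candidate})])
    h_current = _edge_state_entropy(posterior.graphs, posterior.weights)
    groups: dict[bytes, list[int]] = {}
    for idx, g in enumerate(posterior.graphs):
        ess = i_essential_graph(g, enlarged)
        key = ess.directed.tobytes() + ess.undirected.tobytes()
        groups.setdefault(key, []).append(idx)
    h_after = 0.0
    for members in groups.values():
        w = posterior.weights[members]
        w_group = float(w.sum())
        if w_group <= 0:
            continue
        h_after += w_group * _edge_state_entropy(
            [posterior.graphs[m] for m in members], w / w_group
        )
    return max(h_current - h_after, 0.0)


_STRATEGIES = ("random", "info_gain", "edge_orient")


def select_intervention(state: OEDState, posterior: PosteriorSample, strategy: str, seed=0) -> int:
    """Pick the next knockout target: utility argmax or uniform draw.

    Ties break to the lowest node index.
    """
    candidates = list(state.candidate_targets)
    if not candidates:
        raise ValueError("no candidate targets")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return int(candidates[rng.integers(len(candidates))])
    existing = set(t for t in state.samples.family.targets if t)
    if strategy == "edge_orient":
        utilities = [utility_edge_orientation(posterior, existing, c) for c in candidates]
    elif strategy == "info_gain":
        utilities = [utility_information_gain(posterior, existing, c) for c in candidates]
    else:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {_STRATEGIES}")
    best = max(range(len(candidates)), key=lambda k: (utilities[k], -candidates[k]))
    return int(candidates[best])


def run_oed_loop(
    sem: GaussianSEM,
    learner,
    strategy: str = "edge_orient",
    rounds: int = 10,
    B: int = 20,
    seed=0,
    initial: SampleSet | None = None,
    n_obs: int = 100,
    truth: DirectedGraph | None = None,
) -> OEDState:
    """Run the acquisition loop against a known generating SEM.

    Each round: bootstrap the posterior, select a knockout target, draw
    ONE new interventional sample from the true SEM at that target,
    append it, refit the point estimate, and record SHD and AUC-PR
    against the truth.  Round 0 records the initial fit before any
    designed intervention.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    truth = truth or sem.graph
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    streams = ss.spawn(3)
    boot_rng = np.random.default_rng(streams[0])
    select_rng = np.random.default_rng(streams[1])
    sample_stream = streams[2]
    if initial is None:
        from .simulate import sample_observational

        initial = sample_observational(sem, n_obs, seed=ss)
    state = OEDState(samples=initial, candidate_targets=list(range(sem.n_nodes)))

    def record(rnd: int, chosen: int | None) -> None:
        fit = learner(state.samples)
        state.history.append({
            "round": rnd,
            "chosen": chosen,
            "shd": shd(truth, fit.graph),
            "aucpr": aucpr(truth, fit),
        })

    record(0, None)
    for rnd in range(1, rounds + 1):
        posterior = bootstrap_posterior(
            state.samples, learner, B=B, seed=boot_rng.integers(2**31)
        )
        target = select_intervention(
            state, posterior, strategy, seed=select_rng.integers(2**31)
        )
        new = sample_intervention(
            sem, target, KNOCKOUT_VALUE, 1,
            seed=np.random.SeedSequence(
                sample_stream.entropy,
                spawn_key=tuple(sample_stream.spawn_key) + (rnd,),
            ),
        )
        state.samples = state.samples.concat(new)
        record(rnd, target)
    return state
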