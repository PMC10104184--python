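"""Delimited-text I/O for sample sets, graphs, score matrices; fixtures.

All files are tab-delimited text.  A sample set is a samples-by-genes
table whose final ``intervention`` column holds comma-separated clamped
gene labels (empty for observational rows).  A graph file starts with a
header line declaring the node count and labels, followed by one edge
per line as ``source<TAB>target<TAB>{directed,undirected}``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import DirectedGraph, InterventionFamily, PartiallyDirectedGraph
from .simulate import SampleSet

__all__ = [
    "read_sampleset",
    "write_sampleset",
    "sampleset_from_dataframe",
    "sampleset_to_dataframe",
    "read_graph",
    "write_graph",
    "read_scores",
    "write_scores",
    "make_fixtures",
    "write_manifest",
]

INTERVENTION_COLUMN = "intervention"


def sampleset_to_dataframe(s: SampleSet) -> pd.DataFrame:
    frame = pd.DataFrame(s.data, columns=s.node_labels)
    frame[INTERVENTION_COLUMN] = [
        ",".join(s.node_labels[i] for i in sorted(t)) for t in s.family.targets
    ]
    return frame


def sampleset_from_dataframe(frame: pd.DataFrame,
                             intervention_column: str = INTERVENTION_COLUMN) -> SampleSet:
    if intervention_column not in frame.columns:
        raise ValueError(f"missing {intervention_column!r} column")
    labels = [c for c in frame.columns if c != intervention_column]
    label_index = {lab: i for i, lab in enumerate(labels)}
    data = frame[labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-numeric or non-finite expression values")
    targets = []
    for cell in frame[intervention_column].fillna(""):
        cell = str(cell).strip()
        if not cell:
            targets.append(frozenset())
            continue
        names = [c.strip() for c in cell.split(",") if c.strip()]
        unknown = [c for c in names if c not in label_index]
        if unknown:
            raise ValueError(f"unknown node label(s) in intervention column: {unknown}")
        targets.append(frozenset(label_index[c] for c in names))
    return SampleSet(data, InterventionFamily(targets), labels)


def write_sampleset(s: SampleSet, path) -> None:
    sampleset_to_dataframe(s).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sampleset(path) -> SampleSet:
    frame = pd.read_csv(path, sep="\t", dtype={INTERVENTION_COLUMN: str})
    return sampleset_from_dataframe(frame)


def write_graph(g, path) -> None:
    """Write a directed or partially directed graph as an edge-list file."""
    lines = [f"# nodes={g.n_nodes}\tlabels={','.join(g.node_labels)}"]
    if isinstance(g, DirectedGraph):
        directed, undirected = g.edges(), []
    elif isinstance(g, PartiallyDirectedGraph):
        directed, undirected = g.directed_edges(), g.undirected_edges()
    else:
        raise TypeError(f"cannot write graph of type {type(g)!r}")
    for i, j in sorted(directed):
        lines.append(f"{g.node_labels[i]}\t{g.node_labels[j]}\tdirected")
    for i, j in sorted(undirected):
        lines.append(f"{g.node_labels[i]}\t{g.node_labels[j]}\tundirected")
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path):
    """Read an edge-list file; returns a DirectedGraph when all edges are
    directed, else a PartiallyDirectedGraph."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# nodes="):
        raise ValueError("missing graph header line")
    head = lines[0][2:].split("\t")
    n = int(head[0].split("=", 1)[1])
    labels = head[1].split("=", 1)[1].split(",") if len(head) > 1 and head[1] else []
    labels = [l for l in labels if l] or [f"G{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match declared node count")
    index = {lab: i for i, lab in enumerate(labels)}
    directed, undirected = [], []
    seen: set[tuple[int, int]] = set()
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed edge line: {ln!r}")
        src, dst, kind = parts
        if src not in index or dst not in index:
            raise ValueError(f"unknown node label in edge: {ln!r}")
        i, j = index[src], index[dst]
        if i == j:
            raise ValueError(f"self-loop not allowed: {ln!r}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge on pair {key}")
        seen.add(key)
        if kind == "directed":
            directed.append((i, j))
        elif kind == "undirected":
            undirected.append((i, j))
        else:
            raise ValueError(f"unknown edge type {kind!r}")
    if not undirected:
        return DirectedGraph.from_edges(n, directed, labels)
    d = np.zeros((n, n), dtype=np.int8)
    u = np.zeros((n, n), dtype=np.int8)
    for i, j in directed:
        d[i, j] = 1
    for i, j in undirected:
        u[i, j] = u[j, i] = 1
    return PartiallyDirectedGraph(d, u, labels)


def write_scores(scores: np.ndarray, labels, path) -> None:
    pd.DataFrame(scores, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.10g")


def read_scores(path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), list(frame.columns)


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the canonical small fixtures used by tests and examples.

    Chain and collider 3-node SEM datasets plus 10-node Erdős–Rényi,
    scale-free and small-world benchmark instances (truth DAG, SEM
    weights, 100 obs + 10 knockout samples).  Deterministic under seed.
    """
    from .simulate import make_benchmark, random_sem, sample_observational, sample_intervention, KNOCKOUT_VALUE

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, dag: DirectedGraph, sem, samples: SampleSet) -> None:
        p1, p2, p3 = out / f"{name}_truth.tsv", out / f"{name}_samples.tsv", out / f"{name}_weights.tsv"
        write_graph(dag, p1)
        write_sampleset(samples, p2)
        write_scores(sem.weights, dag.node_labels, p3)
        written.extend([p1, p2, p3])

    small = {
        "chain3": DirectedGraph.from_edges(3, [(0, 1), (1, 2)]),
        "collider3": DirectedGraph.from_edges(3, [(0, 2), (1, 2)]),
    }
    for k, (name, dag) in enumerate(small.items()):
        sem = random_sem(dag, seed=np.random.SeedSequence(seed, spawn_key=(10 + k,)))
        samples = sample_observational(sem, 100, seed=np.random.SeedSequence(seed, spawn_key=(20 + k,)))
        for node in range(dag.n_nodes):
            samples = samples.concat(sample_intervention(
                sem, node, KNOCKOUT_VALUE, 1,
                seed=np.random.SeedSequence(seed, spawn_key=(30 + k, node))))
        emit(name, dag, sem, samples)

    bench = {
        "er10": ("erdos_renyi", {"p": 0.5}),
        "ba10": ("scale_free", {"k": 2}),
        "ws10": ("small_world", {"k": 2, "p": 0.5}),
    }
    for k, (name, (kind, params)) in enumerate(bench.items()):
        dag, sem, samples = make_benchmark(
            kind, 10, params, n_obs=100,
            seed=np.random.SeedSequence(seed, spawn_key=(100 + k,)))
        emit(name, dag, sem, samples)
    return written


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, command: str, params: dict, seed,
                   inputs=(), outputs=()) -> None:
    """Record a run's parameters and file digests so it can be re-driven."""
    from . import __version__

    manifest = {
        "command": command,
        "params": params,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": {str(p): _digest(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
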