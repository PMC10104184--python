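# Methods

This note records the model, the algorithmic and numerical choices, and
the known limitations of the `spgies` package. Empirical figures quoted
here are the ones recomputed by `scripts/acceptance.py` and the test
suite; nothing else is claimed.

## Model and assumptions

Data are modelled by a linear structural equation model with Gaussian
noise on a directed acyclic graph `G`:

```
x_j = Σ_{i ∈ Pa_G(j)}  w_ij x_i + ε_j,      ε_j ~ N(0, σ_j²) independent
```

All variables are zero-mean and regressions are fit **without an
intercept**. A knockout of gene `j` is a perfect ("hard") intervention:
incoming edges of `j` are severed and `x_j` is clamped to the constant
`0`. Every sample row is tagged with its (possibly empty) set of
intervention targets; the collection of distinct target sets, always
including the empty set, forms the intervention family.

Identifiability follows the interventional Markov equivalence class
(I-MEC): two DAGs are indistinguishable exactly when, for every target
set in the family, their intervened ("cut") graphs share skeleton and
v-structures. The package's `i_essential_graph` computes the I-essential
graph by orienting v-structures and edges with exactly one endpoint in
some target set, then closing under Meek rules R1–R4; an exhaustive
enumeration oracle (`enumerate_mec`, `essential_from_enumeration`)
verifies this procedure on every 4-node DAG in the test suite
(agreement rate 1.0, also recomputed by the acceptance script).

## Interventional score

The score is a decomposable interventional Gaussian BIC. For node `j`
with candidate parents `Pa`, let the usable rows be those whose target
set does **not** contain `j` (`m` of them), and let `σ̂²` be the
residual variance of the no-intercept least-squares regression of `x_j`
on `x_Pa` over those rows. Then

```
score(j | Pa) = −(m/2)·(1 + log 2πσ̂²) − (log m / 2)·(|Pa| + 1).
```

The total score is the sum over nodes. Rows in which `j` is a knockout
target carry no information about `j`'s mechanism and are excluded from
its local score; they still inform every other node. Local scores are
memoised per `(node, parent-set)`; per-node Gram matrices over the
usable rows are shared across parent sets.

The suite verifies score equivalence across interventional equivalence
classes: all members of an I-MEC receive the same total score on data
generated under that family (to numerical tolerance).

## Search

`GIES.fit` runs greedy phases over DAG space, each phase to a local
optimum, cycled until none improves:

- **forward**: best single-edge insertion (acyclicity-checked);
- **backward**: best single-edge deletion;
- **turning**: best single-edge reversal, feasible when no alternative
  directed path `u ⇝ v` exists outside the edge `(u, v)` itself.

Move gains come from an incrementally maintained delta table
`D[u, v]` (insertion gain if `u ∉ Pa(v)`, deletion gain otherwise;
reversal gain `D[u, v] + D[v, u]`); only columns whose parent sets
changed are recomputed. Reachability uses a float32 repeated-squaring
transitive closure. Ties are broken lexicographically, and a gain must
exceed `1e-9` (`_GAIN_TOL`) to be accepted, making the search fully
deterministic.

**Refinement.** Plain phase cycling demonstrably stalls in local optima
whose score is below that of the true DAG on the 50-node benchmark.
`fit` therefore ends with a deterministic iterated-local-search stage
(`refine=True`, up to 5 rounds): each present edge is tentatively
reversed, phases are re-converged, and the compound move is kept only if
the total score strictly improves. On the benchmark this reaches the
same optimum whether the search starts from the empty graph or from the
true DAG. The score trace records accepted (compound) moves, and
strictly increases.

`SPGIES` first estimates an undirected skeleton from the observational
rows only, then runs the same search restricted to the skeleton's node
pairs, scoring on all rows. Restricted runs never add an edge outside
the allowed set (tested).

## Skeleton estimators

- **PC** (default, `alpha = 0.01`): stable PC with Fisher-z partial
  correlation tests; separating sets are recorded, v-structures
  oriented, Meek closure applied. Only the skeleton (adjacency) is used
  by SP-GIES.
- **CLR**: mutual information matrix (Gaussian closed form
  `−½ log(1 − ρ²)` by default, or an 8-bin histogram estimator),
  z-scored against each gene's row/column background; the top fraction
  (default 10%) of pairs is kept.
- **ARACNE**: MI matrix thresholded by a permutation null (exponential
  tail fit beyond the 0.9 quantile), then pruned by the data-processing
  inequality applied simultaneously to all triangles.

## Benchmark generator — study conditions

The simulation conditions are fixed properties of the study, chosen
once and not tuned:

- topologies: Erdős–Rényi `G(n, p)`, Barabási–Albert (scale-free,
  `m = k`), Watts–Strogatz (small-world, `k` neighbours, rewiring
  probability `p`), oriented by a random permutation. Watts–Strogatz
  keeps exactly `n·k/2` edges and Barabási–Albert `m·(n − m)`; the
  standard `G(n, p)` generator has binomially distributed edge counts
  with mean `p·n(n−1)/2`.
- edge weights `|w| ~ U[0.25, 1]` with random sign; noise variance 1
  for every gene; knockouts clamp to the value 0; the default benchmark
  draws 100 observational rows plus **one** knockout row per gene.

Two consequences are worth stating plainly:

1. **Knockouts clamp to the mean.** Since all variables are zero-mean,
   setting a gene to 0 does not shift the mean of its descendants; the
   orientation signal carried by a knockout row is a pure variance
   signal. A single knockout row therefore orients its edges only
   weakly — with one `do(X)` and one `do(Y)` row added to 100
   observational rows of a two-gene system, the BIC comparison picks
   the true direction only ~60% of the time even at weight 0.9. With
   100 rows per knockout condition the orientation rate is 1.00 (the
   quantity `two_node_orientation_rate` in the acceptance output).
2. **A desk-scale accuracy ceiling.** With weights as small as 0.25 and
   unit noise, some edges carry marginal correlations below what
   `n = 100` observational samples can detect: the PC skeleton at
   `alpha = 0.01` misses a substantial minority of the 50-node
   small-world benchmark's edges, and the single knockout row per gene
   misorients others even when the skeleton is correct, because the BIC
   optimum genuinely places those edges backwards. Measured over 30
   seeds (recomputed by the acceptance script), SP-GIES reaches mean
   AUC-PR ≈ 0.50 versus ≈ 0.28 for the unrestricted search. The
   advantage of skeleton priming is large and stable; the absolute
   level is capped by the study conditions, not by the optimiser.

The generator does **not** emulate transcriptomic count noise,
mRNA-level measurement error, feedback, latent confounding, or partial
knockdowns; it is a linear-Gaussian testbed for the structure-learning
machinery.

## Metrics

- **SHD**: entry-wise L1 distance between adjacency matrices; a
  reversed edge costs 2. An undirected estimated edge is expanded to
  both directed entries before comparison, so matching one direction of
  a true edge costs 1 (the spurious opposite entry).
- **SID**: for each ordered pair `(i, j)` the estimate's parent set
  `Pa_est(i)` is checked as an adjustment set in the true graph via the
  adjustment criterion — forbidden nodes are the descendants of nodes
  on proper causal paths, and validity requires d-separation in the
  proper back-door graph (networkx `is_d_separator`). The
  implementation is verified against an independent numeric oracle
  (`sid_linear_sem_oracle`): random-weight linear SEMs in which the
  covariance-based adjustment estimand is compared to the true total
  effect from `(I − W)^{-1}`. Agreement is exhaustive on all 3-node DAG
  pairs and sampled 4-node pairs.
- **AUC-PR**: scikit-learn average precision over all ordered node
  pairs, with the true adjacency as labels. A binary graph estimate is
  scored as a two-level ranking; an undirected estimated edge scores
  both directions. Under this convention an edge-free (or random)
  predictor scores approximately the edge prevalence
  `#edges / (n(n−1))`, not 0.5 — baselines reported under other PR
  conventions are not comparable. AUC-PR of an edgeless *truth* is
  undefined and rejected.

## Experimental design

`bootstrap_posterior` refits the learner on `B` stratified bootstrap
resamples (resampling within each intervention condition, uniform
weights, default `B = 20`); the member DAGs form a posterior sample
over structures.

- `utility_edge_orientation(posterior, existing, candidate)`: expected
  number of directed edges of each posterior DAG's I-essential graph
  under the family enlarged by the candidate singleton target.
- `utility_information_gain`: current entropy of the pairwise
  edge-state distribution (absent / → / ←) minus the expected entropy
  after the experiment, where posterior DAGs are grouped by their
  I-essential graph under the enlarged family (the experiment's
  observable outcome). On a two-graph `{X→Y, Y→X}` posterior the
  utility is `log 2`.

Both utilities vanish on posteriors that the existing family already
fully orients. `select_intervention` takes the arg-max over candidate
targets (lowest index on ties; `random` strategy ignores utilities).
`run_oed_loop` starts from observational data only, and each round adds
**one** knockout row of the chosen target, refits, and records SHD and
AUC-PR against the truth. The loop is evaluated with the
skeleton-primed learner: its PC skeleton depends only on the
observational rows, which the loop never changes, so rounds move edge
orientations rather than the adjacency estimate. Mean initial and
final SHD per strategy are recomputed by the acceptance script.

## Numerical choices and problem sizes

- Greedy acceptance tolerance `_GAIN_TOL = 1e-9`; lexicographic
  tie-breaks; no randomness in the search itself.
- All random draws flow from `numpy.random.SeedSequence` with explicit
  spawn keys; derived integer seeds are reduced below `2^31`.
- Transitive closure in float32 repeated squaring (exact for these
  0/1 matrices at the sizes used).
- Suite and acceptance sizes: exhaustive oracles at 3–4 nodes,
  randomised invariants at 5–12 nodes, the recovery study at 50 nodes,
  edge-count identities at up to 1000 nodes, the OED study at 10 nodes
  with 10 rounds and `B = 20`. These sizes are the package's own choice
  to keep a full run within desk-scale compute budgets.
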