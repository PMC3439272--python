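# Methods

## Model

The package scores molecular interactions, not genes. Per-gene data values
`w` must be strictly positive and multiplicative: the transition
probability from node `i` to node `j` is `p_ij = w_j / Σ_{k∈N_i} w_k`,
where `N_i` is the set of immediate downstream neighbors of `i` (an
undirected edge is bidirectional and contributes an arc in each direction).
The stationary distribution `g` solves `g = g[(1−q)P + q·1·rᵀ]` with
restart distribution `r = w/Σw` — the restart is *data-biased*, not
uniform: teleportation lands on a node proportionally to its data value,
which is what makes high-data regions sources of walk mass. The probability
of traversing arc `i→j` at stationarity is `e_ij = g_i p_ij`, and the Edge
Flux of an interaction is `EF = log(e_w / e_r)` where the baseline `e_r`
comes from an identical walk with all `w = 1`. Because the baseline walk
sees the same topology, degree and hub structure, the ratio cancels
topology bias and leaves only data signal.

Term scores extend this additively. An interaction carries term `f` when
both endpoints are annotated to it; `p(f)` is the sum of `e` over the
carrying interactions, and `s(f) = log(p_w(f)/p_r(f))`. Set-size bias
cancels for the same reason as topology bias.

Assumptions worth stating: weights are positive and multiplicative
(fold-change-like); the network is taken at face value (no edge
confidences); the walk model treats all interaction types identically; and
directionality is respected only in the transition structure, not in the
data.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 0.01 | restart probability; larger `q` localizes the walk around high-data nodes, smaller `q` lets network structure dominate. The default is deliberately small so connectivity matters. |
| `tol` | 1e-10 | L1 stopping tolerance of the power iteration. Convergence is geometric at rate ≤ 1−q, so the iteration count is ≈ log(1/tol)/q ≈ 2300. Tests against closed-form or dense-solve references pass 1e-13. |
| `max_iter` | 10000 | iteration cap; non-convergence raises with the final residual. |
| `log_base` | e | EF and s(f) are natural-log scores; `--log-base 2` rescales for users used to log2 outputs. |
| `transform` | `up` | log2-ratio x → weight 2^x; `down` uses 2^(−x) so the two directions are exact reciprocals; `identity` takes values as-is (must be positive). |
| `missing_fill` | 1 | weight for unmeasured genes — exactly the baseline weight, so missing data contributes zero Edge Flux evidence. |
| `floor` | 1e-8 | lower clamp keeping weights strictly positive. |
| `min_edges`, `min_level` | 6, 6 | term filters: at least 6 carrying interactions, ontology depth at least 6 (both boundary-inclusive; 0 disables). Shallow terms ("nucleus") are too generic to interpret. |

## Numerical choices

- **Solver.** Sparse power iteration from `r`, L1 stopping rule. A dense
  left-eigenvector solve is used only as an independent oracle in tests.
  Rows with no outgoing arcs (dangling) are replaced by `r`; their
  stationary mass corresponds to no network arc, so the conservation
  identity is `Σe + (dangling mass) = 1`, reducing to `Σe = 1` on
  dangling-free graphs.
- **Baseline caching.** `e_r` depends only on topology and `q`; it is
  computed once per network and reused across all data columns.
- **Undirected symmetrization.** EF of an undirected edge sums the two arc
  probabilities in numerator and denominator before the log: the
  interaction is one event. This makes the isolated-pair identity exact
  (for a single undirected edge, `e_AB + e_BA = Σg = 1` in both walks, so
  EF = 0 regardless of data). Per-arc scores remain available.
- **Undefined scores.** A score whose baseline probability is zero is NaN,
  never 0 — a pseudocount would invent evidence. With positive weights the
  restart makes every node's visitation positive, so this is defensive; it
  can only trigger on degenerate inputs. NaN cells are excluded from
  filters, variance and clustering (incomplete rows are dropped before
  clustering rather than imputed).
- **Determinism.** Node order is sorted, all reductions are sequential,
  and output headers carry parameters but no timestamps; identical inputs
  give byte-identical tables.
- **Duplicate edges.** Deduplication is by (unordered pair, type label);
  a pair seen both directed and undirected within a type resolves to
  undirected (logged). Parallel typed edges between one pair collapse to a
  single arc in the walk so transition probability is not double-counted,
  but stay separate table rows.
- **Ties.** Variance ranking breaks ties by row identifier, lexicographic.
- **Hypergeometric tail.** Computed with exact integer combinatorics
  (`math.comb` over a `Fraction`), returning the float nearest the exact
  rational; Benjamini-Hochberg is the step-up procedure with a monotone
  running minimum.

## Design decisions that were genuinely open

- **Direction of analysis.** Scoring "increased" vs "decreased" expression
  is done by two runs (`up`, `down`) with reciprocal weight transforms,
  preserving symmetry between directions, rather than by signed weights
  (the walk requires positive `w`).
- **Probe collapse.** Many-to-one identifier mapping keeps the value of
  largest magnitude per column (most extreme signal, sign kept); mean is
  available. Collapse happens before the walk — a node has one weight.
- **Ancestor propagation.** Gene annotations are propagated to ancestor
  terms before intersection (true-path semantics), toggleable. The level
  filter exists precisely because propagation inflates shallow terms.
- **Ontology root/levels.** A root is any term without parents, level 0;
  level is the shortest parent-chain from any root. The filter threshold is
  configurable so the base convention is harmless.
- **Term edge counts** are counted within the loaded network (stated in the
  output header), not within any external knowledgebase.

## Synthetic data: what it emulates and what it does not

`PlantedScenario` emulates a small perturbation study over an interactome:
a connected random network (spanning tree + uniform extra edges; a
preferential-attachment option reproduces hub-heavy degree distributions),
a connected module of genes elevated `module_weight/background_weight`-fold
in designated "hot" conditions, and replicated log-normal intensities
(default triplicates, 0.25 log2-units of replicate noise — typical
microarray scatter). Defaults: 200 nodes, 600 edges, 10-node module,
10-fold elevation, 2 conditions × 3 replicates.

It does *not* emulate: realistic interactome degree distributions or
clustering coefficients, correlated noise across genes, probe-level
artifacts, batch effects, or annotation noise (decoy terms are random gene
sets of matched size). Passing the planted-recovery benchmark therefore
shows the method chain is correctly implemented and sensitive at a
realistic signal-to-noise ratio — not that it will rank pathways correctly
in any particular real dataset.

Benchmark problem sizes (200 nodes / 600 edges / 20 seeds; 30 random
50-node graphs for the oracle and nullity checks) were chosen as the
smallest sizes at which topology bias, hub effects and decoy competition
are all present; the full verification run completes in seconds.

## Known limitations

- No edge-confidence weighting: all interactions are equally credible.
- One weight per node per condition; allele- or isoform-level resolution is
  out of scope.
- The level filter needs an ontology; GMT-only annotation sets must disable
  it (`min_level=0`).
- Mixed `and`/`or` filter expressions are not parsed; chain two filters.
- Heatmap images are deliberately not part of the contract; numeric tables
  and newick dendrograms are the exchange formats.
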