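# Methods

This document describes the model implemented by `flowcontrast`, its
parameters and their defaults, the synthetic-data generator used for
verification, and the numerical choices that make runs exactly reproducible.

## 1. Flow model

### 1.1 Context-specialized network

The input is a static, undirected protein–protein interactome and one
expression matrix (genes × samples, log2 scale) per phenotype. For each
phenotype independently:

- Every interactome edge whose two endpoints are both measured gets the
  weight `w = |Pearson r|` of the endpoints' expression across that
  phenotype's samples. Edges with an unmeasured endpoint are dropped, as are
  edges with a zero-variance endpoint (weight defined as 0). At least 3
  samples are required to compute a correlation.
- Edges with `w < cor_threshold` (default **0.5**, boundary inclusive: an
  edge at exactly the threshold is kept) are removed. The same interactome
  therefore yields a different weighted network per phenotype.
- Optionally, the network is first restricted to the *functional
  neighborhoods* of the sources: for each source, the top `(1 − snf)`
  fraction of measured genes ranked by `|r|` to that source (default
  `snf = 0.95`, i.e. top 5%), rounded up, plus the sources themselves.

### 1.2 Flow network construction

The weighted, undirected contextual network is turned into a directed
flow network over a super-source `S` and super-sink `T`:

- Each undirected edge `{u, v}` with weight `w` becomes two antiparallel
  arcs, each with capacity `w` and unit cost `(1 − w) + cost_floor`.
  High-correlation edges are wide and cheap; low-correlation edges are
  narrow and expensive. `cost_floor` (default **1e-4**) keeps every cost
  strictly positive, which rules out zero-cost cycles and guarantees that
  optimal flows decompose into simple `S → T` paths.
- `S → source` arcs carry the total `supply` (default **1.0**), split across
  the selected sources in proportion to `|log2 fold change|` (equal split
  when sources are supplied as a plain gene list). The split is done on the
  integer scale by largest-remainder apportionment so capacities sum exactly
  to the scaled supply.
- Every non-source node `v` gets a terminal arc `v → T` with capacity
  `epsilon_terminal × wdeg(v)` (weighted degree in the contextual network)
  and unit cost `terminal_cost` (default **1.0**). Nodes named in the source
  list get no terminal arc even if their allocated supply is zero, so
  sources never absorb flow.

**Why `epsilon_terminal = 0.02`.** The terminal capacity decides where flow
is *allowed* to stop. It must be small relative to typical edge weights,
otherwise flow exits at the first neighbor it reaches and intermediate
structure is invisible; and a node's total intake capacity
(`epsilon_terminal × wdeg`) must stay below the target-classification
threshold `target_fraction × supply` (default 0.05) for nodes of ordinary
degree, otherwise any well-connected intermediate is labeled a target merely
for existing. With `epsilon_terminal = 0.02`, a node needs weighted degree
above `0.05 / 0.02 = 2.5` — roughly three strong edges' worth — before its
terminal intake alone could reach the target threshold. That reserves the
"target" label for genes where flow genuinely converges through the network
rather than trickling out locally, while still letting every gene absorb a
small share so total delivery does not depend on a single sink.

### 1.3 Solving

All quantities are scaled by `integer_scale` (default **10 000**, minimum
100) and rounded once; capacities and costs are integers from then on. The
solver is successive shortest augmenting paths with Johnson node potentials
(Dijkstra on reduced costs), which yields an exact min-cost max-flow in
integer arithmetic: the maximum deliverable flow from `S` to `T`, and among
all flows of that value, one of minimum total cost. Per-gene throughput,
per-edge flow (net of antiparallel cancellation), terminal absorption, and
the objective are reported both as integers and de-scaled floats.

Exact integer conservation holds at every gene node: inflow equals outflow,
and total terminal absorption equals delivered flow.

### 1.4 Phenotype contrast

Given solutions for phenotypes A and B:

- **Flow difference** per gene: `flow_b − flow_a` on the union of genes
  (missing genes contribute 0). Swapping the phenotypes negates every value.
- **Roles** (disjoint, precedence source > target > router): *source* =
  selected source gene; *target* = terminal absorption ≥
  `target_fraction × supply` (default **0.05**, inclusive) in either
  phenotype; *router* = any other gene with nonzero throughput in either
  phenotype. Zero-throughput genes are unclassified.
- **Impact score** per gene: the mean of three normalized components —
  relative throughput change, relative change of flow over its incident
  edges, and its flow difference normalized by the maximum |flow difference|
  — each saturated to [0, 1].
- **Key edges**: an edge is *exclusive* to a phenotype if it carries flow
  only there; the *ratio* is the larger over the smaller scaled flow. An
  edge is key iff `ratio ≥ ratio_threshold` (default **5.0**, inclusive) or
  it is exclusive.
- **Prioritized subnetwork**: active sources, all targets, the top
  `top_k_routers` (default **20**) routers by |flow difference|, and
  endpoints of key edges.

### 1.5 Downstream stages

- **Source selection**: per-gene Welch t-test between phenotypes on log2
  expression, Benjamini–Hochberg correction; selected iff
  `q ≤ alpha` and `|log2FC| ≥ lfc_min`. A gene-list bypass skips the
  statistics and splits supply equally.
- **Enrichment (ORA)**: hypergeometric upper tail
  `P(X ≥ k)` via `scipy.stats.hypergeom.sf(k − 1, N, K, n)` computed within
  the measured reference universe, BH-corrected across sets.
- **Dependency integration**: a gene is flagged iff the *median* of its
  essentiality scores across cell lines is strictly below
  `dependency_threshold` (default **−1.0**; a median exactly at the
  threshold is *not* flagged). Flags are joined onto the role table.
- **Cross-dataset clustering**: gene × run flow-profile matrices (absent
  genes imputed as 0) are clustered by UPGMA (average linkage) on Euclidean
  distances, with deterministic tie-breaking; output as merge table and
  Newick string.

## 2. Synthetic-data generator

The generator produces a dataset with known ground truth for validation:

- **Interactome**: a Barabási–Albert preferential-attachment graph (default
  300 genes, attachment 2), giving the heavy-tailed degree distribution
  typical of PPI networks.
- **Planted genes**: the *target* is the highest-degree hub. The *router* is
  the lowest-degree gene not adjacent to the target, and the *sources*
  (default 10) are drawn outside the router's neighborhood. This placement
  is a design constraint, not tuning: module co-expression (below) is a
  shared latent factor, so *every* interactome edge between two module
  members is retained at high weight in phenotype B. A high-degree router
  would accumulate enough weighted degree for its terminal capacity alone to
  cross the target threshold (`wdeg > target_fraction / epsilon_terminal =
  2.5`), which would misclassify it by construction; a low-degree router
  with sources outside its neighborhood keeps `wdeg ≈ 1.8 < 2.5` with slack
  for one chance extra retained edge.
- **Expression**: baseline i.i.d. noise in both phenotypes; sources get a
  mean shift of `delta` (default 2.0) in phenotype B; the planted module
  (sources + router + target) shares a latent factor in phenotype B only,
  so rewired edges correlate at `rho_hi` (≈ 0.9) in B and ≈ 0 in A.
- **Rewired edges** (default): each source except the last two connects to
  the target; one source connects to the router; the router connects to the
  target. These edges are added to the interactome but only co-express in
  phenotype B.
- **Dependency scores**: Gaussian noise around 0 for most genes; the router
  (and any configured essential genes) centered below −1.

**Limitations.** The generator is a verification instrument, not a
biological simulator: expression is Gaussian rather than count-based,
co-expression inside the planted module is driven by a single shared factor
(so module edges not on the planted list also light up in phenotype B),
correlations outside the module are near zero rather than realistically
structured, and the interactome has no false edges or ascertainment bias.
Effect sizes (`delta = 2`, `rho_hi = 0.9`) are deliberately strong so that
recovery failures indicate implementation bugs rather than statistical
noise.

## 3. Numerical and determinism choices

- **Integer arithmetic.** One float → integer rounding happens at network
  construction; everything after is exact integer arithmetic. Conservation
  and the reported objective are exact, and results do not depend on
  floating-point summation order.
- **Largest-remainder apportionment** for supply splitting: integer
  capacities sum exactly to the scaled supply; ties broken by gene name.
- **Deterministic solver.** Dijkstra breaks ties lexicographically by node
  label; arc iteration order is fixed by sorted construction. Identical
  inputs and configuration give identical arc flows, not just identical
  objectives.
- **Seeded randomness.** All stochastic steps (synthetic generation) use a
  `numpy` `default_rng` seeded from the configuration. Output files are
  written with fixed column orders, fixed float formatting, and sorted keys
  in JSON, so a rerun is byte-identical; the manifest records SHA-256
  digests of the inputs.
- **Boundary conventions** are part of the contract and are tested:
  `cor_threshold` and `ratio_threshold` are inclusive (≥), the dependency
  median threshold is strict (<).

## 4. Design rationale

- *Min-cost max-flow rather than shortest paths or random walks*: maximum
  flow captures capacity-limited propagation through parallel routes, and
  minimizing cost among maximum flows makes the solution prefer
  high-confidence (high-correlation) interactions without forbidding weak
  ones. The result is a single, reproducible flow pattern per phenotype
  rather than a distribution.
- *Self-written solver with library oracles*: the solver's integer
  determinism and its per-arc flow reporting are part of the package
  contract, which off-the-shelf solvers do not guarantee; correctness is
  instead established in the test suite by comparing against an exhaustive
  enumeration oracle on small networks and against `networkx` on the same
  instances.
- *Established libraries elsewhere*: statistics (scipy, statsmodels),
  graph generation and I/O (networkx), and tabular handling (pandas) use
  standard implementations; tests pin their behavior with exact-arithmetic
  or textbook-formula oracles where precision matters (hypergeometric tail
  vs `fractions.Fraction` summation, BH vs the step-up definition, UPGMA vs
  brute-force average linkage).
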