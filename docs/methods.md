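# Methods

## The model

`netpolarity` analyses *polarised* directed networks: binary directed
graphs in which every node carries one of three roles — **input**
(where signals enter, e.g. sensory neurons), **inter** (intermediate),
or **output** (where signals leave, e.g. motor neurons).  The analysis
asks how efficiently signals propagate from the input side to the
output side when multi-step, possibly recurrent, pathways are taken
into account.

The primitive quantity is the exact count of *walks* between an input
node `i` and an output node `j`.  A pathway with `l` intermediate
nodes (a walk of length `l + 1`) is said to be at **propagation level
`l`**; walks may revisit nodes, so recurrent circuits contribute
heavily at high levels.  Counts come from powers of the adjacency
matrix: the number of level-`l` pathways is `A^(l+1)[i, j]`.  All
powers are computed in exact integer arithmetic — an int64 fast path
with a provable overflow bound, switching to Python big integers
beyond it — because counts grow exponentially with level and float64
silently loses exactness past 2^53.

The **channel connectivity matrix** at level `l` collects these counts
over all `n_in x n_out` channels (ordered input–output pairs) and
compresses their dynamic range:

    M(i, j)_l = log10( m(i, j)_l + b ),    b = 0.1

The offset keeps the logarithm finite on disconnected channels
(`m = 0` maps to −1) while perturbing connected counts negligibly.

Two summary degrees are derived per level:

* **Vertical propagation** `V_l = corr(M_l, M_{l+1})` — the Pearson
  correlation over all channel entries of consecutive levels.  It
  approaches 1 once the input→output pattern has stabilised: each
  further intermediate node then multiplies counts without reshaping
  the pattern.  If either matrix has zero variance the correlation is
  mathematically undefined; the package returns an explicit `None`
  marker (never a silent 0) and the experiment layer drops such points
  while counting them in an `n_undefined` column.
* **Horizontal propagation** `h(i)_l` — per input node, the fraction
  of output nodes reached by at least one pathway — and its mean
  `H_l` over inputs.  By default a channel counts as reached if it is
  connected at *any* level up to `l` (cumulative); the strict
  per-level variant is exposed by a flag.  The cumulative reading
  makes `H_l` monotone in the level and matches the interpretation of
  outputs that "have been" reached; the level-2 values it produces
  also agree with the reference values the package is calibrated
  against.

Level 2 (`V2`, `H2`) is the canonical per-network summary: at levels
3–4 both degrees saturate near 1 for most network families, while at
level 2 families still separate clearly.

`new_node_counts` quantifies recurrence directly: for each channel and
level it counts the intermediate nodes participating in the level's
pathways that were absent from all lower levels.  In recurrent
networks this mean drops toward zero with level even as pathway counts
explode — new pathways reuse old nodes.

## Synthetic network families

The generators reproduce the study conditions the propagation measures
are calibrated on.  Defaults match the *C. elegans* somatic
chemical-synapse connectome scale: 279 nodes, 2194 directed edges,
roles 88 input / 82 inter / 109 output.

* **Ring lattice (RL).**  2194 edges over 279 nodes is a non-integer
  7.86 per node, so a classic k-regular ring is impossible.  Every
  node sends `floor(m/n)` out-edges to its nearest ring neighbours,
  alternating sides (1st clockwise, 1st counter-clockwise, 2nd
  clockwise, ...); the remaining `m mod n` edges go to the
  next-nearest unused neighbour of seeded uniformly-drawn nodes.  This
  preserves locality and keeps out-degrees within one of each other.
* **Small-world (SW).**  The ring lattice with each edge *head*
  independently re-targeted with probability `p` (default 0.3) to a
  uniform node, redrawing on self-loops and duplicates; the tail stays
  fixed (the standard directed adaptation; at `p = 0` the network is
  bit-identical to the ring lattice with the same seed).  Edge count
  is conserved exactly.  At the default parameters the ensemble
  reproduces the reference directed path length (~3.2), Fagiolo
  clustering (~0.23) and small-worldness (~7.4–7.6).
* **Erdős–Rényi (ER).**  Each ordered non-self pair is an edge with
  probability 0.0283 (expected ~2194 edges); self-loops forbidden —
  as they are everywhere in the package, since the level semantics
  (counting intermediate nodes) presuppose loop-free adjacency.

Polarity schemes: uniformly random role sets of given sizes;
contiguous input/output arcs on opposite sides of the ring (inputs
~1/3 of the ring, outputs opposite, two ~1/6 internode arcs between,
ties toward the clockwise arc); and reassignment of existing roles —
`rand` (sizes preserved), `separated` (no module contains both inputs
and outputs; modules are greedily labelled input- or output-side by
decreasing size onto the needier side, with seeded retries),
`reversed` (inputs and outputs interchanged).

## Network statistics

* **Characteristic path length**: mean shortest directed path over
  reachable ordered pairs; unreachable pairs are excluded and their
  fraction surfaced (`full=True`), so results remain diagnosable
  against conventions that penalise disconnection.
* **Clustering**: Fagiolo's directed coefficient,
  `C_i = [(A+Aᵀ)³]_ii / (2[d_i(d_i−1) − 2d_i↔])`, averaged over nodes;
  zero-denominator nodes contribute 0.  On symmetric adjacencies it
  reduces to the undirected Watts–Strogatz coefficient.
* **Small-worldness**: `S = (C/L) / (C_ER/L_ER)` against a seeded ER
  ensemble matched on size and density (default 100 draws).
* **Modules**: Leicht–Newman directed modularity
  `Q = (1/m) Σ_ij [A_ij − k_i^out k_j^in / m] δ(c_i, c_j)`, maximised
  by seeded Leiden restarts (default 20) on the directed graph; the
  best partition is kept, scored by the package's own directed-Q
  implementation.  The optimiser differs from the spectral method the
  measure was introduced with, but the objective — the only thing the
  downstream analysis depends on — is identical.
* **Participation coefficient**: `P_i = 1 − Σ_s (k_{i,s}/k_i)²`, with
  `k` counting both in- and out-links (consistent with the total-degree
  hub ranking).  The modified form multiplies by `N_m/(N_m−1)` (0 when
  `N_m = 1`) so a uniformly spread hub scores exactly 1 even with few
  modules.  Hubs — the top total-degree nodes — classify as
  provincial (`P ≤ 0.30`), connector (`0.30 < P ≤ 0.75`) or kinless
  (`P > 0.75`); boundaries inclusive on the left class, ties in the
  ranking broken by node index.

## Hub planting

`plant_hubs` rearranges a network's links to endow it with `n_hubs`
(default 15) hubs of a chosen class while conserving node and edge
counts exactly.  The procedure is this package's own design:

1. Hub nodes are drawn uniformly at random, restricted (for provincial
   and connector classes) to modules large enough to supply the
   required number of distinct own-module partners per direction.
2. Each designated node is *replaced*: its existing links are removed
   and it is rebuilt to exactly `hub_total_degree` (default 40, in+out,
   added alternately) with partners drawn per class — provincial: own
   module only; kinless: uniform over the network; connector: 50/50.
   Other hubs are admissible partners until they reach their own
   target, so every hub ends at the target exactly.
3. Every link added beyond those freed in step 2 is paid for by
   deleting a uniformly chosen edge between two non-hub nodes, drawn
   from the wiring of the *opposite* locality to what the class
   creates: provincial and connector hubs (which anchor modules)
   consume inter-module edges, kinless hubs consume intra-module
   edges.  Planting thus re-routes background wiring through the hubs
   instead of shifting the network's intra/inter wiring balance twice
   in the same direction.

The replacement form (rather than augmenting the node's existing
links) keeps each hub's neighbourhood purely class-typed, which is
what gives the classes their distinct propagation signatures:
provincial hubs create strong within-module recurrence (raising `V2`
while concentrating flow, lowering `H2`), kinless hubs create global
shortcuts (raising `H2`), and connector hubs do both.  An augment-only
variant was evaluated and discarded because the background damage from
uniform edge harvesting outweighed the connector hubs' mixed
contribution, inverting their expected effect on `V2`.

`hub_total_degree = 40` was fixed once by calibration against the
reference level-2 values for the three classes and is not adjusted per
experiment; provincial module capacity bounds it from above (a module
must hold ~20 distinct partners per direction), which is why a larger
shared value is not attainable at the default network scale.

## Experiments

All experiments derive child seeds deterministically from a master
seed (`numpy.random.SeedSequence`) and are reproducible bit-for-bit.
Stochastic conditions run 100 seeded realizations by default and
report mean ± SD per level; deterministic conditions (a fixed network
with fixed roles) run once.  Hub-removal sweeps rank hubs once on the
intact network by total degree and remove them cumulatively without
re-ranking, recomputing `V2`/`H2` on each reduced network; removed
input/output nodes shrink the channel matrix, and the sweep stops
early (logged) if either side empties.

Problem sizes: acceptance-level computations use the full 279-node
networks with 100 realizations per condition; unit tests use smaller
instances (6–60 nodes) where the property under test is scale-free.

## Known limitations

* The synthetic families emulate the connectome's size, density, and
  small-world statistics, not its biology: no synaptic weights or
  signs (connections are 0/1 by construction), no gap junctions, no
  spatial or developmental constraints, and module structure arises
  only from ring locality.  Passing tests on these families therefore
  validate the measures and generators, not claims about any real
  nervous system; analyses of real connectomes require user-supplied
  edge lists.
* The hub-planting procedure is a reconstruction from first
  principles; its class effects land near, but not exactly on, the
  reference level-2 values (provincial `V2` ~0.77 vs 0.81, connector
  ~0.73 vs 0.80, kinless `H2` ~0.79 vs 0.85 at the default scale).
* The unreachable-pair convention in the path length (exclude and
  report) is one of several in use; the excluded fraction is surfaced
  precisely so users can reconcile against other tools.
* Walk counting is exact and dense; very large graphs (≫10⁴ nodes)
  would need the approximate/spectral shortcuts this package
  deliberately omits.
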