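# Methods

## The propagation model

The interactome is a heterogeneous graph `G = (V, E)` with typed nodes
(protein / biological function) and three edge types: protein–protein and
protein–function edges are undirected; function–function edges encode the
ontology hierarchy and are stored once, child → parent, but traversable in
both directions with separate bias weights (`ff_up`, `ff_down`). Self-loops
are dropped and duplicate edges collapsed at construction; walk semantics
on self-loops are not defined here and nothing downstream needs them. Node
positions 0..N−1 are assigned by sorting on `(node_type, node_id)`, so all
vectors are reproducible across runs and file round-trips.

The transition operator gives the move `i → j` the unnormalized weight of
its traversal type (`pp`, `pf`, `fp`, `ff_up`, `ff_down`) and normalizes
each row to sum to one. With all weights equal the walk reduces to an
unbiased random walk with restarts; the weights are deliberately exposed as
configuration because optimized values are dataset-specific and any
positive setting yields a valid operator.

A diffusion profile is the k-step iterate of

    p_{t+1} = (1 − r) Wᵀ p_t + r p_0,

with `p_0` uniform over the entity's resolved seeds. We define the profile
as `p_k` itself (the stationary visit distribution for large `k`), not a
time-averaged visit count: the iteration contracts at rate `1 − r`, so with
the defaults `r = 0.15`, `k = 1000` the distance to the exact fixed point
is below `0.85^1000 ≈ 10^{-70}` — far beyond double precision — and `p_k`
and the time average coincide to machine precision. The test suite checks
the iterate against an independent dense linear solve of
`(I − (1−r) Ŵᵀ) p = r p_0` to L1 ≤ 1e−8 on random graphs.

Dangling nodes (no outgoing mass) cannot arise from edge-list construction
— every stored edge is traversable both ways — but the iteration still
handles them: mass on a dangling row is redirected to the restart
distribution, conserving total probability exactly. A `self_loop`
alternative is available in `WalkParams.dangling` for operators built by
other means.

Numerical notes: everything is double precision and deterministic (no RNG
anywhere in propagation). Profiles must be nonnegative with
`Σ DP_i = 1 ± 1e−9`, enforced at construction. Cosine similarity of two
valid profiles is clipped into [0, 1] only against rounding noise; a
zero-norm input raises rather than returning a conventional value.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `r` | 0.15 | restart probability; larger = more local profiles |
| `k` | 1000 | iteration steps; any `k ≥ ~200` is converged for `r ≥ 0.05` |
| `bias_weights` | all 1.0 | per-traversal-type move multipliers |
| `top_fraction` | 0.25 (toy) / ~0.001 (large graphs) | joint-high quantile for mechanism subgraphs |

The neutral bias weights are a deliberate default: tuned weights from any
particular study are inputs (YAML config), not constants of this package.

## Ranking, elbow, validation

Entities are ranked by similarity, descending; exact ties break
lexicographically by entity id so rankings are order-independent and
reproducible. Entities with no target resolvable against the interactome
are excluded and reported, never silently dropped.

Elbow detection defaults to the **maximum successive gap** on the sorted
curve — the direct operationalization of "a substantial drop in similarity
score" — with ties going to the smallest index; a constant curve raises an
explicit no-elbow error rather than fabricating a cut. A chord-distance
("kneedle"-style) variant is available for sensitivity analysis; on raw
scores, both are applied to the unnormalized curve.

Fisher's exact test is computed with exact integer hypergeometric
arithmetic: all outcome probabilities under fixed margins share the
denominator `C(N, n)`, so tails are sums of integer numerators and the
returned float is the correctly rounded value of an exact rational. No
normal or chi-squared approximation is involved at any size used here. The
one-sided (`greater`) alternative is the default — the scientific question
is enrichment of beneficial molecules in the top group — and `two_sided`
(minimum-likelihood definition) is also exposed. Degenerate margins (an
empty beneficial column, for example) return p = 1 with a warning.
The test suite cross-checks against brute-force enumeration of every
feasible table for all margins with N ≤ 40 and against
`scipy.stats.fisher_exact`.

The overlap baseline is the binary-vector cosine `|T∩D| / √(|T||D|)`. Any
score strictly monotone in the intersection size would induce the same
"non-zero similarity" filter; cosine was chosen for consistency with the
diffusion comparison. Subset robustness reruns the full pipeline on a
reduced disease gene list and reports top-k membership overlap, plus the
count of molecules passing the non-zero overlap filter under each list.

## Mechanism subgraphs

The localized subgraph retains nodes that are in the top
`ceil(top_fraction · N)` of *both* profiles (stable tie-break by node
index, so retained sets grow monotonically with `top_fraction`), always
adds both seed sets, induces interactome edges, and keeps only connected
components containing at least one seed — the object of interest is the
pathway connecting molecule targets to disease genes, and a jointly-high
island touching neither is a stray cluster. The extraction is purely
score-driven; no manual curation step is modelled.

## What the synthetic generator emulates — and what it does not

`synthetic_data` builds a two-layer stand-in for a real multiscale
interactome at desk scale:

- protein layer: Barabási–Albert preferential attachment (heavy-tailed
  degrees), attachment parameter 1 by default, giving a connected,
  tree-like scale-free layer. The choice of attachment 1 is deliberate:
  with denser attachment the radius-2 neighborhood of any node set covers
  most of a 1000-node graph and planting local structure becomes
  meaningless. Real PPI networks are larger and have cycles and clustering;
  at this scale locality is the property worth preserving.
- function layer: balanced arity-3 rooted tree, edges child → parent,
  mimicking ontology hierarchy depth.
- memberships: per-protein Poisson(2) count of uniformly chosen functions.
- disease: 13 genes as a BFS ball around a random center — a compact
  pathway-like module.
- molecules: 100 entities with 6 targets each; 15 "planted" beneficial
  molecules draw their targets from within graph radius 2 of the disease
  ball, sampled with distance-decaying weights (1 / 0.02 / 0.005 for
  distance 0/1/2), i.e. planted molecules mostly hit the disease genes
  themselves with occasional first- and second-shell neighbors; the
  remaining 85 draw targets uniformly. Planted molecules are labelled
  benefit category `a`, background `d`.

The distance weighting is what makes the planted cohort behave like the
idealized "beneficial molecule": without it, uniform sampling over a
radius-2 ball in a small scale-free graph spreads targets so widely that
planted and background molecules are statistically indistinguishable. One
top-level `rng_seed` fans out to independent per-stage streams (graph,
memberships, disease, molecules), so each stage is reproducible on its own.

Passing tests on this benchmark demonstrate that the pipeline recovers a
planted local enrichment signal through propagation, elbow detection, and
exact-test validation at realistic noise levels. They do **not** establish
anything about a particular real interactome release: real target tables
are sparser and biased, real ontology semantics are richer than a balanced
tree, and real disease gene sets are not perfect BFS balls. Problem sizes
in the shipped tests (up to 1000 proteins, 100 molecules, 50 simulation
seeds) were chosen as the smallest scales at which the planted signal and
its statistics are stable.

## Known limitations

- No identifier mapping: gene symbols/accessions are opaque strings and
  must match between the edge lists, target tables, and gene lists.
- The elbow cut is a single global gap statistic; multi-modal score curves
  with several comparable gaps will resolve to the first, which may not be
  the scientifically interesting one (the chord variant helps diagnose
  this).
- The overlap baseline and the diffusion ranking are compared only through
  non-zero counts and top-k overlap; calibrating their score scales against
  each other is out of scope.
- Bias-weight optimization against treatment labels is intentionally not
  implemented; weights are inputs.
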