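# Methods

## Model

The pipeline treats a factor system as a weighted directed graph whose
edge weights are aggregated expert judgments.  Each of *m* experts scores
every ordered factor pair on a 5-point scale (0 none … 4 very strong);
the per-expert tables are summed elementwise into the direct-influence
matrix O (entries in 0..4m, zero diagonal).  The analysis assumes the
aggregate is meaningful as a cardinal intensity — no expert weighting or
consensus modelling is applied — and that indirect influence accumulates
multiplicatively along paths, which is what the Neumann construction
below encodes.

**Normalization.**  N = O / max_i √(aᵢ² + bᵢ²) with aᵢ, bᵢ the row and
column sums of O.  The denominator is the largest Euclidean norm of any
factor's (out-strength, in-strength) pair; on the bundled example it is
√(182² + 913²) = √866693 ≈ 930.9635, attained at the outcome factor.
This scaling keeps every entry in [0, 1] and, on all systems we generate,
the spectral radius of N below 1.  Convergence is nevertheless checked
explicitly: if ρ(N) ≥ 1 the total-influence stage raises a
`DivergenceError` rather than returning a matrix.

**Total influence.**  T = N(I − N)⁻¹, the closed form of
N + N² + N³ + …  Direct plus all orders of mediated influence.  The
diagonal of T is retained as computed (self-influence through cycles is a
real quantity in this model).  All downstream statistics use the
unrounded T; rounding happens only at report time (3 decimals for N, T
and centrality, 4 for TS/WS), matching the precision at which such
tables are conventionally published.

**Centrality statistics.**  Dᵢ and Cᵢ are the row and column sums of T;
Mᵢ = Dᵢ + Cᵢ (prominence) and Rcᵢ = Dᵢ − Cᵢ (net driver when positive,
net receiver when negative).  By construction ΣD = ΣC = ΣT and ΣRc = 0;
the tests enforce this to 1e-9 on every generated system.

**Intercept.**  λ = mean + σ over all n² entries of T, diagonal
included, with the *population* standard deviation (divisor n²).  The
adjacency cut is strictly greater-than: Aᵢⱼ = 1 iff tᵢⱼ > λ.  Ties at λ
do not occur on the bundled example; a tie would be excluded, which is
the conservative reading of a strict cut.  A user-supplied override can
replace λ when a different edge density is wanted.

**Reachability and loops.**  R is the stable Boolean power of B = A + I;
stabilization within n iterations is asserted, never assumed.  Loops are
the mutual-reachability classes of R (factors i, j with
Rᵢⱼ = Rⱼᵢ = 1), computed directly from R rather than from A so the loop
definition and the reachability matrix can never disagree.  The
condensation R′ over loop classes is checked to be antisymmetric.

**Skeleton.**  S′ = R′ − (R′ − I)² − I evaluated in Boolean arithmetic
(the square is a Boolean product, subtraction is and-not) — the
transitive reduction of the condensed partial order, keeping exactly the
covering edges.  Re-expansion onto factors threads each loop as a single
directed cycle through its members in factor order, and realizes each
condensed edge by the adjacency edge between members with the smallest
(source index, target index) pair.  Both choices are deterministic
tie-breaks; the factor-order cycle plus lowest-index attachment
reproduces the published skeleton of the worked example.  TS carries
tᵢⱼ on every skeleton edge.  WS marks *every* ordered pair inside a loop
with 1 — the full clique, not only the threaded cycle — so the loop
membership is recoverable from WS alone.

**Antagonistic hierarchy.**  For a residual system, Rset(e) is what e
still reaches, Q(e) what still reaches it, Tset = Rset ∩ Q.  The UP
(result-priority) extraction removes all factors with Rset = Tset per
round, assigning batches top-down from level 0; the DOWN
(cause-priority) extraction removes all factors with Q = Tset, stacking
batches bottom-up so its final batch is level 0.  All qualifiers in a
round leave simultaneously — there is no tie-breaking — and loop members
always qualify together, so loops are never split across levels.  Active
elements are factors whose level index differs between the two
partitions.  Layers: root = union of both bottom levels; result = union
of both extractions' levels 0–1, minus any factor already in root (the
subtraction only matters for degenerate two-level systems and keeps the
three layers a partition); intermediate = the rest.  The full causal
series renders a partition bottom-to-top with loop members bracketed,
larger loops first, free factors in factor order.

## Synthetic panels

`generate_panel` draws each cell of each expert table i.i.d. from a
categorical distribution over {0,…,4} using one seeded
`numpy.random.default_rng` stream per panel.  Defaults are 13 factors
and 27 experts — the design of the bundled study — with weights
(0.45, 0.25, 0.15, 0.10, 0.05) chosen so most pairs are judged absent or
weak and a few strong, resembling the sparsity of the real aggregate.
The generator deliberately omits inter-expert correlation, rater bias
and any structural prior on which pairs interact, so passing property
tests demonstrate the pipeline's algebraic correctness and determinism,
not robustness to realistic panel noise.

## Numerical choices

- Matrix inversion and the spectral-radius check use standard dense
  LAPACK routines via numpy; at n ≈ 13 conditioning is a non-issue
  (‖N‖ well below 1).
- Boolean closure is iterated squaring with an explicit n-step
  termination assertion; property tests compare it against an
  independent Floyd–Warshall closure and against networkx's SCC
  algorithm on random digraphs (up to 12 factors, 200 cases).
- The closed-form T is verified against 50-term partial sums to 1e-9
  elementwise for matrices with row sums ≤ 0.3.
- Comparisons against published 3-decimal tables use an absolute
  tolerance of 1.5e-3 (half-ulp of the printed precision plus the
  published tables' own last-digit rounding drift); 4-decimal skeleton
  values use 1.5e-4.
- An all-zero O is rejected at normalization with an explicit message;
  scaling O by a positive integer provably leaves N, and hence every
  downstream artifact, unchanged (tested).

## Degenerate inputs

Single-edge systems normalize that edge to 1.0 exactly.  Systems with
fewer than three extraction levels classify layers by the same rule,
with an empty intermediate layer.  An isolated factor (zero row and
column) forms its own singleton component and is extracted in the first
UP round.  Edgeless adjacency gives R = I, all levels collapse to one,
and exports still produce valid files with isolated ranked nodes.

## Problem sizes

The worked example is 13 × 13 and the whole pipeline runs in
milliseconds.  Randomized property tests use systems of up to 12
factors and a few hundred replicates, which keeps the full suite under
a few seconds while exercising every structural branch (loops of size
≥ 2, isolated factors, dense and sparse regimes).

## Known limitations

- The method is ordinal-in, cardinal-out: it treats summed 0–4 scores
  as ratio-scale influence intensities.  Nothing in the pipeline can
  detect whether that assumption fits a given panel.
- The mean + σ intercept is a single global cut; quantile or per-row
  thresholds are out of scope, as is MICMAC driving/dependence
  quadrant analysis and fuzzy/grey score aggregation.
- Loop re-expansion commits to one cycle through each loop; any cycle
  through the members preserves reachability, so the drawn intra-loop
  edges are a canonical representative, not a claim about which
  pairwise links are "real".
- Published 3-decimal tables constrain T to about ±5e-4 per entry;
  agreement at that precision does not certify more than roughly four
  significant figures of any derived statistic.
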