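# Methods

## Model and problem

A factor graph over discrete variables 𝒳 with factors 𝒜 induces
P(x) ∝ Π_a f_a(x_a).  Graphs may be unnormalized; every probabilistic
quantity is defined relative to the partition function Z, which exact
sum-product message passing provides together with variable and
factor-scope marginals.  Only cycle-free (forest) structures are accepted —
the bipartite variable/factor graph is checked with union-find at
construction — because exact message passing requires a tree.  Evidence
(observed variables) is imposed by zeroing the complementary slices of
every adjacent factor, which preserves structure and table shapes, is
idempotent, and commutes across disjoint variable sets.

An additive score S(x) = Σ_a g_a(x_a) assigns one real table per factor.
Two canonical scores are provided: the surprisal g_a = −log f_a (small
likelihood ⇔ large score) and the log-odds g_a = log(f_a^fg/f_a^bg) against
a structurally identical foreground model.  Significance is the null tail
z = P(S > t).  Because interesting z are 1e−6 and far below, all estimators
control *relative*, not absolute, error, and p-values are carried in log
space end to end (linear values are materialized only for display).

## Exact cumulants by moment-semiring message passing

Tilting the graph by α multiplies each potential by exp(α g_a); the result
is again a factor graph with the same tree, so the full exponential family
of S is reachable by message passing.  κ(θ) = log E[e^{θS}] and its
derivatives are computed exactly in one leaf-to-root pass whose message
payload is a moment triple per state.  In the numerically safe scaled
representation (log-mass z, mean part μ, second part q):

- product of independent parts: (z₁+z₂, μ₁+μ₂, q₁ + 2μ₁μ₂ + q₂);
- summation over states: log-sum-exp on the masses, mass-weighted averaging
  of μ and q.

Each factor contributes the triple (log f_a + θ g_a, g_a, g_a²) per joint
state.  At the root, κ(θ) = log Z̃(θ) − log Z̃(0), κ′(θ) = μ (the tilted mean)
and κ″(θ) = q − μ² (the tilted variance); disconnected components combine by
the product rule.  Zero-mass states propagate as −∞ log-mass with their
(irrelevant) score parts masked to 0, never as NaN; scores of ±∞ are
admitted only on zero-mass states, enforced at ScoreSpec construction.
The tilted variance is clamped to 0 only against rounding at the
10⁻⁹-relative scale; anything more negative raises.

## Tail estimators

**Normal approximation.**  p = Φ̄((t − m_s)/√v_s) with m_s = κ′(0),
v_s = κ″(0).  Standardization is by the standard deviation — the only
dimensionally consistent reading, and the one that agrees with the local
normal approximation inside the saddlepoint derivation.

**Saddlepoint approximation.**  Solve κ′(θ) = t by Newton–Raphson from θ=0
(or a caller-supplied warm start for threshold sweeps), safeguarded by a
bracket on θ that is bisected on overshoot and grown geometrically while
open; tolerance |κ′(θ)−t| ≤ 1e−9·max(1,|t|), at most 100 iterations.  The
equation has no solution outside the exact score range, which min/max-sum
message passing provides; thresholds outside (s_min, s_max) raise a
dedicated error.  The tail formula
p = exp(κ(θ) − tθ)·exp(θ²v/2)·Φ̄(θ√v) is evaluated through the scaled
complementary error function erfcx, so the product never over- or
underflows down to p ≈ 1e−300 (for θ√v < −26 the Mills product reduces to
its exact asymptote).

**Lattice correction.**  For scores on an arithmetic lattice with spacing a
(caller-declared; auto-detection by pairwise gcd is unreliable for float
scores and deliberately not attempted), the continuous formula
underestimates strict tails.  The implemented convention snaps the
threshold up to the smallest lattice point u > t (lattice anchored at
s_min), solves the saddlepoint at u, and multiplies by
K(θ, a) = a|θ|/(1 − e^{−a|θ|}) ≥ 1.  This approximates P(S ≥ u) = P(S > t)
and reproduces exact Binomial(1000, 0.01) strict tails to well under 1%
over p = 1e−3..1e−20, whereas applying K at t directly leaves >100%
error at lattice points.  The inclusive tail P(S ≥ t) is exposed as the
strict tail at t − ε·a.  The correction is off by default: log-odds scores
are generally not lattice-valued.

**Validity regime.**  The SA formula is a *p-value* method: for t below the
mean (θ < 0, p large) it is flagged (`theta_negative_warning`,
`p_above_validity_warning` for p > 0.1) rather than refused, and it is not
monotone in t there — the monotonicity guarantee and the tests cover the
regime t ≥ κ′(0).  Lower tails P(S < t) (e.g. conservation) are computed by
negating score and threshold, so they run in the same upper-tail regime;
the reported tilting parameter is mapped back to the original scale.

**Sampling estimators.**  Forward sampling draws exact configurations: the
root of each component from its marginal, then each factor's unassigned
scope variables jointly from the potential times the upward messages of
their subtrees, conditioned on the assigned neighbour.  All n draws advance
through the traversal as one vectorized batch from a single
`numpy.random.default_rng(seed)` stream in a fixed traversal order, so
estimates are bit-reproducible given (graph, n, seed).  IS weights are
computed analytically, w = exp(κ(α) − α·S(x)) — the normalizing-constant
ratio enters through κ(α) — and the tail estimate is the weighted
exceedance mean with a normal-theory CI on the weighted indicator
(truncated to [0,1]).  α defaults to the saddlepoint-guided value θ(t);
α = 0 reduces to naive sampling with unit weights (asserted, not assumed).
Default n = 10,000.

**Latent statistics.**  When only a subset of variables is observed (the
phylogenetic leaf column), statistics such as the posterior expected score
do not decompose over factors, so SA does not apply — but IS still does:
full configurations are sampled from the tilted graph, the statistic is
evaluated on each sample's observed restriction, and the full-data weights
keep the estimate unbiased.  The default statistic (posterior expected
score, one sum-product per distinct observation pattern, memoized) is
general; `PhyloModel.expected_substitutions` provides the same statistic as
a batched pruning pass (log-mass and conditional-mean messages with a batch
dimension) and is cross-checked against the generic route in the tests.

## Application builders

**Poisson-binomial.**  N disconnected binary variables with unary
potentials (1−p_n, p_n) and scores s_n·y (weights default to 1).  With
equal p the score distribution is exactly binomial, which scipy's binomial
tail verifies as an independent oracle.

**PWM.**  One 4-state variable per column (alphabet fixed A,C,G,T — JASPAR
row order), background as normalized unary potential, score
g_i(j) = log(f_ji/p_j).  Counts receive a pseudocount (default 0.01 per
cell — a convention to admit the zeros common in JASPAR PFMs, not a fitted
value); frequencies are used as given and must be positive.

**Higher-order Markov motifs.**  An order-r chain over A symbols is
compounded into a first-order chain over A^r context states, restoring
tree structure; pairwise factors are suffix/prefix-compatibility indicators
times the (per-position or homogeneous) next-symbol probabilities, and
incompatible transitions carry zero potential and zero score.  A PWM
re-expressed as a context-free order-1 motif yields the identical score
distribution (tested).  `window_scores` scores every offset of a batch of
integer-coded sequences for scan statistics.

**Scan maxima.**  P(max over offsets > t) ≈ 1 − exp(−M·p) with
M = L − k + 1; a warning fires when M·p > 0.5.  The approximation also
degrades for low-complexity (self-overlapping) motifs, which the package
does not detect.  The `--both-strands` CLI convenience doubles M and
averages in the reverse-complement matrix's single-match p — a documented
approximation, exact only for strand-symmetric backgrounds.

**Phylogenetics.**  A rooted Newick tree (dendropy) becomes one 4-state
variable per node, a uniform root prior, and one pairwise factor per branch
holding the JC69 transition matrix
(p_same = ¼ + ¾e^{−4μt/3}); branch lengths are expected substitutions per
site with μ defaulting to 1.  The per-branch score table is the
conditional expected number of substitution events
E[N | a, b] = M_ab/p_ab with M(t) = ∫₀ᵗ e^{Qs} C e^{Q(t−s)} ds and C the
off-diagonal part of the rate matrix, evaluated in the eigenbasis of Q (the
route is generic in Q; JC69 is the default instantiation).  Multiple hits
can cancel, so E[N|a,a] > 0 for all t > 0 — a fully conserved column still
has a positive expected count.  The conservation statistic of an alignment
column is the posterior expected total count given the leaves; conservation
is its lower tail (negative tilts), acceleration the upper.

## Synthetic data and oracles — what they do and do not show

The oracles are implemented independently of the message-passing code
paths: exhaustive enumeration by direct broadcasting over the joint state
space (capped at 2·10⁶ configurations), convolution of independent score
distributions with support merging at 1e−12 (near-equal float supports
would otherwise explode), and a JC69 CTMC path simulator that exploits the
state-independent total rate (Poisson event count, uniform jumps).

Fixture generators define the study conditions: random tree fixtures (gamma
potentials, standard-normal score tables) for oracle equivalence; balanced
trees whose edges carry the stationary channel (1−c)·π + c·I around a
seeded skewed π, with per-factor score vectors from a shared family
(`continuous`/`lattice`) or the exactly shared surprisal vector −log π
(`loglik`), making the coupling c a clean monotone variance-ratio knob; an
order-2, 16-bp motif with Dirichlet(0.5) foreground rows over a
stationary-started Dirichlet(10) homogeneous background; a synthetic
11-leaf tree of total length 13.2 substitutions/site (deep-alignment,
phyloP-like regime where identity columns are rare); and a synthetic
19-column PFM with Dirichlet(1) columns for the PWM benchmark, whose scores
are rounded to a 1e−3 lattice so the convolution support stays finite (the
same device TFM-style exact methods use).

These fixtures emulate the *distributional* features that drive the
estimators — heterogeneous event rates, informative motif columns, context
dependence, deep phylogenies — but not real-data complications: no
alignment errors or indels, no clade-specific rates, no motif
low-complexity structure, no empirical background composition.  Passing
tests demonstrate correctness of the algorithms under the stated models,
not calibration on any particular genome.

Replication protocols are scaled to desk size: reference simulations use
1e5 draws where the figure-scale experiments used 1e6 (CI half-widths
scale accordingly and are always computed from the actual draw count), the
scan study uses 1e4 sequences of 200 bp, the IS unbiasedness check uses
200 seeds × 1e4 samples, and the CTMC cross-validation 1e6 paths.  Where a
comparison pits SA's intrinsic ~10% accuracy on short discrete-ish motifs
against a reference CI, thresholds are taken deep enough in the tail that
the CI is wider than that scale (empirical q ≤ 1e−3 for the 1e5-draw
reference); the scan-maximum coverage check uses the interior of the
Poisson approximation's stated validity range p ∈ [0.005, 0.2], since at
its edges the clumping bias (large p) and compounded single-match error
(small p) sit at the CI boundary.  The IS-vs-naive CI-width contrast for
the phylogenetic tail is evaluated at the naive 1e−3 quantile at matched
n = 1000, where naive sampling still registers occasional hits; at moderate
p naive sampling is legitimately competitive because the full-data IS
weights vary within the hit region.

## Numerical choices

- Natural logarithm throughout; messages and p-values in log space;
  per-message scaling via log-sum-exp.
- Deterministic traversal: components rooted at their first declared
  variable, ties broken by declaration order; repeated runs are
  bit-identical.
- Joint-state tables are row-major with the last scope variable varying
  fastest; 0-based state indexing; the YAML interchange format serializes
  floats via repr for bit-exact round-trips.
- Newton tolerance 1e−9·max(1,|t|); enumeration cap 2·10⁶ configurations;
  convolution support merging at 1e−12.
- Arity-0 factors are rejected (no modelling value); unnormalized graphs
  are accepted everywhere.

## Known limitations

- Cyclic graphs are rejected; there is no junction-tree fallback.
- SA requires the score to decompose over factors — latent-variable
  statistics are sampling-only, as discussed.
- Third and higher cumulants (Lugannani–Rice-style corrections) are out of
  scope; the leading-order tilted-normal formula plus the lattice factor is
  the ceiling of
  analytic accuracy here.
- The normal-theory CI on weighted indicators can undercover when very few
  weighted hits dominate; the relative-SE diagnostic should be consulted
  before trusting a CI in that regime.
- `max_score_pvalue` does not model clumping beyond the Poisson assumption
  and does not detect low-complexity motifs.
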