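# Methods

## The fragmentation model

`fragspace` models unbiased, exhaustive fragmentation of a single transcript
of length `T` bp.  A *fragmentation pattern* is one placement of
non-overlapping fragments, with lengths drawn from an allowed set
`F_1 < … < F_k`, such that every gap — before the first fragment, between
fragments, and after the last — is strictly shorter than the smallest allowed
length `F_1`.  No further fragment can be inserted anywhere: the placement is
maximal.  The *pattern space* is the set of all such patterns, and the model's
central assumption is that **every pattern is equally likely**.  The model is
deliberately sequence-free: no GC, primer, or positional chemistry bias, no
isoform mixtures.

### Counting

The number of patterns satisfies, with `FP(l) = 1` for `0 ≤ l ≤ F_1` and
`FP(l) = 0` for `l < 0`,

    FP(l) = Σ_{i=0}^{F_1−1} Σ_{j=1}^{k} FP(l − F_j − i),     l > F_1

(`i` is the leading gap; the recursion is also valid at `l = F_1`, where it
agrees with the base case, and the implementation exploits this).  For
`T < F_1` the empty placement is the unique pattern: `FP = 1` with zero
coverage.  `pattern_count_table` computes the whole table in
`O(T·(k + F_1))` using a sliding-window sum of the inner sums.

### Profiles

Per-position expectations sum a per-fragment coverage vector `C` (length
`F_j`) over all fragments of all patterns:

- **SPP** (starting-point profile): `C = (1, 0, …, 0)`;
- **FCP** (fragment coverage profile): `C = (1, …, 1)`;
- **RCP** (read coverage profile): ones over the first and last `min(R, F_j)`
  positions, *added*, so paired reads overlapping mid-fragment count 2 and a
  fragment shorter than the read is covered at constant 2.

All profiles derive from one factorization: a pattern containing a fragment
of length `F_j` at position `p` splits bijectively into an exhaustive pattern
on the prefix `[0, p)` and one on the suffix `[p + F_j, T)` (the gap
constraints on both sides are exactly the pattern-space constraints).  Hence
the per-length start matrix

    M[j, p] = FP(p) · FP(T − p − F_j),

whose row sums give the raw SPP, and whose rows combined with `C_j` (via
difference-array sliding sums, algebraically identical to convolution but
`O(T)` per length) give FCP and RCP.  Raw SPP totals equal the number of
fragments over all patterns; dividing by `FP` would give per-pattern means,
and `normalize()` gives sum-to-1 profiles for comparison across models.

### Weighted pattern spaces

An empirical insert-size distribution is imposed through per-length weights
`W(F_j) = observed frequency / expected frequency`, the expected frequency
being each length's share of all fragments in the unweighted pattern space.
Two semantics are exposed, recorded in profile metadata:

- **contribution** (default): patterns remain equiprobable; each fragment's
  coverage vector is scaled by `W(F_j)`.  Row `j` of the start matrix is
  scaled by `W(F_j)`.  This is the arithmetic under which
  (expected frequency × weight, renormalized) reproduces the observed length
  distribution exactly, which is the defining identity of the weights.
- **pattern**: each pattern is reweighted by the product of its fragments'
  weights ("pattern mass" `G`, computed by the same recursion with
  `W`-scaled terms; `G = FP` when all weights are 1).  The start matrix
  becomes `G(p)·W(F_j)·G(T−p−F_j)`.  This is the semantics under which
  sampling is well defined, so the simulator always samples in pattern mode.

The distinction matters only for multi-fragment patterns; with all weights
equal the two coincide.  Whether an empirically weighted profile should
alter pattern probabilities or only contributions is genuinely open; both
are provided and the default follows the weight-times-frequency arithmetic
above.  Zero-weight lengths stay in the model: in contribution mode they
still shape which patterns exist even though their own coverage is silenced.

## Numerics

- The exact path uses Python arbitrary-precision integers end to end
  (object-dtype numpy arrays); `normalize()` on exact profiles produces
  `fractions.Fraction` values that sum to exactly 1.  At the package's
  standard scales (`T = 1000`, `F_1 = 100`) the integers are small enough
  that the exact path is also the fast path.
- A scaled floating-point path (`method="float"`) runs the same recursions in
  log space (log-sum-exp over the sliding window) so that counts beyond
  float range remain representable; exponentiation back to raw counts is only
  done where finite.  The two paths agree to ≤ 1e-9 relative error on every
  instance with `T ≤ 60` (tested exhaustively for several length sets; the
  observed agreement is ~1e-14).
- The brute-force oracle enumerates all patterns depth-first by
  (gap, length) ascending — deterministic ordering — and refuses `T` above a
  safety bound (default 25) unless overridden; oracle equivalence is asserted
  exhaustively for all `T ≤ 18` with singleton/pair length sets from
  {2, 3, 4, 5}.
- Coordinates are 0-based half-open internally; TSV output is 1-based,
  bedGraph 0-based half-open.
- Degenerate inputs: `T < F_1` yields the all-zero profile with a warning;
  all-zero profiles pass through `normalize()` unchanged (flagged, warned);
  duplicate lengths are rejected; ECDFs cannot be built from all-zero
  profiles.

## Simulation

`simulate_spp` runs fragmentation → PCR → sequencing with one seeded numpy
Generator consumed in documented order (fragmentation first, then
sequencing):

1. **Fragmentation.** Each of `M` molecules receives an independently
   sampled pattern, sequentially left to right: at remaining suffix length
   `l ≥ F_1` a (gap `g`, length `F_j`) pair is drawn with probability
   `W(F_j)·G(l−g−F_j) / G(l)`.  Because the candidate masses sum to `G(l)`
   by the counting recursion, the induced distribution over whole patterns
   is exactly uniform (unweighted) or proportional to pattern mass
   (weighted) — no rejection, no approximation.  Candidate tables are
   cached per suffix length; a vectorized batch path samples all molecules
   in parallel.
2. **PCR.** Every fragment's multiplicity is multiplied by exactly
   `2**cycles` (default 15, i.e. 32,768-fold): perfectly uniform, perfectly
   efficient amplification, with no duplicate-marking or efficiency model.
   Uniform amplification provably never changes normalized profiles.
3. **Sequencing.** `S` fragments (default 100,000) are drawn *without
   replacement* from the amplified pool — multivariate hypergeometric over
   fragment species.  numpy's kernel caps the pool at 1e9, so larger pools
   are sampled by drawing `S` distinct uniform item indices (rejection on
   duplicates, rare since `S` ≪ pool) and binning by species; the two
   routes are distributionally identical.  Sequencing depth per repetition
   is an explicit parameter; whether real pipelines resample fragments is
   left as a knob, with without-replacement as the fixed default.

### What the simulator does and does not emulate

It reproduces molecule-level sampling of the pattern space, ideal PCR, and
finite sequencing depth.  It does not generate read sequences, errors, PCR
bias, size selection, mapping artifacts, or multi-transcript mixtures —
passing tests therefore demonstrate the combinatorial sampling behaviour of
the model, not fidelity to any particular wet-lab protocol.  Likewise the
bundled bell-shaped histogram generator (truncated, discretized normal;
deterministic) emulates only the *shape* of real insert-size distributions,
not their noise or long tails.

## Molecule-number estimation

An observed SPP is sum-normalized and summarized as the ECDF of its `T`
per-position values — structural zeros included (positions that cannot hold a
start; whether to include them is open, and including them is the fixed
choice).  A reference set simulates `n_rep` repetitions at each candidate
molecule number `M` and **pools** all `n_rep · T` normalized values into one
ECDF per `M` (pooling, not averaging of per-repetition ECDFs, is the fixed
interpretation).  The distance between two ECDFs over the sorted unique
union `x` of their value lists is

    d = Σ_{i=1}^{n−1} (E_m(x_i) − E_d(x_i))² · (x_{i+1} − x_i),

with right-continuous step evaluation; the largest merged value contributes
no interval, exactly as the formula is printed.  The predicted `M` is the
grid argmin, ties broken toward the smaller `M` (conservative estimate).
The default grid is 43 log-spaced values from 50 to 50,000 inclusive (the
spacing of the grid is a design choice; it is overridable).

### Study conditions and problem sizes

The standard conditions used by the tests and the acceptance script are
`T = 1000`, single fragment length 100, `R = 100`, 15 PCR cycles, and
`S = 20,000` sequenced fragments per repetition.  Recovery is evaluated on
the grid {50, 150, 500, 1500, 5000} with 20 reference repetitions per grid
point and 20 test profiles per `M` — a deliberately reduced replica of the
full 43-point/100-repetition design that preserves its structure; at these
sizes the per-`M` ECDF distances separate by one to three orders of
magnitude and recovery is exact in ≥ 90% of trials (typically 100%).
Variability is summarized as the mean per-position standard deviation of
sum-normalized SPs across 20 repetitions, strictly decreasing over
`M ∈ {50, 500, 5000, 50000}`.

### Convergence floor

The normalized simulated SPP converges to the model SPP as `M` grows, but
with ~7.2 fragments per molecule over ~901 start positions the expected L1
fluctuation of a finite sample is `Σ_i sqrt(2 p_i (1−p_i)/(π n))/2 ≈ 0.02`
(total variation) at `M = 50,000`; the convergence test asserts strict
monotone decrease and a bound of 1.5× this statistical floor rather than an
arbitrary small constant.

## Known limitations

- Exact profiles at very large `T` with very many lengths are `O(T·k)` big
  integer work; the float path exists for that regime but raw (unnormalized)
  values beyond ~1e308 are only available in log space.
- Weights derived from a bell-shaped empirical distribution against the
  L-shaped pattern-space expectation grow enormously with length (the
  expected frequency of near-`T` fragments is combinatorially tiny); this is
  faithful to the definition but makes weighted profiles numerically
  dominated by the longest lengths.
- The estimator assumes the test profile was generated under the reference's
  exact conditions (same `T`, lengths, `S`, cycles); no model-mismatch
  diagnostics are provided beyond the per-`M` distance table.
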