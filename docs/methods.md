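# Methods

## The model

Rally outcomes of one match are coded 1/0 from the focal player's
perspective. The null model throughout is that outcomes are independent
Bernoulli(p) draws at the match's overall point-winning probability
p = wins/n. Both opponents' series are complements of each other, so every
statistic here is symmetric about 0.5 (DMA) or 11 (CP) under the swap;
analyses can be run from either side.

## Double moving average

A forward simple moving average of window N = 4 (backward-looking:
M_i averages rallies i−3..i) followed by a backward moving average of
M_i..M_{i+3} yields the DMA. Window 4 balances stability against
responsiveness for 11-point table tennis sets; other windows are supported
in code (the composed kernel is the triangular one of length 2N−1) but the
17-value support claims and the expected-distribution machinery are
specific to N = 4.

The composition is identical to the weighted kernel
(1,2,3,4,3,2,1)/16 over seven consecutive rallies. The printed form of
that kernel in the sports-performance literature omits the divisor; 16 is forced both
by equivalence with the two-pass composition and by the grid step of the
attainable values (0.0625 = 1/16). Both routes are implemented
independently (`double_moving_average` composes two box filters on integer
numerators; `dma_weighted` convolves with the kernel) and the test suite
asserts exact elementwise equality of their integer numerators — never a
floating tolerance, since all values are multiples of 1/16 and therefore
exact in binary floating point.

**Edge policy.** The DMA needs a full 7-rally neighbourhood, so it is
defined for rallies 4..n−3 ("valid-only", n−6 values per match); this is
the default everywhere because the 17-point support and the expected
distribution both assume full windows. A "shrink" policy (windows
truncated at the match edges, one value per rally) is available for
plotting complete match courses; its edge values leave the 1/16 grid and
are rejected by the grid-based tests. Boundary-touch counts can differ
between the two policies; reported counts use valid-only.

**Summaries.** Per match we report mean, sample SD (ddof = 1), IQR and
CV of the valid DMA values plus boundary-touch flags. Quartiles use linear
interpolation of order statistics (the common statistics-package default);
the convention is fixed here because the IQR of a 17-point discrete
distribution is sensitive to it and published descriptions do not state
one.

## Exact expected DMA distribution

Each of the 128 length-7 win/loss sequences receives probability
p^k (1−p)^(7−k) for its k wins — per-sequence weighting, not the binomial
pmf split across sequences, which is the reading that makes the
accumulated sums correct — and is mapped through the kernel. Zero-mass
support points are retained so all distributions share the fixed 17-point
grid. Invariants verified by tests: total mass 1, mean exactly p (the DMA
is a convex combination of Bernoulli(p) variables), and mirror symmetry
between p and 1−p. Published support listings of this statistic contain
"0.1825", which is not a multiple of 1/16; it is treated as a typo for
0.1875 = 3/16.

## Kolmogorov–Smirnov comparison

The observed empirical CDF (all n−6 valid DMA values) and the expected CDF
are evaluated only at the 17 grid points; d is their maximum absolute
difference. Ties on the grid are thereby handled exactly.

Two p-values:

* **asymptotic** — the standard one-sample K-S law at (d, n). Retained as
  the conventional screening value, but it assumes a continuous reference
  distribution and independent observations; the DMA violates both
  (discrete grid; overlapping windows autocorrelate consecutive values),
  making it conservative in practice.
* **monte_carlo** (recommended) — whole iid Bernoulli matches of the same
  n and p are simulated; each replicate's DMA, estimated winning
  probability and d are recomputed exactly as for a real match, and the
  p-value is the fraction of replicate d's ≥ the observed one.
  Re-estimating p per replicate matters: the observed d is measured
  against a reference law whose parameter was fitted to the same match
  (its mean matches by construction), so replicates must carry the same
  fitting step — the parametric-bootstrap analogue of the Lilliefors
  correction. Without it the test's null rejection rate collapses to ~0;
  with it, calibration lands near the nominal 5% (slightly conservative
  due to the discrete atoms of d).

## Kurtosis null and z-test

Excess kurtosis of the DMA distribution is the non-parametric fluctuation
measure: below-null kurtosis = flatter/bimodal = larger swings. The null
for a match with p and m = n−6 valid DMA values is simulated by drawing a
Bernoulli(p) stream of 10^6 outcomes, DMA-transforming it once, cutting
the 10^6 − 6 valid values into floor((10^6−6)/m) consecutive segments of m
values, and computing each segment's kurtosis; the observed kurtosis is
z-tested two-sided against the segments' mean and SD. At m = 100 this
gives 9,999 segments (the uncut arithmetic is 10,000; the DMA edge trim
costs at most one).

Design choices:

* **Segment length in DMA values, not rallies.** The stream's DMA series
  is segmented into pieces of exactly the match's valid-DMA count, so
  observed and simulated kurtoses are computed by the same formula on
  samples of identical size — exchangeable under the null. Segmenting raw
  rallies instead would make simulated segments systematically longer by 6.
* **Kurtosis formula.** Sample excess kurtosis with the standard
  small-sample bias adjustment (`variant="adjusted"`); a plain
  moment-based variant is selectable. The same variant is always applied
  to the observed match and the null segments, so the z statistic is
  internally consistent under either choice.
* **Zero-variance segments** (possible at p near 0 or 1) are dropped and
  counted; if more than 1% are dropped the run aborts, since the normal
  approximation of the null is then suspect. Nulls require 0 < p < 1 and
  at least 20 DMA values.
* **Caching.** In batch runs nulls are cached by (p, segment length) with
  per-null seeds derived from the master seed via `SeedSequence`, so the
  report is reproducible regardless of match order and a tournament with
  many same-length matches does not redo identical simulations.

Calibration under the iid null (p = 0.577, n = 100, the typical scale of a
best-of-seven match) is verified at 5% ± 3 binomial SE over 1,000
simulated matches for both tests; regime-switching matches (alternating
p = 0.8/0.2 in 25-rally blocks) are verified to push observed kurtosis
below the null mean and rejection rates far above 5%.

## Competition performance

The per-set score (SCP) of the set winner is 22 − loser's points for sets
won at 11, and for deuce sets won w:(w−2) decays toward 11:

* exponential (default): 11 + 2·1.25^−(w−11) — 12.6 at 12–10, 12.28 at
  13–11, strictly decreasing, always above 11;
* linear (sensitivity variant): max(11, 13 − 1.25·(w−11)) — shares the
  11–9 > 12–10 > 13–11 ordering but reaches the floor of 11 at 13–11, so
  it is only non-increasing beyond that.

The set loser receives 22 − SCP; match CP is the mean of the focal
player's per-set values, and the opponents' CPs sum to 22 by construction.
The exact algebraic form of the improved score as printed in the
sports-performance literature is typographically corrupted beyond
recovery; both variants here are reconstructions constrained to reproduce
every property the accompanying description states —
range [0, 22], 22 for an all-11–0 sweep, 0 for the swept player, symmetry
about 11, strictly decreasing dominance across 11–9, 12–10, 13–11, and the
printed constants 11, 22 and 1.25 with a ± structure around 11. The
equal-margin traditional score (11 ± margin) is kept as a baseline. The
two variants agree on all non-deuce sets and on every extreme; quantities
that depend on the deuce decay rate are variant-tagged in the output.

Note a consequence the worked example in the README shows: a match winner
whose wins were deuce sets can score below 11 — the improved score
measures dominance, not victory.

## Synthetic data

Generators emit rally series, not DMA series, so tests exercise the whole
pipeline:

* `iid` — Bernoulli(p); matches the null model of both tests. Calibration
  runs use p = 0.577 and n = 100, the typical winning probability and
  rally count of an elite best-of-seven match.
* `markov` — stationary two-state chain parameterised by (marginal p,
  lag-1 autocorrelation rho) with P(1|1) = p + rho(1−p),
  P(1|0) = p(1−rho); rho = 0 is exactly iid, and the parameterisation
  keeps p and rho orthogonal. This operationalises "streakiness".
* `regimes` — concatenated Bernoulli blocks of differing p: the
  advantageous / stalemate / disadvantageous phases used for power
  analysis. The standard power condition is alternating 0.8/0.2 blocks of
  25 rallies.

What the generators do **not** emulate: set structure and scoring states
(no serve rotation, no 11-point terminations, no deuce dynamics), player
fatigue or psychology, and any dependence between p and rally length.
Passing calibration on these generators shows the tests behave correctly
under their stated null and alternatives — not that real matches satisfy
the iid assumptions.

## Numerical conventions and problem sizes

All DMA arithmetic is integer-exact (numerators over 16); grid statistics
compare integer numerators. Randomness is PCG64
(`numpy.random.default_rng`) everywhere; batch runs derive all per-match
and per-null seeds from one master seed via `SeedSequence`. Monte-Carlo
p-values use the plain fraction of replicate statistics ≥ observed (ties
count, with 1e−12 slack for float rounding). Default sizes: 10^6-draw
kurtosis streams, 2,000 K-S replicates per match; the test suite's
calibration experiments use 1,000 matches with 400 K-S replicates each,
sizes at which the Monte-Carlo error is well below the tolerance bands
being checked.

## Known limitations

* The K-S and kurtosis flags are per-match at alpha = 0.05 with no
  multiplicity correction; batch reports carry the expected false-positive
  count so tournament-level flag counts can be judged against chance.
* The asymptotic K-S p-value is conservative here (discreteness,
  autocorrelation); use the Monte-Carlo method when the p-value itself
  matters.
* The kurtosis z-test assumes approximate normality of the segment
  kurtosis distribution; it is mildly skewed, which is why calibration is
  verified empirically rather than assumed.
* CP deuce decay beyond the constraints listed above is a modelling choice;
  conclusions sensitive to the exact decay rate should be checked under
  both variants.
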