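# Methods

## The ZML rank-probability model

The package's target distribution is the Zipf–Mandelbrot–Li law for an
alphabet of M symbols ranked by frequency,

    p(r) = C (r + β)^(−α),   α = log(M+1)/log(M),   β = M/(M+1),

the parameterization derived from Li's random-typing model (a source
emitting M letters and one space uniformly at random). Two normalizations
are exposed because they answer different questions:

- `zml_probabilities(M)` normalizes over ranks 1..M by explicit summation.
  This is the finite-alphabet target used by the partitioner, MaxIntel and
  LCEM, where exactly M symbols exist. No zeta-function approximation is
  involved; M never exceeds a few hundred in practice.
- `zml_word_law(M, n_ranks)` normalizes over the unbounded rank support
  with the Hurwitz zeta function, C = 1/ζ(α, 1+β) (exact; the sum
  converges since α > 1 for M ≥ 2). This is the law the *word* ranks of a
  random-typing source follow, whose vocabulary is infinite. Comparing
  random-typing word frequencies against the rank-M-normalized vector
  would be a category error: the M single-letter words are equiprobable by
  symmetry, so their top-M-renormalized distribution is flat and sits at a
  fixed total-variation distance (~0.18 at M = 4) from any M-rank power
  law, no matter how much text is generated. Against the unbounded-support
  law the measured top-4 TV at 10^6 characters is ≈ 0.04, and the
  full-rank TV (law renormalized over the observed vocabulary) decreases
  with text length.

α is undefined at M = 1 (log 1 = 0); the distribution is the point mass
regardless, and the stored exponent is set to 1.0 by convention.

Ranks are 1-based everywhere. `rank_divergence` is plain total-variation
distance, used as the convergence metric throughout.

## CDF-ZML partitioning

Interior breakpoint k is the empirical quantile (linear interpolation
between order statistics, `numpy.quantile`) of the cumulative ZML mass
Σ_{r≤k} p(r). Cells are half-open [U_i, U_{i+1}) with the last cell
closed and ties going right — the inclusive bounds of the usual
quantizer definition are ambiguous exactly on breakpoints, and a fixed
convention makes outputs bit-reproducible. Values beyond the training
range fall into the first/last cell rather than erroring, since the outer
breakpoints notionally extend to the training infimum/supremum. Rank 1 is
assigned to the leftmost cell; any other spatial arrangement is the
MaxIntel module's job. Training requires ≥ 10·M samples; a zero-width
cell (heavily tied data) raises a degenerate-partition error naming the
cell.

## MaxIntel

The intelligibility objective sums over *consecutive rank pairs*,
λc = Σ_{r<M} ψ_r (pos(r) − pos(r+1))², with ψ_r = p_ZML(r) by default and
an arbitrary weight vector accepted for generality. The adjacent-pair
form directly encodes the design goal — symbols nearest in probabilistic
rank are the most confusable and should be farthest apart in input
space; an all-pairs form would reward spreading already-dissimilar
symbols. The objective is invariant under spatial reflection, so optima
come in mirror pairs; determinism is obtained by lexicographic
tie-breaking.

Optimization is exhaustive for M ≤ 8 (at most 8! = 40320 permutations,
well under a second) and therefore exactly optimal there, verified
against the independent `brute_force_arrange` enumeration. For larger M
a deterministic heuristic seeds the arrangement by placing ranks
alternately at the two ends of the spatial axis (most probable first)
and refines it by best-improvement pairwise-swap hill climbing; the
result is a local optimum guaranteed no worse than the identity
arrangement. At M = 20 the optimized λc exceeds the identity value by a
factor of ~217.

The per-rank curve repeats the (M−1)-th term for rank M so both the
identity and optimized curves have length M.

## LCEM

Diagonal-covariance Gaussian mixture, standard E-step in the log domain
(`logsumexp`; no division by zero even in density tails). The M-step
updates means and variances by responsibility weighting, floors variances
at 10⁻⁶ of the total data variance to prevent singular collapse, and
blends the weights:

    w ← (1−η)·ŵ + η·z_match,

where z_match gives each cluster the ZML probability of its rank under
descending-ŵ order (stable sort). The two limits are exact: η = 0 is
plain EM (verified to agree with an independently implemented reference
EM to ≤ 10⁻⁶ in mean log-likelihood on identical initialization), and
η = 1 pins the sorted weights to the ZML vector. The blended form was
chosen over a multiplicative penalty because it makes both limits exact
and testable.

Initialization is k-means++ center seeding from the data, per-dimension
data variances, uniform weights — fully determined by the seed. Empty
clusters (total responsibility < 10⁻⁸·n) are re-seeded at the sample
with the lowest model density, keeping the alphabet size fixed. The
stopping rule is |ΔH(w)| < tol (default 10⁻⁵ bits, max 200 iterations):
the weight vector's entropy is the quantity whose convergence defines a
usable symbol alphabet.

The entropic error D(sorted(w) ‖ ZML) is *not* monotone early in a fit:
while clusters migrate, the likelihood-driven ŵ changes irregularly and
the error curve is visibly non-smooth, typically settling into a
monotone decrease within ~30–40 iterations on the M = 12 benchmark
(2-D, component separation 8 standard deviations, n = 10⁴, mixing
weights exactly ZML). Tests assert the monotone tail after a 30-iteration
burn-in with a 10⁻⁴-bit tolerance for fixed-point wobble, and final
sorted-weight TV ≤ 0.05 against the target. The log-likelihood trace is
finite at every iteration but likewise not asserted monotone.

## Entropy profiling and change detection

`plugin_entropy` is the plug-in estimator −Σ p̂ log₂ p̂ with 0·log 0 = 0.
It is negatively biased on short windows (≈ (M−1)/(2N ln 2) bits ≈ 0.006
bits at M = 5, N = 500), which is irrelevant for detection since only
relative changes matter; the estimator sits behind the
`entropy_estimator` hook so a bias-corrected variant can replace it.
Windows are non-overlapping, default 500 symbols, trailing partial
window discarded. `detect_change` flags windows with entropy below
mean − k·std (population std, default k = 2); a zero-variance trace
yields no flags.

Word-length symbolization lowercases, keeps maximal alphabetic runs
(digits and punctuation dropped), and bins lengths 1–3, 4–6, 7–9, 10–12,
≥13 into five symbols. The strict-inequality statement of these bins
leaves lengths 3, 6, 9 and 12 unassigned; closing each bin at its upper
gap is the smallest totalizing convention and is the one implemented —
a deliberate interpretation, flagged here.

## Synthetic-language pipeline

Spaces are the n most frequent symbols (ties broken by alphabet order):
the "do-nothing" operation of a behavior stream is its least surprising,
most frequent symbol, exactly as the space is in text. For multi-axis
data the intended use is one `detect_spaces` call per axis-direction
stream (six directions for triaxial data); the shipped univariate demo
uses the top-1 rule on a single symbolized stream, which is the
configuration actually demonstrated end to end. Words are maximal
non-space runs; ranking is by descending count with first-occurrence
tie-breaking; rank-r words map to the rank-r coarse POS category, with
surplus words collapsing into the last category so the rendering stays
total.

The packaged POS table (`data/pos_table_synthetic.csv`) is a *synthetic
stand-in* profile: eight coarse categories with plausible descending
probabilities and each category's archetypal most-frequent English word
(noun/"time", verb/"said", …). It is an input fixture, not a corpus
analysis; any user-supplied 3-column CSV (category, probability,
placeholder) replaces it. The translation output is deliberately
speculative — a way of viewing a possible narrative, with no claim of
semantic fidelity.

## Synthetic data generators

All generators take explicit seeds and are bit-reproducible.

- `random_typing_text(M, n_chars, seed)`: IID uniform over M letters and
  a space. Word lengths are geometric with ratio M/(M+1) (verified to
  TV ≤ 0.02 at 10⁶ characters).
- `two_author_text`: main words drawn uniformly over the five length
  bins (windowed entropy ≈ log₂ 5), inserts drawn from bin 1 (entropy
  ≈ 0), giving a separation far beyond the ≥ 3σ the detector needs.
  Defaults: 105,000 words — a full novel's length — carrying ten
  1,500-word inserts (3 windows each). The inserted fraction, 14%,
  matters: the mean − k·std rule can only flag a low-entropy class
  occupying fraction f < 1/(1+k²) of the windows (two-point-mixture
  algebra), so inserts must be rare enough to read as anomalies rather
  than a second mode — which is also what "short segments interspersed
  in a novel" means physically. Insert positions are seeded uniformly
  via a multinomial gap construction and never overlap.
- `sample_zml_mixture`: unit-variance Gaussians at lattice sites with
  spacing = `separation` (pairwise distance ≥ separation by
  construction), mixing weights exactly `zml_probabilities(M)`.
- `gen_accelerometer`: a hidden Markov state chain (geometric dwell,
  mean 1 s, floor 0.2 s) modulating a shared standardized AR(1) core
  (φ = 0.8) scaled and shifted per state, per axis — the simplest
  process with visible behavioral regimes at 100 Hz. It emulates the
  *structure* of triaxial accelerometry (regime switching, short-range
  autocorrelation, state-specific variance), not any real animal's
  dynamics; passing tests demonstrate the pipeline's mechanics, not
  ethological validity.

## Problem sizes

Tests and the acceptance script use the benchmark scales the methods are
demonstrated at: 10⁵ training/held-out samples for partition conformance,
10⁶ characters for the random-typing law, n = 10⁴ with five seeds for
the M = 12 LCEM benchmark, twenty 105k-word replicates for authorship
detection, and 10 s at 100 Hz (1000 samples) for the translation
pipeline.

## Known limitations

- The plug-in entropy estimator is biased on short windows; no
  bias-corrected or coverage-adjusted estimator is included.
- LCEM covariances are diagonal; no model selection over M.
- The MaxIntel heuristic beyond M = 8 is a local optimizer; only the
  ≥-identity guarantee is certified there.
- The POS mapping assumes coarse-category rank stability across
  languages and uses a synthetic rank table; translations are
  placeholder narratives, not decoded meaning.
- Orthographically extended ZML variants, infinite-support Zipf fitting
  and maximum-likelihood exponent estimation are out of scope.
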