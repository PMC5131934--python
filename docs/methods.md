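# Methods

## Ordinal symbolization

A real-valued series x₁…x_M is scanned with overlapping windows of D samples
spaced τ apart (stride 1), giving W = M − (D−1)τ windows.  Each window is
replaced by the permutation that sorts it ascending; ties are broken by
ascending temporal index (stable sort), so the map is total and
deterministic.  Patterns are indexed by the lexicographic rank of the sorting
permutation (identity → 0).  Two properties drive everything downstream:
the histogram is exactly invariant under strictly increasing affine maps of
the amplitudes, and it is sensitive only to the time ordering — which is why
the aggressive amplitude normalization of the preprocessing stage costs no
information.

Defaults are D = 5, τ = 1 (120 bins; a 5000-sample trajectory yields
W = 4996 windows, comfortably above the D! ≪ W requirement).  D = 3 or 4
produce coarse histograms and D = 6 (720 bins) leaves many empty bins at
this trajectory length; a warning is logged whenever W < 10·D!.

The lexicographic bin order matters only for the Fisher measure, which
differences neighbouring bins.  H and C are permutation-symmetric in the
bins; F is not, so the ordering is frozen in one place (`sigquant.ordinal`)
and documented as part of the contract.

## Quantifiers

With natural logarithms and N = D!:

- Raw Shannon entropy S[P] = −Σ pᵢ ln pᵢ (0·ln 0 := 0); normalized
  H[P] = S[P]/ln N ∈ [0, 1].
- Jensen–Shannon divergence J[P,Q] = S[(P+Q)/2] − S[P]/2 − S[Q]/2.
- MPR statistical complexity C[P] = (J[P,P_e]/J_max)·H[P], with P_e uniform
  and J_max = −½[((N+1)/N)·ln(N+1) − 2·ln 2N + ln N], the divergence of a
  delta from the uniform.  C vanishes identically at both entropy extremes.
- Discrete Fisher information F[P] = F₀·Σᵢ(√pᵢ₊₁ − √pᵢ)², F₀ = 1 when P is
  a delta on the first or last bin and 1/2 otherwise, normalizing F into
  [0, 1] (any delta scores exactly 1; the uniform scores 0).

Degenerate inputs are handled by construction: zero-probability bins
contribute nothing to entropy terms and enter Fisher differences as √0.

## Preprocessing

Raw signatures are min–max rescaled per axis into [0,1]×[0,1] (a constant
axis maps to 0 with a warning), then each coordinate is interpolated against
the normalized sample index u_i = i/(n−1) with a monotone (PCHIP) cubic
Hermite interpolant and evaluated at M = 5000 equispaced parameters.
Index parameterization — rather than wall-clock time or arc length — is the
minimal reading of "expand to a fixed length"; timestamps, when present in a
file, are parsed but unused.  PCHIP is chosen over a free cubic spline so
the interpolant cannot overshoot outside the unit square; endpoints are
pinned exactly (polynomial evaluation at the final knot can be one ulp off)
and residual round-off is clipped to [0,1].  Pen-up segments are not split:
each signature is one continuous pair of series.

## Stability indices

For a subject's genuine ensemble {P_j}, j = 1…k, with equal weights:

- Global: Δ = S[mean_j P_j] − mean_j S[P_j] ≥ 0 (concavity), reported as
  η = √Δ by default.  The square root makes the quantity a metric-like
  dispersion; the raw divergence is available via `apply_sqrt=False` and a
  normalized variant divides by ln N.  Entropies here are raw (S, not H).
- Local: ξ = mean_j F[P_j] − F[mean_j P_j] (Jensen–Fisher).  ξ is normally
  non-negative but the F₀ endpoint switch can in principle make it negative;
  such values are logged and returned as-is, never clamped.

Identical replicate ensembles short-circuit to exactly 0 (floating-point
averaging of identical rows would otherwise leave ~1e−16 residue whose
square root is a spuriously large 1e−8).

Sensitivity: η responds to replicate-to-replicate perturbation strength in
the small-perturbation regime and saturates (near 0.07 at these problem
sizes) once the fine structure of the 120-bin histograms has fully
decorrelated; beyond that point additional template jitter no longer
increases the divergence.  The monotonicity experiment in the test suite
therefore probes jitter scales 0.0005–0.008 at a fixed raw sample count,
isolating the jitter effect from length-driven dispersion.

## Typology and classification

Subjects are summarized by the sample mean and SD (n−1 denominator) of each
quantifier over their genuine signatures.  Clustering operates on one
quantifier at a time by default (the mean/SD pair of both coordinates,
a 4-D space), because each feature is analyzed independently; an
all-features mode exists.  Distances: Euclidean, Manhattan or Chebyshev.
Agglomerative clustering uses average linkage by default (unspecified
upstream; average is the common robust choice for automatic dendrograms,
and it is configurable); "levels" are merge heights as a percentage of
total tree height, and cuts are available by relative height or cluster
count.  Neighbor-joining trees are built from the same distance matrix and
midpoint-rooted for display; both trees export Newick.

The parallelepiped classifier stores per-class per-feature min–max boxes;
prediction returns the unique containing class, "unclassified" outside all
boxes, and resolves overlaps by smallest box volume, then declaration order
(an invented but deterministic tie rule).

## Verification

Per subject: sample n genuine vectors without replacement for training;
the held-out genuine are positives, all forgeries negatives.  The model is
a one-class SVM with Gaussian kernel k(u,v) = exp(−‖u−v‖²/(2σ²)), σ² = 10,
ν = 0.1 (a conventional one-class default), solver tolerance 1e−6 for
reproducible, order-invariant fits.  Because σ² conventions differ across
SVM tool chains, the alternative γ = 1/σ² reading is selectable.  Features
are already commensurate in [0,1]⁶, so no standardization is applied by
default (a z-scoring switch exists).

Metrics per repetition, averaged over 10 repetitions per (subject, n) and
then over subjects:

- ACC at the fixed threshold 0.  Note a structural small-n artifact: with
  ν·n ≤ 1 every training point is a bounded support vector and the
  positive-score region is empty, so ACC at n = 5 (and often 10) equals the
  all-reject rate; the trend across n remains informative.
- AUC as the Mann–Whitney rank statistic (ties ½) — the probability a
  random genuine outscores a random forgery.
- EER by sweeping the pooled score thresholds and linearly interpolating
  FAR and FRR between the adjacent thresholds bracketing their crossing.
  EER is a fraction in [0, 0.5]; reports also render it in percent, since
  both scales appear in the verification literature.

Every (subject, n, repetition) cell draws an independent substream of the
protocol seed, so reports are byte-reproducible.

## Synthetic cohort generator

The generator is a statistical stand-in for a licensed MCYT-style corpus,
not a biomechanical handwriting model.  A subject template is a sum of K
stroke components — Gaussian-envelope sinusoids in x and y on a
left-to-right drift — with K and the total oscillation budget drawn from a
planted complexity class: low (2–4 strokes, 4–9 cycles), medium (6–9,
16–28), high (12–18, 40–60).  The cycle budget controls the density of
direction changes and hence the ordinal entropy, which is what makes the
planted typology recoverable by entropy clustering.  Raw sample counts vary
per signature (300–1500), exercising the resampling stage the way variable
real capture lengths would.

Genuine realizations jitter template amplitudes, frequencies, phases and
drift at relative scale 0.03 plus tiny observation noise (1e−4 in template
units — small enough that structure, not noise, dominates the ordinal
spectrum).  Forgeries use jitter 0.12, a smooth monotone time warp
(deliberate reproduction) and additive hand tremor (amplitude 0.025,
60–100 cycles), which raises and disperses their entropy/complexity and
lowers their Fisher information relative to genuine signatures — the
qualitative pattern reported for real skilled forgeries.  (Fisher moves
opposite to entropy: tremor spreads probability across neighbouring
patterns, flattening the local gradient.)

Determinism: each subject consumes its own `SeedSequence` substream, so the
first k subjects of a cohort are identical whatever `n_subjects` is.

What the generator does *not* emulate: pen-up gaps, pressure dynamics,
within-session correlation between acquisition blocks, the strong X/Y
entropy coupling observed in real forgeries (tremor is drawn independently
per coordinate), or realistic letter shapes.  Passing tests on this cohort
demonstrate that the pipeline's statistics behave as designed under the
assumed structure — not that the method attains any particular accuracy on
real signature corpora, which require the licensed data.

## Problem sizes

The default cohort is 100 subjects × (25 genuine + 25 forgeries), matching
the protocol shape the method targets; feature extraction over the 5000
signatures and the full verification sweep complete in well under a minute
on one CPU.  Unit and property tests run on smaller cohorts (4–20 subjects)
chosen to exercise the same code paths quickly.

## Known limitations

- The Fisher measure depends on the frozen lexicographic bin order; other
  orderings give different (equally valid) values, so cross-study Fisher
  comparisons require matching conventions.
- The EER interpolation and a dense-grid threshold search agree only up to
  the step height 1/min(P, N) of the empirical FAR/FRR curves; with the
  protocol's 20–25 test scores per class, per-repetition EER has that
  granularity.
- ACC at the default threshold is degenerate for ν·n ≤ 1 (see above);
  threshold calibration is deliberately out of scope.
- `read_signature` accepts any equal-length coordinate pair (≥ 2 samples
  are required only at resampling); extremely short signatures produce
  heavily undersampled histograms, flagged by the window-count warning.
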