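# Methods

## Signal model and preprocessing

A dark-adapted pupil recording is modelled as a mm-scale diameter trace
sampled nominally at 240 Hz, in which blinks appear as runs of exactly zero
and tracker artifacts as impulsive outliers. Device timestamps are treated
as uniform at the nominal rate; sub-millisecond jitter is ignored because
the device reports a mean sampling frequency and every later stage operates
on a resampled uniform grid anyway.

Preprocessing runs deblink → Hampel → low-pass → baseline → percent change
→ spline compression. The ordering of the Hampel and low-pass steps is a
design choice (despiking before smoothing keeps spike energy out of the
filter); the baseline is taken *after* artifact cleaning so a spike cannot
masquerade as the first-minute maximum.

- **Deblink.** Interior zero runs are bridged linearly between flanking
  valid samples. Leading/trailing runs take the nearest valid value, since
  linear interpolation is undefined past the data edge. The operation is
  idempotent.
- **Hampel window.** `w = 0.44 · f_s/f_0` is generally non-integer
  (52.8 at the defaults); it is rounded to the nearest odd integer (ties
  upward) and clamped at 3 so the moving median stays centered. The
  outlier threshold is 3 scaled-MAD units (1.4826·MAD), the conventional
  Hampel identifier.
- **Low-pass.** 4th-order Butterworth at 2 Hz applied forward-backward
  (zero phase), the standard phase-preserving choice for slow physiological
  signals. Passband gain is within 1% below f_0/4.
- **Baseline.** Maximum diameter over the first 60 s. Recordings shorter
  than the window fall back to the full span with a logged warning rather
  than failing.
- **Compression.** Cubic-spline evaluation on a uniform 5 Hz grid
  (5 samples/s comfortably satisfies Nyquist for the 0.45 Hz band edge).

## Band decomposition

EMD uses cubic-spline envelopes through local extrema with two-point mirror
extension at the boundaries, Huang's SD sifting criterion (SD < 0.2), at
most 10 siftings per mode and at most 12 modes. Completeness
(`Σ IMF + residual = input`) holds to machine precision by construction.
The residual trend is discarded rather than counted toward LF: it carries
the slow drift that the baseline correction is meant to remove, not
autonomic oscillation.

Each IMF's dominant frequency is the argmax of a MUSIC pseudospectrum
(autocorrelation order 20, signal-subspace dimension 4, grid step
0.005 Hz over [0, 2.5] Hz). "Most of the power in the autonomic band" is
operationalized as *dominant MUSIC peak ≤ 0.45 Hz*; modes at or above
0.15 Hz go to HF (the boundary belongs to HF so the partition of
[0, 0.45] is exhaustive and exclusive), faster modes are discarded. A
subject whose decomposition leaves either band empty is reported as not
analyzable rather than silently zero-filled.

## Cross-recurrence quantification

Both band components are embedded with one shared (dimension, delay) pair
estimated from the percent-change series itself:

- **Embedding dimension** comes from the eigen-spectrum of the
  trajectory-matrix Gram matrix at the cap dimension (12): the normalized
  log10 spectrum is scanned for its last decrement larger than a plateau
  tolerance (0.5 decades, configurable), and the dimension one past that
  drop is returned. A spectrum with no such drop — white noise — returns
  the cap. The procedure is deterministic.
- **Delay** maximizes sample entropy (m = embedding dimension, tolerance
  0.2·SD, Chebyshev norm, self-matches excluded) over delays 1 …
  ⌊w/m⌋ with w the *unrounded* Hampel width 52.8; ties break toward the
  smaller delay. Both length-m and length-(m+1) template counts run over
  the common index set, so a constant series has entropy exactly 0.

The FAN cross-recurrence matrix marks, per HF-state column, the
k = round(0.20·N′) nearest LF states in Euclidean distance (distance ties
break toward the smaller index). This pins the recurrence rate at 20% by
construction — recurrence density is a constraint, not a measurement.
DET is the percentage of recurrence points on diagonal lines of length
≥ 2, with *all* recurrence points in the denominator (a cross-recurrence
plot has no identity line to exclude). ENT is the base-2 Shannon entropy
of the line-length histogram, in bits (the normative table is binned in
0.05-bit steps, which fixes the base).

## Cohort model

The cohort feature table has one row per subject: age, Epworth Sleepiness
Scale (0–24), ENT (bits), DET (%), mean percent change. The Gaussian
copula draws latent multivariate-normal vectors with the cohort's Pearson
correlation over all five columns (repaired to the nearest PSD matrix by
eigenvalue clipping at 1e-10 if needed), maps them through the standard
normal CDF, then through each column's empirical inverse CDF with linear
interpolation between order statistics; age and ESS are rounded to
integers. Margins can therefore never leave the observed range — the
simulation interpolates the cohort, it does not extrapolate it.

The Doornik–Hansen statistic standardizes each column, decorrelates with
the symmetric inverse square root of the correlation matrix, and sums the
squared D'Agostino skewness transform and the squared gamma/Wilson–Hilferty
kurtosis transform (conditional on skewness) over the transformed
coordinates; the null distribution is χ² with 2p degrees of freedom. The
test is invariant to affine rescaling of each column and its type-I error
at n = 100 is calibrated by simulation in the test suite.

The (1−α) prediction ellipse in the (ENT, DET/100) plane — DET rescaled by
1/100 so both axes are order 0.1–1 — uses axis lengths
`a_x = 2·sqrt(λ₁·(n−1)·p·F_{1−α}(p, n−p)/(n−p))` (λ₁ ≥ λ₂ the covariance
eigenvalues; a_y likewise with λ₂), orientation θ = atan2 of the leading
eigenvector folded into [0, π), and geometric semiaxes a_x/2, a_y/2. The
F *quantile* (not density) is the only reading that gives dimensionally
consistent axes. Normative DET intervals per ENT bin are the min/max of
the ellipse's y-section over each bin (computed from a densely sampled
contour; for a convex region these extremes lie on the boundary), rescaled
to % and rounded to integers; bins not intersecting the x-extent are
omitted.

Clustering operates on the same (ENT, DET/100) coordinates — already
commensurate, so no further standardization. L1 K-means assigns by
cityblock distance and updates centroids with the component-wise median
(the L1-optimal center), keeps the best of 20 restarts, reseeds a restart
whose update empties a cluster, and labels the lower-ENT centroid as
cluster 1. With 20 restarts the partition of the bundled cohort is stable
across seeds. Boundary points count as inside the ellipse. The comparison
battery is Box's M (χ² approximation, df = p(p+1)/2), two-sample Hotelling
T² (pooled covariance, exact F transform) and two-sided Mann–Whitney U
with midrank ties and the normal approximation (the half-integer U values
this convention produces are the reason it was chosen).

## Synthetic data

The generator emulates a 15-minute dark-condition session: diameter
= baseline·(1 + (drift + Σ LF sines + Σ HF sines + noise)/100), with a
slow half-period cosine drift (2% default), white Gaussian noise (0.3% of
baseline) plus an optional 1/f component, Poisson blinks (12/min, 200 ms,
written as exact zeros per the device convention) and Poisson spikes
(2/min, ±8%). Everything is determined by one seed. Default band content
is two LF tones (0.05, 0.10 Hz at 1.5%, 1.0%) and two HF tones (0.25,
0.35 Hz at 0.8%, 0.5%) — amplitudes in the low-percent range typical of
spontaneous pupillary oscillation. `generate_coupled_pair` provides a
controlled CRQA stress test: series B mixes a phase-locked copy of A with
a spectrum-matched phase-randomized surrogate, so coupling 1 gives
identical dynamics and coupling 0 gives independent dynamics with the
same spectrum.

**What the generator does not emulate.** Its band components are smooth,
band-limited (≤ 0.45 Hz) functions. Real pupil IMFs carry cycle-scale
irregularity from broadband physiological and device noise. This matters
for CRQA: the embedded trajectory of any smooth signal oversampled at
5 Hz moves slowly relative to a 20%-FAN neighbourhood, so recurrence
points chain into long diagonals and DET saturates near 100% with ENT of
several bits — for *any* choice of bandwidth, noise level or duration
(verified across 0.02–0.08 Hz bandwidths, noise up to the component
amplitude, 300–900 s). Observed cohort values (DET ≈ 30–57%, ENT ≈
0.7–1.1 bits) correspond to the opposite regime, scattered noise-like
cross-recurrences, which the suite exercises directly with independent
state sequences. Passing tests therefore demonstrate correct recurrence
*machinery* and correct qualitative ordering (coupled > independent DET;
periodic pairs near 100%), not that the generator reproduces the empirical
DET/ENT distribution of real recordings.

## Problem sizes and numerical conventions

The test suite runs subjects of 300 s (1500 samples at 5 Hz after
compression), where the full per-subject chain takes a few seconds; the
cohort stages use the bundled 26- and 100-row tables and run in well under
a second. Type-I-error simulations use 2000 replicates at n = 100.
Degenerate inputs fail loudly with typed exceptions (constant series, empty
bands, undefined sample entropy, singular covariances) rather than
returning sentinel values. Reported DET is in percent, ENT in bits, RR as
a fraction; the recurrence matrix is boolean with columns indexing HF
states.

## Known limitations

- The symplectic-spectrum plateau tolerance has no canonical value; 0.5
  decades is a configuration parameter, and smoothly decaying spectra can
  push the estimate to the cap.
- The embedding hyper-parameters are estimated once from the percent-change
  series and shared by both bands, so band-specific dynamics are not
  reflected in the embedding.
- The copula preserves pairwise Pearson structure and margins only; it
  cannot generate values outside the observed range, so extreme-tail
  behaviour of a larger population is not represented.
- Normative DET intervals inherit the integer rounding of the output
  table; sub-point precision would be spurious given two-decimal inputs.
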