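# Methods

`ewcomm` implements event-windowed communication (EWC) analysis for
parcellated electrophysiological recordings: inference of directed
inter-areal communication from lagged, past-conditioned dependence inside
windows anchored at salient signal events, estimation of oscillatory
measures inside the same windows, and statistics that relate the two —
surrogate-calibrated "principle matrices", per-region dominant-band reports,
and alignment to the principal functional gradient. This note documents the
model and procedure, the parameters that matter, the synthetic generator the
package is validated on, numerical choices, and known limitations.

## Event-windowed communication

A recording is an N x T matrix of region amplitudes at sampling rate SR
(Hz). It is split into consecutive 10-s epochs (`epoch_length_s`, trailing
remainder discarded) and each epoch is processed independently.

**Events.** Within an epoch, each region's signal is z-scored and a run of
consecutive samples with |z| > `z_threshold` (default 3) is one event whose
onset is the run's first sample. Collapsing runs to a single onset prevents
one burst from spawning hundreds of near-identical windows. Events are
discarded when a full window of past does not precede them or when the
window plus the region's largest outgoing delay would cross the epoch end,
so every analyzed window is interior to the epoch.

**Windows and delays.** For each event of a source region i, a window of
`window_s` = 1 s starts at the onset; for every structurally connected
target j a same-length window starts `delay_ij` later, where
`delay_ij = round(ED_ij / v * SR)` with ED the centroid Euclidean distance
(mm) and `v` = 10 m/s the assumed conduction velocity. Delays are rounded to
integer samples; zero is allowed. Temporal ordering is the only source of
directional asymmetry: with all delays zero the event-wise dependence is
exactly symmetric.

**Dependence.** Each window pair is scored by the partial correlation of the
source and target windows given both regions' immediately preceding
one-window past segments (regression with intercept on the two
sample-aligned past covariates, Pearson correlation of the residuals),
which discounts predictable internal dynamics; the p-value uses a
t-distribution with L - 4 degrees of freedom (L window samples). Event-wise
values failing a Bonferroni gate at `alpha_event` / N_events are set to
zero, where N_events counts all boundary-filtered events in the epoch across
regions (the number of tests performed in it). The epoch's communication
entry (i, j) is the arithmetic mean of gated values over source i's usable
events — zeros from non-significant events are data (inferred absence of
communication) and are included. The result is an N x N x M tensor with
structural zeros on the diagonal, on non-edges, and in zero-event epochs.

The partial correlation is the only implemented dependence measure; the
engine's interface would admit others (conditional mutual information,
distance correlation) but they are out of scope.

## Windowed oscillatory measures

Inside exactly the same window pairs:

- **Target relative band power.** Welch PSD of the target window (segment
  length SR/2, 50% overlap, Hamming taper, one-sided), band power as the
  trapezoidal integral over each band — theta 4-6, alpha 8-12, beta 14-24,
  low gamma 30-59, high gamma 60-80 Hz — divided by the trapezoidal
  integral over the full PSD support (0 to Nyquist). The five relative
  powers therefore sum to less than one. Note one property of this
  estimator worth knowing: a noise-free 10 Hz tone yields alpha relative
  power ~= 0.87, not 1, because Hamming-window leakage and the 2-Hz
  trapezoid grid put a nontrivial share of total power outside the band's
  grid points.
- **ISPC** (inter-site phase clustering, a.k.a. phase-locking value):
  |mean_t exp(i(phi_source(t) - phi_target(t)))| over the window, with
  phases from the Hilbert analytic signal of the band-passed epoch. Whole
  epochs are filtered (zero-phase Butterworth, order 4 per pass) before
  phase extraction so windows avoid filter edge transients; the target
  phase window sits at the delay-shifted position, mirroring the
  communication windows. Phases are wrapped; no unwrapping is needed since
  ISPC uses wrapped differences.

Both tensors are event-averaged per (source, target, epoch) and share the
communication tensor's zero pattern.

## Leakage correction

Source-reconstructed recordings carry instantaneous cross-talk between
parcels. When enabled (default), each epoch matrix is replaced by the
nearest matrix (Frobenius sense) whose rows are exactly uncorrelated at lag
zero: rows are written as an orthonormal frame times per-row scalings and
the two are alternated (orthogonal Procrustes update, then least-squares
scaling update) until the relative change drops below 1e-9 or 200
iterations. All regions are treated symmetrically; rank-deficient epochs
are an error naming the dependent rows. The correction is applied per epoch,
before event detection.

One consequence to be aware of: orthogonalization removes genuine coupling
that is close to zero lag. At v = 10 m/s, inter-centroid distances under
~100 mm give delays of a few samples, and low-frequency (alpha) coupled
components are then largely instantaneous and get suppressed together with
leakage. For validation runs on synthetic data — which contain no leakage —
the correction is therefore disabled; on real source-localized data it
should stay on, with the understanding that short-delay low-frequency
coupling is partly sacrificed.

## Principle matrices and the surrogate null

For each source region the epoch-concatenated communication row (restricted
to structural neighbours; a 1 x (degree x M) vector) is Pearson-correlated
with the matching concatenation of each of the 10 measures (5 power bands,
5 ISPC bands), giving the N x 10 principle matrix. Cells with fewer than 10
paired samples, or degenerate variance, are flagged missing.

Because communication and the oscillatory measures derive from the same
signal, their correlation contains a trivial component. The null: per
surrogate, per source, and per epoch, one random integer k in [0, L) is
drawn and every region except the source is cyclically shifted forward by
k; events are re-detected on the (unchanged) source; windows, gated partial
correlations, Welch powers and ISPC are recomputed on the shifted targets
through the same engine as the observed pass; and a surrogate principle
matrix is assembled. The cyclic shift preserves each series' marginal
distribution and circular autocorrelation and destroys only source-target
alignment. Because one shift is shared by all targets of a source within an
epoch (as in the original design), surrogate cells of a row are dependent,
and the null is correspondingly wider than an independent-samples Pearson
null — this is a feature: the observed row's cells share source windows and
are equally dependent.

Implementation note: the shift is applied as a circular index shift into
the per-epoch (already filtered) series rather than rolling the raw signal
and re-filtering. For a circular shift, filter-then-shift and
shift-then-filter coincide except for the wrap discontinuity that rolling a
non-periodic signal would itself fabricate; indexing avoids that artifact
and an S-fold increase in filtering work. All window statistics are
genuinely recomputed per surrogate.

Empirical p-values compare magnitudes, p = #(|s| >= |o|) / S, floored at
1/S. The one-sided form (s >= o on signed values) would trivially pass any
strongly negative observed correlation, yet negative dependencies (e.g.
communication preferring low-gamma targets) are scientifically meaningful
findings; the magnitude comparison treats both signs symmetrically. S
defaults to 1,000; validation experiments in this package run S = 100-200
and state so. Benjamini-Hochberg FDR at q = 0.05 is applied across regions
separately per measure column; non-significant correlations are set to
zero ("masked"). Group maps average masked per-recording matrices (masking
precedes averaging).

**Top-band reports.** Across >= 3 recordings, a one-way ANOVA over the five
band columns (separately for power and ISPC) identifies regions with any
band differentiation at alpha = 0.05; where significant, Tukey-Kramer HSD
on the top two bands decides whether a single band dominates
(`single_dominant`). Regions with a non-significant ANOVA carry no top
band. Observations are recordings; with multiple runs per subject the
caller decides what constitutes a recording.

## Functional gradients and spin tests

The principal gradient is obtained by diffusion embedding of a symmetric FC
matrix: per row the top 10% of connections are kept (never fewer than three
neighbours, so small matrices do not shred), rows are compared by cosine
similarity to form a non-negative affinity, the diffusion operator uses
anisotropic normalization alpha = 0.5, and the gradient is the first
non-trivial eigenvector of the Markov operator, scaled by its eigenvalue.
The sign is fixed to positive skew — an arbitrary but documented convention
making runs comparable. A disconnected affinity graph or a degenerate
leading eigengap is an error (no stable gradient exists).

Alignment between a masked principle-matrix column and the gradient is the
Spearman correlation over non-missing regions. Significance comes from a
spin test: random 3-D rotations of the unit-sphere parcel coordinates
(mirrored across hemispheres when labels are provided), nearest-neighbour
reassignment at parcel level (duplicates permitted), Spearman recomputed
per spin, p_spin = (1 + #(|null r| >= |observed r|)) / (1 + s). The +1
correction keeps p positive at finite spins. Spins preserve each map's
value multiset and spatial autocorrelation.

## The synthetic generator

`simulate_recording` produces recordings with known ground truth:

- **Baselines.** Per region, a sum of damped stochastic harmonic
  oscillators (second-order autoregressive resonators driven by white
  noise; pole radius exp(-pi * bandwidth / SR), unstable parameters are an
  error naming the band) — one per band, weighted by the region's band
  profile — over a 1/f background, normalized to unit variance. The default
  profile is resting-like (alpha-dominant). Each band oscillator is
  multiplied by a slow log-normal envelope (Gaussian-smoothed white noise,
  correlation time `slow_mod_tau_s` = 10 s, coefficient of variation
  `slow_mod_cv` = 0.5) emulating the waxing and waning of band power in
  real recordings; without it, band power would be statistically constant
  across 10-s epochs and power-tracking analyses would have nothing to
  detect.
- **Events.** Poisson-timed multiplicative bursts (~100 ms, cosine-ramped
  Tukey envelope, amplitude `event_amplitude` = 6 x baseline SD) injected
  into every region; onsets are recorded as ground truth. Bursts are
  spectrum-preserving (multiplicative), though their 100-ms transient
  slightly broadens single-window spectra.
- **Coupling.** For each directed coupled pair, a scaled copy of the source
  signal delayed by round(ED/v * SR) samples is added to the target
  (zero-padded, strictly causal). By default each structural edge carries
  one random direction at `coupling_gain`; an explicit directed gain matrix
  can be given. Coupling is feedforward (copies of baselines), so arbitrary
  gain patterns are stable.
- **Gating.** Optional per-sample modulation of the coupling gain,
  normalized to mean one so gated and ungated runs are power-comparable,
  with an exponent (default 1) that deepens modulation without changing
  its timing:
  - `target_power`: the target's gated-band Hilbert envelope, smoothed
    over 1 s so the gate acts at the timescale the windowed power
    estimates resolve;
  - `phase_coherence`: the sliding one-second phase-locking magnitude of
    the source-target phase difference in the gated band, |boxcar mean of
    exp(i * dphi)|. A raw per-sample cosine gate was rejected deliberately:
    it is symmetric under consistently-antiphase windows (gain near zero
    while phase consistency is perfect), so it would be structurally
    decorrelated from ISPC, which measures consistency irrespective of
    angle. The phase-locking gate embodies "communication via coherence"
    as ISPC operationalizes it.
  Under gating the transmitted copy is the source's band-limited
  (gated-band) component at unit SD — the gated channel routes the gated
  rhythm. A broadband copy would imprint the gain modulation on every
  band's ISPC (via the shared 1/f background), making the planted band
  unidentifiable in principle; band-specific routing is also what the
  coherence hypothesis describes.
- Measurement noise: additive white noise at `noise_sd` (default 0.2).
- All randomness comes from the config seed; identical seeds give
  bit-identical outputs. Gating uses acausal (Hilbert/boxcar) transforms of
  the baselines; the coupled copy itself remains causal (target at t
  depends on source at <= t - delay).

The gradient fixture (`make_gradient_fixture`) lays regions along a smooth
one-dimensional functional axis split into contiguous modules, with FC
decaying smoothly from the within-module to the between-module level plus
symmetric noise, and parcel coordinates along a jittered arc of the unit
sphere. Hard block structure is deliberately avoided: after top-10% row
sparsification its cosine affinity graph is exactly disconnected, which is
an error by construction, not a useful fixture.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analyses rely on: band-limited
rhythms with 1/f background, slow power modulation, transient endogenous
events, distance-proportional delays, directed coupling, and optional
power/coherence gating. It does not emulate volume conduction / source
leakage (the orthogonalization is validated analytically instead),
biophysical neural-mass dynamics, cross-frequency coupling, or
non-stationary artifacts. Passing validation here shows the machinery
recovers planted effects under the stated conditions; it does not certify
performance on real MEG, where effect sizes, leakage, and confounds differ.

## Validation experiment conditions

Chosen once, for desk-scale compute and identifiable planted effects, and
used by both the test suite and the acceptance script:

- **Directionality / common drive:** 4-node motif (true A->B at 4 ms,
  A->C at 20 ms, structural B-C edge silent, D isolated), coupling 0.5,
  events at 0.5 Hz, 300 s at 250 Hz, default profile, 50 seeds.
- **Null calibration:** 12 regions, density 0.3, coupling 0, otherwise
  default generator settings, S = 200 surrogates, 10 seeds; post-FDR
  admission rate and uniformity of surrogate p-values are checked.
- **Gating recovery (power and coherence):** 6 regions, density 0.6,
  280 s, bidirectional coupling 0.8 on every edge, events at 0.4 Hz,
  alpha-dominant profile (non-gated rhythms weak, so competing measure
  columns sit near their noise floors), slow-modulation CV 1.0, gating
  exponent 2, S = 100, leakage correction off (no leakage is simulated,
  and orthogonalization would suppress genuine near-zero-lag coupling),
  20 seeds. These choices make the planted effect strong enough to clear
  the honestly wide surrogate null at desk scale — because one cyclic
  shift is shared by all targets of a source per epoch, the null's width
  shrinks with the number of epochs rather than the number of cells, so
  recording length is the binding resource. Weaker planted effects degrade
  recovery smoothly.
- **Gradient machinery:** 40-region two-module fixture; module separation
  by gradient sign, spin-p uniformity under independence, self-alignment
  significance.

## Numerical choices

- Filters: Butterworth order 4 per pass, `sosfiltfilt` (zero-phase,
  effective order 8).
- Normal equations of the windowed regression are solved from moment
  matrices (3 x 3 per window pair), identical to explicit residualization
  to ~1e-12 and batch-friendly; degenerate residual variance (relative to
  the window's own scale) returns r = 0, p = 1.
- Welch band powers in the inner loop use a precomputed segmentation plan
  that reproduces `scipy.signal.welch` to ~1e-13.
- Bonferroni gate: strict inequality p < alpha/N_events keeps an estimate.
- BH-FDR via `statsmodels.multipletests`; ANOVA via `scipy.stats.f_oneway`;
  Tukey-Kramer via `statsmodels` `pairwise_tukeyhsd`; each is cross-checked
  in the tests against a from-first-principles oracle.
- Diffusion embedding: eigendecomposition of the symmetrized normalized
  operator; degeneracy tolerance 1e-8 on the leading non-trivial eigengap.
- The surrogate ensemble runs the shared engine in single precision
  (surrogate correlations are only needed to ~1e-4 for empirical p-values);
  the observed pass is double precision. The slow-modulation envelope is
  produced by Fourier-domain Gaussian smoothing (direct convolution kernels
  at 10-s correlation times would span tens of thousands of taps).
- Ties in nearest-neighbour spin reassignment resolve to the lowest index
  (argmin), deterministically.

## Limitations

- Partial correlation captures linear dependence only.
- The window-level t-test assumes white residuals. Band-limited rhythms
  lower the effective degrees of freedom far below L - 4, so the raw
  Bonferroni gate is markedly anti-conservative on realistic spectra (a
  sizable fraction of null cells pass it). Downstream inference must not
  rely on the gate alone; the cyclic-surrogate correction absorbs this
  bias, and the null-calibration experiment verifies that the post-FDR
  admission rate is controlled. The gate's conservativeness holds, and is
  tested, in its validity domain (white signals).
- The z-score event detector is vulnerable to within-epoch drift and to
  long high-amplitude stretches inflating the epoch SD.
- Event onsets of one underlying burst can fragment into several detected
  events when the oscillation crosses zero mid-burst; windows then overlap
  heavily and are not independent samples.
- The surrogate null conditions on the observed event catalog of the
  source; it does not model uncertainty in event detection itself.
- With a 10 m/s conduction velocity and centimetre-scale distances, delays
  are a few samples at 250 Hz; leakage orthogonalization then removes part
  of genuine low-frequency coupling (see above).
- Spin tests assume parcel centroids on a sphere; parcel area and boundary
  effects are ignored (parcel-level technique).
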