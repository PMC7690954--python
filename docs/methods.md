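# Methods

`gridspeed` re-implements the standard single-unit and LFP analyses of rodent
medial-entorhinal-cortex (MEC) spatial-coding studies — the kind used to ask
whether grid, head-direction (HD), and speed coding survive a disease model —
and validates every estimator against a synthetic-session generator with
known ground truth.  This note records the models, the constants, and the
choices made where the procedure was genuinely open.

## Synthetic sessions

**Trajectory.** Open-field exploration is an Ornstein–Uhlenbeck (OU)
velocity process with reflecting walls in an 80 × 80 cm arena, sampled at
25 Hz (camera rate).  The per-axis stationary standard deviation is set to
`mean_speed_target · sqrt(2/π)` so the stationary speed is Rayleigh with the
requested mean (default 8 cm/s), spanning roughly 0–25 cm/s — covering the
1–30 cm/s range every speed analysis assumes, with a few percent of time
below 1 cm/s to define immobility.  Velocity relaxes with a 1 s time
constant; a slow OU angular drift (0.5 s time constant, 0.8 rad/s SD) adds
path curvature without altering the speed distribution.  Track sessions use
a 1D arc-length OU process mapped onto the 150 cm linear or L-shaped
geometry.  Heading is emitted directly as the direction of motion; the
two-LED geometry is not simulated because heading is what downstream code
consumes.

**Units.** Firing models per kind, all expressed as rate functions
λ(x, y, hd, speed, t):

- *grid*: rectified sum of three cosine gratings at 60° separations
  (wave number 4π/(√3·spacing)), scaled so lattice vertices reach
  `base_rate`;
- *hd*: von Mises in heading, peak `base_rate`, concentration κ;
- *speed*: `max(0, base + slope·s)` (linear) or
  `base + slope·τ·(1 − e^(−s/τ))` (saturating, initial slope matched), with
  an optional sign flip for negatively modulated cells;
- *place*: isotropic Gaussian bump; *conjunctive*: grid × HD product;
  *untuned*: constant;
- theta modulation multiplies any rate by `1 + depth·cos(2π f_θ t)`.

Spikes are drawn by thinning a homogeneous Poisson process at an
analytically known rate bound, so constant-rate trains are exactly Poisson
(tested via count moments and exponential inter-spike intervals).

**LFP.** Theta is a sinusoid whose instantaneous amplitude and frequency are
affine in running speed (defaults: 0.15 mV + 0.01 mV per cm/s;
7.5 Hz + 0.045 Hz per cm/s, the healthy-coupling scale), with phase the
integral of instantaneous frequency.  Slow (40 Hz) and fast (90 Hz) gamma
components get their own amplitude slopes.  The background is pink (1/f)
noise at 0.05 mV RMS plus 0.01 mV white noise, chosen so the theta peak
stands above a realistic 1/f floor without swamping it.

**What the generator does not emulate:** theta-phase precession and
phase-locked spiking, conduction/sorting artefacts, non-stationary
representations (remapping, drift), border/object cells, and realistic
inter-animal variability.  Passing tests therefore show that the estimators
recover the statistical structure they target at realistic SNR, not that
they are robust to every pathology of real recordings.

## Preprocessing

Invalid tracking samples are linearly interpolated between the nearest valid
neighbours (edge gaps held at the nearest valid value) and flagged.  Heading
comes from the LED1→LED2 vector, zero along +x, counter-clockwise positive;
samples with fewer than two LEDs are discarded from the HD series, never
interpolated.  Running speed on a uniform binning is the first-to-last
displacement within each bin divided by the covered time span — robust to
25 Hz pixel jitter and never exceeding the raw polyline length.  Bins above
50 cm/s are flagged as tracking errors and excluded everywhere.  Speed is
binned at 0.5 s for LFP analysis (matching the spectral windows) and 40 ms
for single-unit speed scoring.

## LFP–speed coupling

Non-overlapping 0.5 s windows are analysed with a multitaper estimator
(DPSS, time-bandwidth NW = 2, 3 tapers — Chronux-style defaults), zero-padded
to 2¹⁴ points.  Band power is the mean in-band PSD averaged over tapers.
**Peak frequency is located on the first (most concentrated) taper's
spectrum**: with NW = 2 on 0.5 s windows the taper-averaged PSD is
flat-topped over the 2W = 8 Hz bandwidth and its argmax rides the lobe
edges, which compresses frequency–speed slopes toward zero; the first taper
is maximally concentrated at the spectral line and recovers a generative
0.045 Hz·(cm/s)⁻¹ slope within ~10%.  Windows are averaged in 1 cm/s speed
bins (1–30 cm/s), normalised by the mean power of immobility windows
(< 1 cm/s; absence of immobility is an explicit error), and summarised by
OLS on the occupied bin centres with the Fisher z of the Pearson r (|r|
clamped at 1 − 10⁻¹² so degenerate perfect fits stay finite).  Bands:
theta 5–12 Hz (matching the TMI band), slow gamma 30–50 Hz, fast gamma
60–120 Hz.  Raw (not log) power enters the regression.

## Single-unit metrics

**TMI.** Spike-train autocorrelogram at ±500 ms lags, 2 ms bins (exactly
symmetric by construction; self-pairs excluded).  The zero-lag bin is
reduced to the next maximal value, the function mean-subtracted,
Hamming-tapered, and Fourier-transformed at length 2¹⁶; power is the squared
transform divided by the autocorrelogram length (501).  TMI is the mean
power within ±1 Hz of the spectral peak inside 5–12 Hz divided by the mean
power over 0–125 Hz; TMI > 5 defines theta modulation.  Two measured
properties worth knowing: (i) a *perfectly periodic* 8 Hz train yields
TMI ≈ 3, not a large value — the comb spreads power over ~15 harmonics
inside the denominator band — whereas sinusoidally rate-modulated trains
(depth 0.8) give TMI ≈ 55; (ii) the homogeneous-Poisson null is
heavier-tailed than white noise (lag bins share spikes and correlate
harmonically), so ~8% of 10 Hz/600 s null trains exceed 5; the threshold
sits essentially at the null 95th percentile.

**Waveform class.** Half-width < 0.35 ms ⇒ putative interneuron, otherwise
putative excitatory (the boundary itself goes to excitatory); mean rate
> 10 Hz sets the fast-spiking flag.

## Tuning scores

**Rate maps.** 3 × 3 cm bins; spikes assigned to the nearest-in-time
trajectory sample (25 Hz resolution exceeds what 40 ms interpolation could
add); occupancy-normalised rate smoothed by a 2D Gaussian of σ = 1.5 bins
renormalised over visited bins only (unvisited bins stay undefined, never
zero).

**Grid score.** The spatial autocorrelation is the Pearson correlation of
the smoothed map with itself at every integer bin offset, computed over
mutually visited bins (FFT-accelerated) and masked below 20 overlapping
bins.  The central field is the contiguous region around zero lag with
r > 0.5; surrounding fields are local maxima with r > 0.1 lying within 0.9×
the map half-extent (extreme lags can overlap in a single row and correlate
at exactly 1.0, which would otherwise hijack the annulus).  The annulus runs
from the central-field edge to 1.25× the sixth-nearest peak distance; with
fewer than six peaks a flagged fallback (2× median peak distance, or half
the supported radius with no peaks) is used.  The map is rotated 30°–150° in
30° steps (bilinear) and g = min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀).  Ideal
hexagonal patterns score g > 1.3; isotropic patterns ≈ 0; square-symmetric
patterns < 0.

**Spatial information.** Skaggs SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) bits/spike on
the smoothed map over visited bins; invariant to rate scaling; exact on the
closed-form cases (uniform → 0, one of N equal bins → log₂ N).

**HD score.** 3° bins, occupancy-normalised, circularly smoothed with a
Gaussian window spanning 14° (σ = 3.5°, i.e. window = 4σ; the same window/σ
convention is applied to all three smoothing constants, since the source
procedure conflates them); normalisation precedes smoothing.  Score =
resultant mean vector length of the smoothed histogram.  κ = 2 von Mises
units recover R = I₁(2)/I₀(2) ≈ 0.698 within 0.05.

**Speed score.** Rate and speed in 40 ms bins, each smoothed with a 500 ms
Gaussian window (σ = 125 ms); bins kept where smoothed speed ∈ [2, 30] cm/s
and the 1 cm/s speed bin holds > 0.5% of the session; score z = atanh(r).
Zero-variance series give an invalid (flagged) score, excluded from
classification.  Speed-relationship form compares OLS fits of the 1 cm/s
tuning curve against speed and against log speed (a saturating rate is
nearly affine in log speed); the sign is the sign of r.

## Shuffle null and classification

Each shuffle forward-shifts all spikes by one uniform draw in
[20 s, T − 20 s], wrapped modulo T — preserving count, mean rate, and the
circular ISI multiset.  At least 250 shuffles per unit (fewer triggers a
warning); draws are seeded per (global seed, unit, shuffle index) so nulls
are exactly reproducible.  Scores pool across the units of a group (the
"global distribution"), with per-unit pooling available in configuration.
Grid/SI/HD use the one-sided 95th percentile; speed is two-sided (5th/95th).
A unit is "spatially modulated (non-grid)" only when SI passes and the grid
criterion does not.  Units passing two or more of {grid, spatial non-grid,
HD, speed} are conjunctive; none, unclassified.  On untuned cohorts each
rule flags at its nominal rate (≈5% one-sided, ≈10% two-sided; exact
binomial check in the acceptance suite).

## Controls

Split-half: metrics recomputed independently on the two wall-clock halves;
undefined halves are flagged missing.  Downsampling: Bernoulli thinning at
retention 1/k over a log-spaced factor grid spanning 1–100 (default 10
factors × 3 seeds at acceptance scale, 20 × 10 available), with the shuffle
threshold recomputed from the thinned trains at every factor.  Synthetic
grid units stay above threshold until mean rates fall well below 0.1 Hz.

## Group statistics

Proportion tables use the uncorrected Pearson chi-square (this convention
reproduces the published statistics from their printed counts exactly);
score distributions use Mann–Whitney U (min(U₁, U₂) reported by default;
tie-corrected p, exact for small tie-free samples) and medians with IQR;
paired comparisons use the Wilcoxon signed-rank normal approximation with
zeros dropped and degenerate inputs (fewer than two nonzero differences)
returning p = 1.

## Problem sizes

Desk-scale defaults, chosen once: null calibration uses 100 untuned units
sharing one 10-minute session's behaviour (as units of one recording do)
with 250 shuffles each; parameter recovery uses 50 independent 20-minute
sessions per cell class; LFP coupling uses 20 coupled plus 10 uncoupled
10-minute signals; TMI discrimination uses 100 modulated and 100 unmodulated
10-minute trains; downsampling uses one 20-minute grid unit, 10 factors,
3 thinning seeds, 250 shuffles per factor.

## Known limitations

- The estimator suite is validated on synthetic sessions; the study's
  real-data medians, U statistics, and per-genotype thresholds require the
  original recordings and are out of scope.
- TMI's threshold-5 rule has a measured ~8% false-positive rate on
  homogeneous Poisson trains (see above); it is a fixed published constant,
  not a calibrated null percentile.
- Grid-score values depend mildly on annulus construction; the fallback
  annulus is flagged so borderline units can be audited.
- Track sessions keep 2D coordinates; no linearisation is applied before
  speed scoring.
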