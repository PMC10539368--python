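# Methods

This note records the models behind each pipeline, the defaults that
matter, the numerical choices, and what the synthetic generators do and do
not emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Widefield imaging chain

**Acquisition model.** Trials are 2.5 s with a 0.5 s pre-stimulus period.
The two illumination wavelengths are interleaved at 60 Hz, so each channel
runs at 30 Hz after de-interleaving, with a half-sample (1/60 s) timing
offset between channels, recorded in the trial-set metadata. Raw frames
default to 880×800 pixels (7.5 µm pitch) so that 4×4 binning yields 220×200
pixels at ~30 µm — binning is plain block averaging, which conserves the
global frame mean exactly and scales the stored pixel pitch.

**Hemodynamic correction.** The calcium-insensitive 405 nm channel carries
the same multiplicative blood-volume artifact as the 465 nm channel but no
calcium signal. Per pixel, `scale = mean_t(465)/mean_t(405)` and
`corrected = 465 − scale·405`. The subtraction direction preserves positive
stimulus responses (scaled-405-minus-465 would invert them while cancelling
the same artifact). The corrected stack fluctuates about zero by
construction, which would leave F₀ ≈ 0 and ΔF/F undefined; the session
pipeline therefore adds back the per-pixel temporal mean of the 465 nm
channel before computing ΔF/F — a pure offset that restores the baseline
fluorescence level without reintroducing the artifact. Channels are paired
frame-by-frame (nearest sample); the half-sample offset leaves a residual
below 0.5 % ΔF/F that averages out over trials with random hemodynamic
phase. Pixels with a zero 405 nm mean are masked and logged.
Single-wavelength sessions skip correction (`correct=False`).

**Filtering.** `preprocess_trace` applies a least-squares linear detrend,
then a second-order Butterworth high-pass at 0.01 Hz and low-pass at 10 Hz,
both forward–backward (zero phase, so latency estimates are unbiased; the
effective magnitude response is the squared single-pass response). A 0.01 Hz
corner at tens of Hz sampling places the filter poles so close to z = 1 that
direct double-precision filtering is unstable; for such extreme corners the
sub-cutoff baseline is instead estimated on a decimated copy of the series
(where the corner is well conditioned), interpolated back, and subtracted.
The session pipeline leaves this preprocessing off by default: on a 2.5 s
trial epoch the high-pass has nothing to remove beyond the (already
subtracted) linear trend, while detrending a window dominated by the
response would bias the baseline. It is intended for long, drifting
recordings.

**ΔF/F and metrics.** F₀ is the mean over the 500 ms window immediately
before the stimulus; ΔF_t = (F_t − F₀)/F₀. On the trial-averaged ROI trace:
peak = max post-stimulus ΔF/F; latency = time from stimulus to the peak
sample; duration = time from stimulus onset to the first post-peak sample at
or below 20 % of peak (ties broken by first crossing; traces that never
return are censored at the trial end and flagged); AUC = sample sum of ΔF/F
from onset through the duration endpoint (units ΔF/F·samples — a dt-scaled
integral is a trivial rescale and deliberately not the default);
normalized AUC = AUC/peak. Active area max-projects the ΔF/F frames from
stimulus to peak and counts pixels above the projection mean + 2 SD
(mean + 2 SD, rather than 2 SD about zero, keeps the threshold meaningful
for projections with a nonzero floor), converted by the squared pixel pitch.
Non-positive peaks mark the trace non-responsive. ROI masks are inputs; when
absent, the pixel with the largest trial-averaged response is used.

## Section-image profiling

Chromogenic images are inverted to signal-positive before analysis.
Background subtraction uses the rolling-ball algorithm
(`skimage.restoration.rolling_ball`; radius 300 px for cortical-depth ISH,
50 px for fos sections), clipped at zero. Depth profiles average the ROI
across the tangential axis, split the depth axis into n near-equal
contiguous segments (boundaries at ⌊b·L/n⌋), and report per-bin means; the
knockout-vs-control comparison uses 10 bins and per-bin log₂(test/control),
the electroporated-vs-contralateral comparison uses 100 bins with a single
log₂ fold-change of the mean over the L4 bin range. Zero-control bins are
flagged NaN rather than propagated. The B2–C2–D2 row profile uses 30 bins
by default (the bin count is not prescribed anywhere; 10 per barrel is fine
enough to resolve the three barrels) and normalizes to the mean of the bins
falling in the C2 interval (middle third by default). Fos ratios use raw
ROI means for intensity and cell counts inside circular ROIs; registration
(C2 centering, common crop) is the caller's responsibility, mirroring
landmark-based alignment. Group heatmaps binarize each image with Otsu's
threshold (the concrete reading of "automatic thresholding") and average.

**Directional shift test.** Per-gene mean log-fold-changes are tested with
a one-sample signed-rank statistic against a shifted null (±0.1), one-sided
in the stated direction. The null distribution is exact for n ≤ 25: a
dynamic program over all 2ⁿ sign assignments of the |d| midranks (doubled to
integers), validated in tests against full enumeration. Zeros are dropped
(Wilcoxon convention) with a warning; all-zero input returns p = 1. The
hollow/septa family correction (Holm) is applied by the caller. A
two-sample rank-sum has no single-sample shift null of this form, which is
why the one-sample statistic is the implementation.

## Connectivity indices

IOC divides each region's presynaptic count by the starter count, making
brains with different labeling efficiency comparable; it is equivariant
under joint rescaling of counts and starters, and additive over child
regions. Regions are opaque string ids — atlas registration happens
upstream. Counts are assumed to exclude starter neurons. Per-hemisphere
tables are kept separate; pooling is a caller decision. Double-label
percentages are 100·(double-positive)/(transfected) per section, densities
are labeled count per ROI area; zero denominators flag the section missing.

## Photostimulation input maps

The grid is 15 depth rows (pia → white matter) × 28 columns at the default
site spacing; laminar borders map layer names to half-open row ranges (L5
split into L5a/L5b when borders provide it) and the home column is a
half-open column range. Event detection low-pass filters the trace
(1 kHz), finds contiguous runs below −threshold (default 3× the
pre-stimulus baseline SD, floored at 1 pA so noiseless traces have a finite
threshold), keeps events whose onset falls inside the 150 ms post-stimulus
window, and reports absolute peak amplitudes. An optional early-latency
veto (e.g. 0–7 ms) discards direct somatic responses; it is off by default
since recorded cells are assumed pre-screened. Site sums are order-invariant
by construction; binning averages per-site sums per layer, inside vs
outside the home column, so the total map sum equals the
count-weighted sum over bins. One sweep per site is assumed.

## Behavior

A bout counts toward interaction time when the animal is in the 4 cm × 4 cm
zone and makes whisker-directed contact, and the bout is not excluded
(climbing, pass-through). Overlapping valid bouts of one texture are merged
so time is not double-counted. The NTD index (novel − familiar)/total is
antisymmetric under label swap, scale-invariant, and bounded in [−1, 1];
it is computed on the test segment only (the A-vs-A pre-test is scored
separately, never pooled).

## Mixed models and the bootstrap test

The binomial model is y_ij ~ Bernoulli(logit⁻¹(b₀ + β·group_i + u_i)),
u_i ~ N(0, σ²), with neuron-level rows clustered by animal — the modeling
unit is the neuron, not an animal-level aggregate. The marginal likelihood
integrates each animal's intercept by adaptive Gauss–Hermite quadrature:
25 nodes by default, re-centered at the per-animal posterior mode with its
Laplace curvature (modes by Newton iterations, warm-started between
optimizer evaluations). The likelihood is maximized by Nelder–Mead over
(b₀, β, log σ) with a refinement pass; log σ is floored at log 1e-6, and
fits with log σ below log 1e-4 are flagged as boundary (σ = 0) fits, where
the model collapses to plain logistic regression. Standard errors come from
the observed information (numerical Hessian); at the σ boundary the full
Hessian is singular and the fixed-effect block is inverted with log σ held
fixed. Agreement with an independent reference implementation (lme4::glmer,
nAGQ = 25) is pinned in the test suite to ~1e-4 on a frozen dataset, and
estimates are stable to doubling the node count to within 1e-4.

The linear model y_ij = b₀ + β·group_i + u_i + ε_ij profiles the fixed
effects and residual variance out in closed form for each variance ratio
θ = σ²/τ² (Sherman–Morrison inverse of I + θJ per cluster), leaving a
bounded one-dimensional search over log θ plus an explicit θ = 0 boundary
candidate. ML (not REML) is used throughout so likelihood-ratio statistics
are valid.

The parametric bootstrap simulates B datasets from the fitted *null* model
(new random intercepts each replicate), refits null and alternative, and
uses the likelihood ratio as statistic: p = (1 + #{LR* ≥ LR_obs})/(B + 1),
never zero, with granularity 1/(B+1). Defaults are B = 4999 for the
binomial model and B = 999 for the linear model (the corresponding p-value
floors are 0.0002 and 0.001). Bootstrap refits use warm starts from the
null fit, a reduced node count, and loosened optimizer tolerances — the LR
statistic needs far less precision than the reported estimates. Replicates
that fail to refit are dropped and counted, with a warning beyond 5 %.
Type-I error calibration is checked in the acceptance suite on the linear
model (its near-closed-form fits make 200 runs × B = 199 feasible); the
floor identities are exercised for both models.

Pooled log-odds (the σ = 0 closed form) uses a +0.5 continuity correction
per cell for degenerate proportions, with a warning. Welch's t uses
Satterthwaite degrees of freedom; Holm or Benjamini–Hochberg adjustment is
applied across the caller-specified family, and pairs with zero variance in
both groups are flagged rather than corrected.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of spec + seed (bit-identical reruns,
checked) and returns a ground-truth sidecar that serializes to JSON.

* **Widefield** movies share a multiplicative hemodynamic sinusoid between
  channels (1 Hz default, random phase per trial — a stand-in for cardiac/
  respiratory blood-volume oscillation), scale the channels by (1.0, 0.8)
  gains, and add the stimulus-locked transient only to the 465 nm channel:
  instantaneous rise at onset, exponential decay (τ = 0.5 s, a GCaMP6f-like
  constant), Gaussian spatial footprint, amplitude 0.03 ΔF/F over a
  baseline of 1000 counts with Gaussian read noise (SD 5). The step-onset
  single-exponential shape is chosen so every response metric has a closed
  form. Not emulated: optics/PSF, vascular anatomy, motion, photobleaching,
  shot-noise scaling, or spiking dynamics — so passing recovery tests shows
  the chain is correct under its own assumptions, not that real movies are
  this clean.
* **Barrel images** place Poisson numbers of Gaussian-spot cells uniformly
  in circular barrels on a 3×3 grid over an optional linear background
  gradient. No somata shapes, no staining texture.
* **Tracing counts** are independent Poisson draws per region; **behavior**
  bouts choose the novel texture with probability p (expected index
  2p − 1) with exponential durations and texture-independent contact/
  exclusion flags; **morphology** outcomes follow exactly the GLMM above;
  **EPSC grids** inject fast-rise/exponential-decay inward events at known
  sites and latencies into Gaussian noise.

## Problem sizes in tests and acceptance

Simulated widefield sessions in the test and acceptance suites use reduced
48×48-pixel frames (binned to 12×12) with the full 60-trial, 2.5 s, 30 Hz
structure and the default amplitudes: per-pixel recovery does not depend on
how many pixels surround the response, so the field size is purely a
problem-size choice. GLMM recovery uses 100 cohorts of 20 + 20 animals × 20
neurons; bootstrap calibration uses 200 null cohorts at B = 199 on the
linear model. The acceptance script averages 20 cohorts per mixed-model
design and runs the binomial bootstrap once at B = 4999 with 5 quadrature
nodes.

## Known limitations

Single random intercept only (no crossed effects, random slopes, REML, or
Bayesian fits). Rolling-ball equivalence to ImageJ's implementation is
approximate. No automatic barrel segmentation, cell detection, atlas
registration, or motion correction — coordinates, counts, ROIs, and
registered images are inputs. The linear-mixed bootstrap with very few
clusters (3 per group) has a heavy-tailed null LR distribution; its p-value
floor is then not reliably attainable even for large true effects, and the
acceptance report shows the honest value.
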