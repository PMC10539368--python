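# barrelquant

Quantification pipelines for rodent barrel-cortex experiments. The package
is aimed at labs measuring how layer-4 circuitry responds to whisker input
— widefield calcium imaging through a cranial window, c-fos/ISH section
imaging, monosynaptic rabies tracing, laser-scanning photostimulation in
slices, and whisker-guided texture discrimination — and at the clustered
statistics those experiments need. Every analysis has a matching
synthetic-data generator with known ground truth, so the full chain can be
validated end to end without any imaging data.

## What it computes

**Widefield imaging** (`barrelquant.widefield`). Interleaved dual-wavelength
movies (calcium-sensitive 465 nm, calcium-insensitive 405 nm) are spatially
binned 4×4, optionally detrended/band-filtered (0.01–10 Hz, second-order
Butterworth, zero phase), and hemodynamically corrected per pixel:

    scale(y,x) = mean_t F465 / mean_t F405
    corrected  = F465 − scale · F405

Both channels carry the same multiplicative blood-volume artifact, so the
subtraction cancels it while the GCaMP transient survives. ΔF/F₀ uses the
500 ms pre-stimulus mean as F₀; trial-averaged ROI traces yield the response
peak, peak latency, duration to 20 % of peak, AUC (sample sum over the
response), normalized AUC (AUC/peak), and active cortical area (pixels above
mean + 2 SD of the stimulus-to-peak maximum projection, × pixel area).

**Barrel-map sections** (`barrelquant.barrelmap`). Rolling-ball background
subtraction; cortical-depth intensity profiles in 10 bins with per-bin
log₂(test/control); 100-bin radial profiles and the L4 log₂ fold-change of
electroporated vs contralateral hemispheres; B2–C2–D2 row profiles
normalized to the principal (C2) barrel; outside/inside fos⁺ cell and
intensity ratios; group heatmaps of Otsu-thresholded images; and an exact
one-sided signed-rank test of a location shift beyond ±0.1.

**Connectivity** (`barrelquant.connectivity`). Index of connectivity for
rabies tracing, IOC = presynaptic neurons in a region / starter neurons,
region ratios such as VPM/POm, and CTB double-label percentages and
densities.

**Photostimulation maps** (`barrelquant.slicemap`). Inward-current events
whose onset falls within 150 ms of photostimulation are detected per site of
a 15 × 28 grid; summed peak amplitudes give the input map, which is averaged
per layer inside vs outside the recorded cell's home column.

**Behavior** (`barrelquant.behavior`). Novel-texture-discrimination index
NTD = (novel − familiar)/(novel + familiar) over valid interaction bouts
(in-zone, whisker contact, non-climbing).

**Clustered statistics** (`barrelquant.stats`). Neuron-level binary outcomes
clustered within animals are modeled as a logistic GLMM,

    y_ij ~ Bernoulli(logit⁻¹(b₀ + β·group_i + u_i)),   u_i ~ N(0, σ²),

fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
(25 nodes); numeric per-section outcomes use the analogous Gaussian
random-intercept model fitted by profiled ML. Group effects are tested by a
parametric bootstrap of the likelihood ratio: data are re-simulated from the
fitted null, both models refitted, and p = (1 + #{LR\* ≥ LR_obs})/(B + 1),
so the smallest attainable p is 1/(B+1) (0.0002 at B = 4999, 0.001 at
B = 999). Utilities: pooled log-odds ratios, Welch's t with Holm or
Benjamini–Hochberg correction.

## Worked example

```python
import numpy as np
from barrelquant import synthdata as sd, widefield as wf, stats as st

# a 60-trial dual-wavelength session (reduced 48x48 field, 2.5 s trials,
# 0.5 s pre-stimulus, 30 Hz/channel, hemodynamic modulation 0.05,
# neural amplitude 0.03, tau 0.5 s)
spec = sd.WidefieldSimSpec(raw_height=48, raw_width=48, response_sigma=16.0,
                           n_trials=60, seed=1)
trials, truth = sd.make_widefield_trials(spec)
roi = np.zeros((12, 12), dtype=bool); roi[6, 6] = True
metrics, trace, _ = wf.analyze_session(trials, roi_mask=roi, bin_factor=4)
print(f"peak dF/F      : {metrics.peak:.4f}   (injected {truth.params['neural_amplitude']})")
print(f"peak latency   : {metrics.latency:.3f} s")
print(f"duration (20%) : {metrics.duration:.3f} s  (tau*ln5 = {0.5*np.log(5):.3f} s)")
print(f"normalized AUC : {metrics.auc_norm:.2f} samples")
print(f"active area    : {metrics.area_mm2:.4f} mm^2\n")

# animal-clustered morphology outcomes (19 vs 8 animals, ~13 neurons each)
tab, _ = sd.make_morphology_data((19, 8), 13, beta=2.41, sigma=0.38,
                                 baseline_logit=np.log(0.42/0.58), seed=1)
fit = st.BinomialMixedModel.from_dataframe(tab).fit()
st.parametric_bootstrap_test(fit, B=999, seed=1)
print(fit.summary())
```

prints

```
peak dF/F      : 0.0297   (injected 0.03)
peak latency   : 0.000 s
duration (20%) : 0.800 s  (tau*ln5 = 0.805 s)
normalized AUC : 12.48 samples
active area    : 0.0027 mm^2

BinomialMixedModel (ML, single random intercept)
  groups (animals): 27   observations: 351
  fixed effect beta :  2.6047  (s.e. 0.3446)
  sigma_animal      :  0.0000  [boundary]
  log-likelihood    : -199.6788
  parametric bootstrap p = 0.001 (B = 999)
```

The corrected peak recovers the injected ΔF/F amplitude within 1 %, the
duration matches the closed-form τ·ln 5 to one frame, and the mixed-model
β̂ (log odds of a pyramidal outcome, mutant vs control) sits within one
standard error of the generating β = 2.41; p hit the smallest value B = 999
replicates allow. (This seed fits σ at its zero boundary — with 27 animals
the between-animal variance is only weakly identified.)

A `barrelquant` console script exposes each pipeline
(`simulate, widefield, fosmap, profile, ioc, slicemap, ntd, morpho`); every
run stamps a provenance manifest with its inputs, parameters, seed, and
output hashes.

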