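# Methods

This note records the models implemented by `gliocircuit`, the assumptions
behind them, the parameter choices that matter, and what the synthetic-data
generators do and do not emulate.

## ECoG preprocessing

The signal path is fixed: downsample → bipolar re-reference → notch →
band-pass + Hilbert power → trial segmentation. The stages and their
defaults:

* **Downsampling** to `fs_target` (default 2000 Hz) uses polyphase
  resampling with its built-in anti-alias filter. Marker onsets floor and
  offsets ceil in the new sample units so a trial never loses interior time
  to rounding.
* **Bipolar derivation** subtracts adjacent contacts within a strip
  (1−2, 2−3, 3−4), so an m-contact strip yields m−1 channels and any signal
  common to the strip — in particular a shared scalp reference — cancels
  exactly. The synthetic generator therefore produces already-referenced
  voltages; no separate reference channel is modelled.
* **Notch filtering** removes every integer harmonic of the configured base
  frequencies (defaults 50 Hz mains and a 79 Hz equipment artefact) below
  Nyquist. Each harmonic is an IIR notch with quality factor 30, applied
  forward–backward. The Q was chosen so that high-gamma content *between*
  the 79-Hz harmonics survives; the original acquisition filters are not
  described precisely enough to copy, so a conventional narrow design is
  used.
* **Band power** is `|analytic(x_band)|²` with a 4th-order Butterworth
  band-pass applied forward–backward (70–250 Hz for high gamma; delta 1–4,
  alpha 8–12, beta 13–30, gamma 30–70 Hz for the specificity analysis).
  All filtering pads the signal with 1 s of reflection; the segmentation
  trims (≥ 1 s everywhere) discard whatever edge transients remain, and a
  pulse's power peak moves by at most 2 samples through the notch bank
  (asserted in tests).
* **Segmentation** trims 2 s from both ends of rest trials and 1 s from
  both ends of counting trials (manual marker error), plus 3 s from the
  start of switch trials (their initial easy phase). The task-trial trim is
  applied symmetrically at both ends: reaction-time error affects onset and
  offset marking alike. This is a declared reading of an ambiguous
  protocol sentence, not an inference.

## Rotation permutation test

Per electrode and contrast, all trials of the two conditions are
concatenated **in recorded order** into a closed loop of length L samples.
One jitter, uniform on {1, …, L−1}, shifts every marker modulo L;
condition means and the PSC are recomputed from the rotated markers. This
preserves trial lengths and the temporal autocorrelation of the power
series. Conventions, all declared rather than inferred:

* jitter granularity is one sample (the finest faithful choice), and the
  identity jitter 0 is excluded from the null — it *is* the observed
  statistic;
* for the easy > rest contrast the loop includes the rest trials (both
  conditions of the contrast enter the loop);
* two-tailed p = `2·min(r_lo, r_hi)` with `r = (count + 1)/(n + 1)`, capped
  at 1, so p is never 0; a rotation-invariant (constant-power) loop returns
  p = 1 with a degeneracy flag;
* the default rotation count is 100,000; calibration studies and the test
  suite run 2,000 (smallest attainable p ≈ 0.001), which is enough to
  resolve the .05 threshold.

The implementation shifts markers over a fixed loop using prefix sums, so a
full 2,000-rotation test over hundreds of channels takes milliseconds; its
equivalence to explicitly rotating the series is asserted against a
brute-force oracle on a 20-sample loop.

## Seed-based connectivity and the spin test

Electrode world coordinates snap to the nearest grey-matter/tumour voxel;
among candidates tied at voxel precision, the one whose distances to
already-snapped neighbours best match the nominal 10-mm strip spacing wins.
Seeds are 2.5-mm spheres intersected with the parenchyma mask. The map is
Pearson r of the seed-mean time series with every parenchyma voxel, Fisher
z-transformed with |r| clipped to 1−10⁻⁷ (finite everywhere), then smoothed
at 5-mm FWHM with a mask-renormalised Gaussian (non-parenchyma voxels are
excluded from the smoothing support). Zero-variance voxels get r = 0 and a
flag. Surface values are nearest-voxel samples within a 3-mm bound on a
synthetic sphere with a declared vertex→world mapping — a deliberate
replacement for subject-specific surface registration, which is out of
scope; the spin test only requires values on a sphere.

The spin null rotates the **map** (never the parcel labels) by Haar-uniform
rotations of SO(3), resampling by nearest vertex. Per-network medians over
valid vertices form the null; the two-tailed p uses the same `+1/(n+1)`
convention as the temporal test. Invalid vertices are excluded from both
observed and surrogate medians, and a surrogate parcel left with no valid
vertex contributes no null draw (the count is reported). One sphere stands
in for the two-hemisphere construction; the inferential logic does not
depend on hemisphere count.

A known resolution limit, found by simulation: for a **binary** parcel
indicator map the median saturates (observed median 1.0), and about 9% of
random rotations land the indicator on a majority of its own parcel, so the
tie-inclusive two-tailed p cannot fall below ≈ 0.19 at any rotation count.
The statistic is designed for continuous connectivity maps, where ties have
measure zero; a continuous peaked map at the same settings reaches
p ≈ 0.008. The conservative tie rule is kept because it is the one that
preserves validity under the null.

## Tumour-network connectivity

Every tumour voxel outside the network mask is correlated with the
network-mean time series; two-sided p-values use the exact t transform
`t = r√((n−2)/(1−r²))` (small-n volumes make the normal approximation
inappropriate). Survivors satisfy `p < α/m` (Bonferroni over the m tested
voxels, FWER < .05 by default); the summary is mean r over survivors, and
the tumour/network overlap count is reported for use as a model covariate.

## Association models

* **Grid:** one linear mixed model per (contrast, network) cell — PSC as
  response, network FC as the fixed effect, a participant random intercept
  (four-participant cohorts cannot support random slopes). The FC term is
  tested by Type II Wald χ² on 1 df, computed as `(estimate/SE)²` against
  χ²(1). Estimation delegates to statsmodels' REML; singular or
  non-converged fits are flagged, never dropped. At zero random-intercept
  variance the model profiles exactly to pooled OLS (provided as a
  diagnostic mode and asserted in tests).
* **Cohort models:** ordinary least squares with dummy coding; reference
  levels frontal / left / no-antiseizure / female / month-12. Standardized
  estimates scale the response and continuous predictors to unit sample SD
  and leave dummies 0/1, so dummy coefficients read as shifts in
  response-SD units. The sensitivity variant drops patients whose latest
  assessment was immediately post-operative.

## Synthetic data

The generators emulate the statistical structure the analyses assume, with
defaults chosen to mirror the study conditions:

* **ECoG:** 1/f background (spectral shaping, exponent 1, 20 µV RMS), line
  components at 50 and 79 Hz, and a 70–250 Hz noise carrier (10 µV RMS)
  whose envelope power is multiplied by the planted condition factors —
  multiplicative on power rather than additive on amplitude precisely so
  the true PSC has the closed form `(factor − 1)·100`. The default trial
  plan is one 2-min rest baseline and three 20-s trials per counting
  condition (the protocol allowed 2–5); acquisition-scale sampling is
  10 kHz with analysis at 2 kHz.
* **BOLD:** a 20³ grid at 2-mm/1.06-s resolution with 200 volumes (the real
  acquisition is emulated in structure, not size), seven disjoint spherical
  network supports with unit loadings, white voxel noise (σ = 1), and a
  tumour sphere whose voxels couple to chosen networks with weights
  w ∈ [0, 1]; the population tumour-voxel/network correlation is
  `w/√(w² + σ²/Var c)`.
* **Sphere:** an icosphere (10·4^s + 2 vertices) with parcels grown from
  random seed vertices; chord-distance Voronoi cells on a sphere are
  geodesically convex, hence contiguous on the mesh graph.
* **Cohort:** 17 patients by default; location-shifted connectivity,
  dummy-coded covariates, and follow-up scores from a linear model with
  planted standardized coefficients plus N(0, σ) residuals; follow-up
  missingness is Bernoulli.

Not emulated: haemodynamic response convolution, motion and physiological
artefacts, neurovascular uncoupling inside the tumour, registration error,
electrode brain-shift, and glioma biology. Passing tests therefore show
that the *inference machinery* is correct and calibrated under its own
assumptions — not that those assumptions hold in patient data.

## Problem sizes and numerical choices

Calibration studies run at what a desk check needs rather than publication
scale, chosen once: 200 null electrodes × 2,000 rotations for the temporal
test (per-electrode PSC estimator SD ≈ 3 points with four 10-s trials per
condition); 200 replicates × 500 spins for the spatial test on an s = 3
icosphere; 200 replicates for mixed-model calibration. Parameter-recovery
checks use 5 × 20-s trials per condition (ECoG), 8 participants × 5
electrodes (grid), and n = 100–200 patients (cohort), sizes at which
Monte-Carlo error is small against the stated tolerances. Random state is
always an explicit integer seed; batch studies derive per-batch seeds by
fixed affine maps kept below 2³¹.

## Known limitations

* EDF export quantises to 16 bits over each channel's range and pads to
  whole seconds; the text format is lossless and preferred for fixtures.
* Electrode coordinates are taken as given; brain-shift correction and
  surface back-projection are out of scope.
* The volume↔surface step is nearest-voxel sampling on a synthetic sphere,
  not anatomical registration.
* No multiple-comparison correction is applied across electrodes or across
  the 14 grid models, matching the analysis design this pipeline
  implements.
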