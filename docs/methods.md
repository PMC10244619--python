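# Methods

## Scope and data model

The package analyses time series of 2D EIT impedance frames (arbitrary
units, AU) from supine neonates. A recording is a `(time, row, column)`
float32 stack with frame rate, subject id, body weight and a fixed
orientation convention: row 0 is ventral, the last row dorsal. In supine
position the dorsal lung is gravity-dependent; every gravity-related metric
(AHR, the silent-space split) is defined against this convention, which is
stored in the container sidecar so that it can never be ambiguous at
analysis time.

Recordings are stored as a JSON sidecar plus a raw little-endian float32
frame file (frame-major, row-major within a frame). The format is
deliberately minimal — bit-exact round trips, language agnostic, no
dependency on any vendor container. Whether the device exports absolute or
baseline-referenced impedance is left to the data: values are stored as
given and all reported metrics except EELI/kg are invariant to a global
positive rescaling.

## Lung ROI

The clinical analysis projects an anatomical chest atlas into the image and
discards non-lung pixels. The vendor atlas is proprietary, so the package
uses a parametric two-ellipse atlas, mirror-symmetric about the vertical
midline, with defaults chosen so that on the 32×32 neonatal grid the lung
bounding box spans rows 6–25. Two conventions follow from the bounding box:

* **Ventral/dorsal halves.** The box is split at its horizontal midline;
  with an odd number of rows the middle row contributes weight 0.5 to each
  half. This makes the halves well defined for any geometry and makes AHR
  the ratio of two row-weighted EELI sums.
* **Exclusion is NaN, never zero.** Out-of-lung pixels are set to NaN and
  skipped by all downstream statistics; zero-filling would corrupt means
  and standard deviations.

Body-weight normalization divides every pixel by the weight in kg (units
AU/kg) and flags the recording; normalizing twice raises a state error.
Because the other metrics are scale-invariant, normalization order relative
to masking does not matter (a property test asserts this).

## Segment selection and artefact screen

Analysis uses a contiguous window (default 30 s) containing
`floor(duration×fs) + 1` frames, endpoints included, so that a window
aligned with end-expiration holds a whole number of breaths. The paper
trail for artefact handling in bedside EIT is thin ("artefact-free" is a
judgement call by the operator), so the screen here is deliberately simple
and scale-free: the global lung-sum signal must keep its robust z-score
(median/MAD of the window itself) within ±6 for at least 99% of frames.
Tidal oscillation itself reaches |z| ≈ 1, a 20× amplitude spike exceeds the
limit by an order of magnitude. A failing window is flagged (and excluded
by the pipeline) or, with `artefact_hard_fail`, rejected outright.

## Breath segmentation

Breaths are detected on the global lung-sum waveform:

1. **Cardiac tone removal.** The residual above an 8th-order zero-phase
   Butterworth low-pass (default 2 Hz) is fitted with a single sinusoid
   (frequency from the FFT peak refined by least squares, amplitude/phase
   by linear least squares on the trusted interior of the window) and
   subtracted, iterating up to four times. A sinusoid extrapolates exactly,
   so this also cleans the boundary zones where any zero-phase filter has
   reflection transients. Nothing is subtracted unless the tone dominates
   the residual, so noise-only residuals are untouched.
2. **Low-pass and extrema.** The cleaned signal is mirror-padded, filtered,
   and local maxima/minima are kept if their prominence exceeds 25% of the
   median peak-to-trough excursion.
3. **Boundary recovery.** Within ~2 cutoff periods of the window edges the
   filtered signal is not trusted. End-expirations there are recovered by
   extrapolating one median breath period beyond the outermost trusted
   troughs and refining on the fold-averaged breath template; a candidate
   is accepted only at interior-trough level, so a window that starts
   mid-breath does not gain a spurious breath.
4. Breaths are trough–peak–trough triples; fewer than two is an error.

Defaults (2 Hz cutoff, order 8, 25% prominence) are configurable. The
filter order matters: at 40 breaths/min a 4th-order filter leaves enough
2.5 Hz cardiac residual to displace detected end-expirations by more than
one frame, while order 8 bounds the displacement at about half a frame.

**Limitation.** Cardiac activity below roughly 0.8× the low-pass cutoff
(≈ 96/min at the default) is spectrally inseparable from breathing with
this design; the intended regime is the neonatal heart-rate band
(≳ 120/min) well above the respiratory band.

## Pixel maps and metrics

With breaths in hand, `eeli_map` is the mean pixel value over the unique
end-expiration frames and `tv_map` the mean over breaths of the
end-inspiration minus preceding end-expiration difference, with negative
per-breath differences (possible under noise) clamped to zero because
tidal variation is physically nonnegative.

* **Aer%** — share of lung pixels with EELI above 10% of the lung maximum.
  The aeration criterion is not spelled out in the clinical literature at
  pixel level; the 10%-of-maximum rule mirrors the established silent-space
  convention and is configurable (`aeration_threshold_frac`).
* **AHR** — ventral ÷ dorsal row-weighted EELI sums; a zero dorsal sum is
  an error (never infinity).
* **CV** — population SD ÷ mean of `tv_map` ("impedance changes" is read as
  tidal variation, the standard functional-EIT pixel quantity; a sample-SD
  convention is available via `sd_convention`).
* **Center of ventilation** — TV-weighted mean row position, as a fraction
  of lung height (0 = ventral edge, 1 = dorsal edge).
* **Silent spaces** — lung pixels with TV below 10% of the lung maximum
  (`silent_threshold_frac`); silent pixels ventral of the
  center-of-ventilation line count as non-gravity-dependent, dorsal as
  gravity-dependent, a pixel exactly on the line splits 0.5/0.5, so
  SS_NGD + SS_GD ≡ SS_total. As percentages they are invariant to weight
  normalization.

Degenerate inputs return degenerate values with warnings (all-zero EELI →
Aer% 0; all-silent TV → SS 100 split evenly) rather than errors, because a
cohort run must survive a single pathological subject.

**Limitation.** `tv_map` point-samples two frames per breath, so a cardiac
component contributes its instantaneous value at those frames; with the
zero-clamp this biases TV upward for weakly ventilated pixels. Breath
averaging suppresses but does not remove the bias. Silent-space estimates
are reliable when the cardiac amplitude is small compared to the silent
threshold (10% of the maximum tidal swing); the synthetic default is a
cardiac-free tidal signal, and the cardiac term exists to stress breath
*timing*, which is protected by the tone removal above.

## Synthetic recordings

Frames are synthesized directly in image space (no electrode-level forward
or inverse reconstruction):

    value(t) = EELI_p + TV_p/2 × (1 − cos(2π·f_resp·t)) + cardiac + noise

The raised cosine puts each pixel's minimum exactly at its EELI value, and
the breath period is snapped to a whole number of frames so end-expirations
sit exactly on frame indices — this is what makes breath-detection and
metric-recovery tests exact rather than approximate. Scenario knobs, with
defaults chosen as plausible neonatal values:

| Parameter | Default | Meaning |
|---|---|---|
| grid_shape | 32×32 | device lattice |
| frame_rate_hz | 51 | device frame rate |
| eeli_base | 10 AU | aerated-pixel end-expiratory level |
| gradient_g | 1.0 | target ventral/dorsal EELI ratio (= true AHR) |
| aerated_fraction | 1.0 | share of lung pixels with nonzero EELI |
| tidal_amp | 2 AU | per-pixel tidal swing |
| tidal_dispersion | 0 | mean-zero amplitude spread (drives true CV) |
| silent_fraction | 0 | share of lung pixels planted silent |
| silent_placement | dorsal | dorsal / ventral / random |
| resp_rate_per_min | 60 | breath rate (period snapped to frames) |
| cardiac_rate/amp | 150 / 0 | optional uniform sinusoid over lung pixels |
| noise_sd | 0 | i.i.d. Gaussian pixel noise, AU |
| body_weight_g | 1140 | median birth weight of the target population |

The ventral–dorsal gradient multiplies aerated pixels by `exp(γ·x(row))`
(x = 1 ventral-most, 0 dorsal-most) with γ solved by Brent's method so the
row-weighted ventral/dorsal ratio equals `gradient_g` to ~1e-12 — a linear
ramp cannot reach large ratios. Planted silent pixels oscillate at 5% of
`tidal_amp`, below the 10% threshold but not degenerate-zero, so tests
exercise the threshold rather than a trivial zero. Non-aerated pixels do
not ventilate, so they are silent too; all ground truth (`ScenarioTruth`)
is computed from the noiseless pixel maps through the very same metric
formulas the measurement path uses, which makes the generator a closed-form
oracle for the entire signal-processing chain. `tidal_dispersion` is capped
at 0.8 so dispersed pixels never cross the silent threshold.

The oracle scenario sampler draws tidal amplitudes between 20% and 50% of
the EELI baseline — the physiological regime — which also keeps float32
container quantization of the tidal-difference maps about two orders of
magnitude below the 1e-6 oracle tolerance.

What the generator does **not** emulate: electrode physics and
reconstruction artefacts, breath-to-breath variability (rate and amplitude
are constant within a recording), posture changes, belt movement, and
non-sinusoidal cardiac waveforms. Passing oracle tests therefore
demonstrates correctness of the analysis chain, not robustness to every
bedside artefact.

## Synthetic cohorts

Cohort rows pair a six-predictor vector (multivariate normal with
configurable means, SDs and correlation, clipped to valid ranges) with
clinical covariates and three Bernoulli outcomes drawn from a known
logistic model; the linear predictor is evaluated on the clipped values
actually written to the table, so the generating model holds exactly for
the emitted data. Clinical distributions follow the target population
(gestational age ≈ N(29.6, 1.8) weeks, birth weight ≈ N(1140, 355) g, 50%
male). The default oxygen-at-28-days model uses odds ratios of 0.8 per Aer%
point and 9.58 per AHR unit — published effect sizes used as simulation
settings — with the intercept balancing prevalence at 0.5 for an average
infant; early failure is a weak Aer% effect around 22% prevalence; the BPD
outcome is a rare null (~3%), mirroring a cohort with a single event. One
global seed drives a counter-based substream per subject
(`SeedSequence(seed, spawn_key=(i,))`), so any prefix of a cohort is
reproducible independently of its length.

The pipeline's `simulate` stage maps each cohort row to a recording
scenario heuristically (AHR → gradient, Aer% → aerated fraction, silent
total minus the unaerated share → planted silent fraction placed toward the
heavier side, CV → tidal dispersion, EELI/kg → a post-hoc map rescale);
`extract` then re-measures the metrics from the frames, so fitted models
run on measured, not planted, values.

## Outcome models

Logistic models are fitted by Newton/IRLS maximum likelihood (score
tolerance 1e-8, ≤50 iterations) with Wald standard errors from the inverse
observed information; odds ratios are reported with exp(β ± 1.96·SE)
intervals, per unit by default and per SD behind a `standardize` flag
(published "per unit" effect sizes for ratio-scale predictors like AHR are
ambiguous; both conventions are one flag apart). Complete or quasi-complete
separation — runaway coefficients or a separation warning from the
optimizer — is flagged and the odds ratio withheld rather than reporting
astronomically large values; penalized alternatives were deliberately not
substituted, favoring transparency over silent modification. No
multiplicity adjustment is applied across the 5-predictor × 3-outcome
screen, mirroring common practice in small exploratory cohorts; the output
carries unadjusted p-values and a significance flag at α = 0.05 only.

ROC AUCs are rank-based (Mann–Whitney; tied pairs count 0.5) and apparent
(in-sample) — again mirroring small-cohort practice — with a stratified
cross-validation option off by default. Model comparisons fit clinical
{GA, sex, birth weight}, EIT {Aer%, AHR} and combined models; comparisons
are skipped with a recorded reason when the smaller outcome class has fewer
than 5 events (configurable), and univariate fits on such outcomes carry an
"unreliable" flag.

## Reproducibility and problem sizes

Every output carries a provenance block (hash of the analysis-relevant
configuration, seed, package version) and no timestamps; a fixed
config+seed reproduces the full pipeline byte for byte, which the test
suite asserts at the study's size of 32 subjects. Default verification
sizes — 50 oracle scenarios, 200 replicate cohorts of n = 500 for coverage,
30-s recordings at 51 Hz — were chosen so the whole suite exercises every
claim at meaningful precision while remaining quick to run routinely.
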