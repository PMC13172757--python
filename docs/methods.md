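# Methods

This note documents the signal model, the parameter choices and their
rationale, the numerical decisions, and the known limitations of
`taplab`. Problem sizes (cohort sizes, sampling rates, durations) used
in examples and tests are the package's own choices for a plausible
small clinical study; nothing here depends on external data.

## Signal model

The observable is the index-fingertip-to-thumb-tip Euclidean distance
`d(t)` computed per video frame from 2-D hand landmarks (normalized
image coordinates or pixels — the features are reported in the input's
units per second where applicable). Repetitive finger tapping renders
`d(t)` as a quasi-periodic train of opening/closing pulses. Bradykinesia
manifests as reduced mean speed, progressive amplitude decrement, and
elevated cycle-to-cycle variability of amplitude and rhythm.

## Conditioning pipeline

Order: linear detrend → Savitzky–Golay → resample → Butterworth.

- **Quality control** — a recording is usable when at most 5 % of
  frames lack both landmarks (strict "more than 5 %" excludes), it
  contains at least 15 s of continuous tracked signal, and no runs of
  retained frames fall at or below the occlusion confidence threshold
  (default 0.0, i.e. only fully occluded detections count).
- **Linear detrend** removes slow drift (camera or hand translation)
  that would otherwise bias amplitude estimates.
- **Savitzky–Golay** (2nd order) suppresses landmark jitter while
  preserving pulse peaks. The window is the largest odd number of
  samples not exceeding one third of the expected tap period
  (`fps / expected_freq / 3`), floored at 5 — short enough never to
  merge adjacent taps at tapping rates up to ~4 Hz.
- **Resampling to 50 Hz** (linear interpolation) puts recordings from
  heterogeneous cameras on a common rate before filtering. The output
  grid spans `span + one input frame period`, i.e.
  `n_out = round(duration * 50)`; the final samples are linearly
  extrapolated from the last input segment.
- **Butterworth low-pass** (5th order, 10 Hz cutoff, zero-phase via
  forward–backward filtering) removes residual high-frequency noise.
  10 Hz sits well above voluntary tapping rates (≤ ~5 Hz) and well
  below the 25 Hz Nyquist limit. Zero-phase filtering avoids lag that
  would shift peak times.

Every step appends an entry to the waveform's provenance tuple;
feature extraction refuses waveforms that have not passed the
Butterworth stage (override with `require_conditioned=False`).

## Tap segmentation and features

Peaks are strict local maxima (plateaus resolve to their leftmost
sample) with topographic prominence at least 10 % of the signal range,
then greedily thinned in decreasing height order with a 0.2 s
refractory period — no two retained peaks may be closer than 0.2 s,
equivalent to a 5 Hz ceiling on instantaneous tap rate. Valleys are the
minima between consecutive retained peaks. The amplitude of a cycle is
its peak height minus the mean of the adjacent valleys (one-sided at
the ends). At least 5 cycles are required; otherwise
`InsufficientCyclesError`.

- `V = mean(|Δd|) * sample_rate` — mean absolute first derivative.
- `Δa` — OLS slope of amplitude against 0-based cycle index.
- `aCoV = sd(A) / mean(A)`, `ifCoV = sd(if) / mean(if)` with
  `if_i = 1 / (t_{i+1} - t_i)` and sample (n − 1) standard deviations.

## Synthetic tapping generator

The generator exists because the pipeline must be testable end to end
without patient recordings. Per bout:

1. Instantaneous frequencies are log-normal with the requested mean
   and coefficient of variation; peak-to-peak gaps are drawn directly
   as their reciprocals, so the realized intervals carry the target
   rhythm CoV by construction.
2. Cycle amplitudes are gamma with the requested mean and CoV;
   amplitude decrement is a deterministic linear trend added to the
   expected amplitude.
3. Each tap is rendered as a symmetric raised-cosine pulse centred on
   its peak time, with half-width equal to half the shorter adjacent
   gap and zero dwell in between. Symmetry matters: with asymmetric
   (valley-to-valley) pulses, smoothing filters shift each maximum
   toward the broader lobe, which regularizes the intervals and biases
   extracted ifCoV low by 0.06–0.12. With symmetric pulses the mean
   extraction bias for both CoVs stays below 0.05 across targets up to
   0.6 (Monte-Carlo tested against the realized per-bout cycle list).
4. Gaussian measurement noise (default SD 0.005 normalized units)
   stands in for landmark jitter.

For this pulse shape the total variation per cycle is `2A` (rise `A`
plus fall `A` with no dwell), so a noiseless metronomic bout has
`V ≈ 2 · mean_amplitude · frequency`. (A pure sinusoid would give
`4Af`; the difference is pulse geometry, and the `2Af` identity is
what the zero-variability tests pin.)

Group specifications are given as median and quartiles `[q1, q3]`
(the natural summary for skewed clinical features). They are converted
to log-normal parameters by `location = ln(median)` and
`scale = ln(q3/q1) / (2 · z₀.₇₅)` with `z₀.₇₅ ≈ 0.6745`. This
preserves the median exactly and the quartile *ratio* exactly; the two
individual quartiles are symmetrized in log space (an exact log-normal
match to three arbitrary quantiles is overdetermined).

Cohort simulation draws one parameter set and one bout per subject,
runs the real conditioning and extraction code, and records QC
failures (including bouts whose random draws yield fewer than 5
detectable cycles) as excluded subjects with missing features rather
than erroring out. Per-subject seeds are drawn from the cohort seed's
generator in the half-open range [0, 2³¹ − 1).

Synthetic clinical anchors (total motor score, the finger-tapping
item, disease duration) are generated with fixed rank correlations to
the variability features so correlation machinery can be exercised;
the imaging ratio (SBR) is generated independently. These are
conveniences for testing, not claims about clinical coupling strength.

## Statistics

- **Mann–Whitney U** uses the exact null distribution when
  `n1·n2 ≤ 400` and no ties are present, otherwise the tie-corrected
  normal approximation — appropriate at small-cohort scale.
- **AUC–U identity**: `AUC = U / (n1·n2)` where U counts pairs won by
  the positive group (ties half-weighted).
- **ROC** standard errors and confidence intervals use the DeLong
  placement-value method (cross-checked in the tests against the R
  `pROC` implementation). AUC is reported in the raw score direction;
  values below 0.5 are allowed and not flipped.
- **Youden cutoff**: candidate cutoffs are midpoints between adjacent
  unique scores; `score ≥ cutoff` is a positive call; ties on the
  Youden index break toward higher specificity, then lower cutoff.
  Pooled accuracy = `(sens·n₊ + spec·n₋) / n`. `confusion_accuracy`
  first rounds the rates to integer confusion counts so that accuracy
  computed from reported percentages is exact.
- **Logistic regression** (statsmodels, Newton, tolerance 1e-8)
  reports Wald statistics, odds ratios, the omnibus likelihood-ratio
  test, Cox–Snell and Nagelkerke R², and classification rate at 0.5.
  Perfect separation falls back to a ridge-regularized fit and is
  flagged (`converged=False`) instead of raising. Predictors enter
  untransformed by default.
- **Spearman correlations** use tie-aware average ranks; 95 % CIs are
  percentile bootstrap over paired resamples (default 1000, seeded).
  Degenerate (constant) resamples are skipped.
- **Multiplicity** uses Benjamini–Hochberg step-up q-values, applied
  within each clinical-anchor family of four features.

## Known limitations

- The extraction recovery guarantee (|mean bias| < 0.05 for both CoVs)
  holds for amplitude/rhythm CoV targets up to 0.6 when both vary
  together. At artificial corner cases — one CoV 0.6 with the other
  exactly 0 — interaction between pulse rendering and smoothing can
  push the bias to ≈ +0.12 (aCoV) or −0.06 (ifCoV). These corners do
  not occur in the simulated clinical contrasts.
- The generator renders one stereotyped pulse shape; it does not model
  hesitations, freezing episodes, or partial-amplitude "stutter" taps.
- 2-D landmark distances are camera-projection dependent; V is only
  comparable across recordings in normalized or otherwise calibrated
  units.
- One acceptance reference pair is internally inconsistent:
  U = 97.5 over 320 pairs gives AUC 0.3047 → 0.30 at two decimals, not
  the stated 0.31 (0.31 would require U ≈ 99.2). The corresponding
  acceptance test asserts the stated value and therefore fails; the
  arithmetic, not the assertion, is what the package stands behind,
  and the other three pairs (0.93, 0.83, 0.36) are consistent.
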