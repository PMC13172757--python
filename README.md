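# taplab

Kinematic analysis of finger tapping from markerless hand-landmark
tracking, aimed at objective motor assessment in Parkinson's disease.

## The problem

Clinical rating of bradykinesia (e.g., the finger-tapping item of the
MDS-UPDRS part III) is ordinal and rater-dependent. Video-based hand
pose estimation produces per-frame fingertip coordinates from ordinary
camera recordings; from those, the index–thumb distance over time is a
one-dimensional signal whose cycle-to-cycle properties quantify the
cardinal features of bradykinesia: slowness, amplitude decrement, and
variability of amplitude and rhythm.

`taplab` implements the full chain from landmark time series to
cohort-level statistics:

1. **Ingestion** (`taplab.landmarks`) — long-format landmark CSV →
   index–thumb Euclidean distance waveform, with dropped-frame
   bookkeeping.
2. **Conditioning** (`taplab.preprocess`) — quality control (≤ 5 %
   dropped frames, ≥ 15 s continuous, no occlusion runs), linear
   detrend, 2nd-order Savitzky–Golay smoothing, resampling to 50 Hz,
   5th-order zero-phase Butterworth low-pass at 10 Hz.
3. **Feature extraction** (`taplab.kinematics`) — tap-cycle
   segmentation by prominence-filtered peak detection with a 0.2 s
   refractory period, then four features per recording:
   - **V** — mean absolute first derivative of the distance signal
     (opening/closing speed);
   - **Δa** — ordinary-least-squares slope of cycle amplitude on cycle
     index (amplitude decrement);
   - **aCoV** — coefficient of variation of cycle amplitudes;
   - **ifCoV** — coefficient of variation of instantaneous frequency
     (reciprocal peak-to-peak intervals).
4. **Statistics** (`taplab.stats`) — Mann–Whitney U with the
   AUC = U/(n₁·n₂) identity, DeLong ROC standard errors and confidence
   intervals, Youden-index cutoffs, binary logistic regression with
   Cox–Snell/Nagelkerke R², Spearman correlations with bootstrap CIs,
   and Benjamini–Hochberg false-discovery-rate adjustment.
5. **Synthetic cohorts** (`taplab.synthetic`) — a generative model of
   tapping bouts (log-normal instantaneous frequency, gamma cycle
   amplitudes, deterministic linear decrement, raised-cosine pulse
   rendering, Gaussian measurement noise) whose group parameters are
   specified via median and quartiles, so cohorts resembling a
   patient/control contrast can be simulated when recordings are not
   available.
6. **Reporting** (`taplab.report`) — selection-flow accounting for
   retrospective cohort assembly and an end-to-end pipeline that writes
   tidy CSV tables plus a JSON manifest, byte-reproducible under a
   fixed seed.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite checks every numerical routine against independent
brute-force oracles (pairwise AUC, exhaustive Youden scan, hand-rolled
Benjamini–Hochberg step-up, textbook peak detection) and includes
Monte-Carlo recovery tests for the generator. One acceptance test,
`test_criterion_1_auc_u_identity_on_cohort_scale_values`, fails by
design: one of its reference value pairs is internally inconsistent
(U = 97.5 over 320 pairs is 0.3047, which rounds to 0.30, not the
stated 0.31). The assertion is kept as stated rather than loosened;
see `docs/methods.md`.

## Worked example

```python
from taplab.synthetic import TapGenParams, simulate_tap_waveform
from taplab.preprocess import condition
from taplab.kinematics import extract_features

params = TapGenParams(mean_amplitude=0.15, amplitude_cov=0.35,
                      mean_frequency=2.0, rhythm_cov=0.40,
                      decrement_slope=-0.001, noise_sd=0.005,
                      fps=30.0, duration_s=15.0, seed=7)
waveform, truth = simulate_tap_waveform(params)
features = extract_features(condition(waveform))
print(features)
```

prints

```text
KinematicFeatures(V=0.41807613375318964, delta_a=-0.0016988732506423476,
aCoV=0.29756709510542984, ifCoV=0.3119625243801696, n_cycles=22, qc_pass=True)
```

The extracted aCoV (0.298) and ifCoV (0.312) recover the generator
targets (0.35, 0.40) up to the sampling noise of a single 15 s bout;
averaged over many bouts the extraction bias is below 0.05 (this is
tested).

A full cohort analysis from the command line:

```bash
taplab report --seed 1 --out-dir demo
cat demo/summary.txt
```

```text
taplab cohort report (seed=1)
subjects simulated: 42  (QC-excluded: 0)

  V        AUC=0.184 [0.050-0.318] cutoff=2.287 acc=26.2%
  delta_a  AUC=0.347 [0.180-0.513] cutoff=0.000 acc=40.5%
  aCoV     AUC=0.875 [0.741-1.000] cutoff=0.185 acc=90.5%
  ifCoV    AUC=0.988 [0.964-1.000] cutoff=0.200 acc=95.2%

logistic: omnibus chi2(4)=46.11 p=2.341e-09; Nagelkerke R2=1.000; correct=100.0%
```

Variability features (aCoV, ifCoV) discriminate the two simulated
groups strongly; velocity is reported in its raw direction, so its AUC
falls below 0.5 when the positive group taps more slowly. Other CLI
commands (`taplab extract`, `preprocess`, `features`, `stats`, `flow`)
operate on CSV files stage by stage; see `taplab --help`.

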