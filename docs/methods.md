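# Methods

This note documents the models, defaults and numerical choices behind
`stresscare`, and what the synthetic experiments do and do not show.

## Recording model and bundle format

A recording is a set of channels — each a real-valued series with its own
sampling rate and a device placement (wrist or chest) — plus a per-sample
condition label series at a stated label rate. Condition codes are fixed
package-wide: 0 baseline, 1 stress, 2 amusement. Time is implicit
(index / rate) and all windows are half-open intervals [t, t + W) in
seconds. Channel placements follow the common hardware split: wrist
devices carry sweat, BVP, EDA, TEMP and a 3-axis accelerometer; chest
devices sweat, ECG, RESP, EMG, TEMP, EDA (and optionally ACC).

Bundles are deliberately plain: a JSON manifest, one single-column CSV per
channel written at `%.17g` (read back with round-trip float parsing, so
write→read is the identity), and a label CSV. An optional boolean mask
column marks samples excluded from analysis; the WESAD importer uses it for
the dataset's non-study protocol phases (transients, meditation) rather
than relabelling them. WESAD has no dedicated sweat sensor, so the importer
mirrors a configurable source channel (default EDA) under the name `sweat`
and logs the substitution loudly; the mirrored channel is a placeholder,
not a measurement.

## Conditioning

* **Cardiac band-pass.** BVP and ECG are filtered with an order-3
  Butterworth band-pass applied forward–backward (`sosfiltfilt`), cutoffs
  38/60 ≈ 0.633 Hz and 220/60 ≈ 3.667 Hz. The BPM→Hz conversion treats the
  stated heart-rate bounds as the fundamental band; it is configurable.
  Zero-phase filtering costs a doubled effective order but keeps filtered
  samples aligned with the label stream, which matters because windows take
  per-sample majority labels.
* **Smoothing.** Every non-BVP channel is Savitzky–Golay smoothed,
  polynomial order 3, window 10 samples rounded up to 11 (the filter
  requires an odd, centred window; the effective window is logged). The
  order-3 filter reproduces cubic trends exactly, so slow physiology
  (tonic EDA, temperature drift) passes untouched while sample noise is
  attenuated. ECG is smoothed first, then band-passed; the order is
  configurable and immaterial for linear filters.

Both filters are length-preserving, deterministic, and run on the whole
series before segmentation, so filtering and windowing commute.

## Segmentation

Windows of W = 50 s advance by S = 8 s from t = 0 of each contiguous
unmasked run; no partial trailing window is emitted. A run of usable
duration T therefore yields exactly floor((T − W)/S) + 1 candidate
windows — the closed form is property-tested against a brute-force
enumerator. Each window takes its modal per-sample label; windows whose
modal label covers ≤ 50 % of samples, or ties, are dropped and counted in
a report. The default 720 s schedule (baseline 240 s, amusement 120 s,
stress 240 s, baseline 120 s) yields 84 windows per subject.

## Features

The canonical per-channel set (11 features) is frozen and documented in
`stresscare.features`: mean, population std, min, max, dynamic range,
least-squares slope against time in seconds, absolute integral Σ|x|/rate,
peak frequency (argmax of the plain mean-removed periodogram, DC excluded),
band power (total non-DC periodogram power, which by Parseval equals the
population variance), and first-difference mean/std. The periodogram is an
untapered DFT magnitude-squared — the simplest defensible spectral
estimate at this window length. Cross-channel Pearson correlations are
computed within a device only, for the pairs a branch names, after
reducing the higher-rate channel to the lower rate by non-overlapping
block means. Degenerate statistics (zero-variance slices) yield 0 instead
of NaN — classifier backends need finite inputs — and each row carries a
`degenerate_count` column recording how many were patched.

## Gated ensemble

Branch classifiers are early-fusion models: the design matrix is the
column concatenation of the branch's modality features plus their
within-branch correlations. Backend hyperparameters are frozen in
`stresscare.model.BACKEND_DEFAULTS`: unlimited-depth decision tree,
100-tree random forest, RBF-kernel SVM with in-fold standardisation and
Platt-scaled probabilities, and gradient boosting with 100 rounds,
learning rate 0.1, depth 6. All training is seeded; two runs with equal
seeds produce identical predictions.

The gate maps context features (the accelerometer block on the wrist, EMG
features on the chest) to a probability per branch. Its supervision —
"which branch is appropriate for this segment" — is derived from data:
within each training fold, branches predict internal held-out subjects
(grouped 3-fold), each segment is labelled with the branch that classified
it best, and ties go to the branch with fewer modalities, then to
registration order. When one branch is always best the supervision is
degenerate and a constant gate is fitted with a warning. Gate backends
default per device (wrist: random forest; chest: gradient boosting), with
the decision tree available as a low-cost option.

Branch selection at threshold b keeps {i : pᵢ ≥ (1 − b)·max(p)} — the
unique rule linear in b that meets both endpoint behaviours (b = 0 argmax
only, b = 1 all branches) and gives selections nested in b. Late fusion
averages the selected branches' probability vectors (majority voting is a
config switch); argmax ties break toward the lowest class code, which is
deterministic and seed-independent. Unanimous inputs are returned
bit-exactly rather than re-averaged.

## Evaluation

Accuracy is trace/total of the confusion matrix; for two classes this
equals (TP + TN)/(TP + FP + TN + FN). Macro F1 averages 2xy/(x + y) over
the task's class count n_c — fixed by the task (2 or 3), not by the labels
observed, with absent or undefined classes contributing 0, so folds remain
comparable. Both metrics are verified against naive per-sample loop
oracles to 1e-12. The two-class task merges baseline and amusement into
non-stress (code 0); stress keeps code 1. The protocol is
leave-one-subject-out by default (k-fold by subject is available), and
every report carries a config fingerprint (SHA-256 of the canonical config
JSON) plus the package version and seed.

## Synthetic cohort

The simulator is specified in `stresscare.synth`'s module docstring; the
defaults are the package's study conditions: 8 subjects, the 720 s block
schedule above, heart rate 70±5 / 80±5 / 95±5 BPM
(baseline/amusement/stress) redrawn per block with 10 s linear ramps,
skin-conductance-response rates 0.03 / 0.06 / 0.15 events/s with a
1 s-rise 4 s-decay bi-exponential kernel, condition-scaled EMG bursts,
condition-dependent respiration rate and temperature drift, and
condition-independent motion episodes. Values without an external anchor
(noise levels, respiration rates, burst shapes) were chosen once as
physiologically plausible orders of magnitude and are all serialised in
`SynthConfig`. `null_config` zeroes every condition delta for calibration
runs.

What the simulator emulates — and what it does not: signals have
state-dependent first- and second-order structure at realistic rates, but
no PPG/QRS waveform morphology, no motion artefacts coupled into other
channels, no sensor drift or dropout, and between-subject variation limited
to independent parameter draws. Passing the cohort-recovery tests shows the
pipeline recovers planted, separable state structure across subjects; it
does not certify performance on real wearable data.

Two behaviours of the default cohort are worth knowing:

* Because per-block heart rates are drawn independently (±5 BPM around
  means 15 BPM apart), occasionally a subject's amusement block draws a
  higher rate than its stress block; classifiers trained on the other
  subjects then misclassify much of that subject's session. This is an
  intended feature of the generator — per-window separability is good but
  not perfect — and makes LOSO scores fluctuate by a few points across
  master seeds (WB2 two-class macro F1 ≈ 0.88–0.91 over seeds 0–3).
* Since every branch classifies most windows correctly, branch-correctness
  ties are common, and the cheapest-branch tie-break often collapses the
  gate supervision to the smallest branch (a constant gate, with warning).
  The gated ensemble then legitimately reduces to that branch; contexts in
  which branches genuinely disagree (e.g. heavy motion corrupting BVP) are
  not part of the default simulation.

## Problem sizes

The shipped tests and the acceptance script use the 8-subject default
cohort (672 pooled windows), 1000-draw oracle comparisons for the
closed-form checks, and 10⁴ random vectors for the selection-rule
properties; a full synthetic run completes in well under a minute on one
CPU.

## Known limitations

* The chest pathway is fully implemented (registry CB1–CB28, EMG gate) but
  the default experiments exercise the wrist; chest simulation at the
  native 700 Hz is costly and used with reduced rates in tests.
* The gate cannot combine wrist and chest branches in one ensemble.
* No artifact detection, R-peak/HRV analysis, SCR decomposition, or
  deep-learning backends.
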