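# stresscare

Context-aware, gated multi-branch sensor fusion for stress classification
from wrist- and chest-worn physiological sensors.

Wearable devices record heterogeneous biosignals — blood volume pulse
(BVP), electrodermal activity (EDA/GSR), a slow sweat/humidity channel,
skin temperature, electromyography (EMG), respiration and acceleration —
whose usefulness for affect recognition depends on context: motion corrupts
a wrist optical pulse sensor, muscle contraction corrupts chest signals.
`stresscare` implements a pipeline for this setting, aimed at researchers
in wearable affective computing:

1. **Conditioning** — cardiac channels (BVP, ECG) pass through a zero-phase
   order-3 Butterworth band-pass covering physiological heart rates
   (38–220 beats/min, i.e. 0.633–3.667 Hz); all other channels are smoothed
   with a Savitzky–Golay filter (order 3, window 10 → 11 samples).
2. **Segmentation** — 50 s sliding windows with an 8 s stride; each window
   takes the majority per-sample condition label (baseline / stress /
   amusement) and is dropped if the modal label covers ≤ 50 % of it.
3. **Features** — per channel and window: mean, standard deviation,
   extrema, dynamic range, slope, absolute integral, peak frequency, total
   spectral power, and first-difference statistics; plus within-device
   Pearson correlations and a full motion block (per-axis + magnitude
   features) from the accelerometer.
4. **Gated ensemble** — each *branch* is a classifier (decision tree,
   random forest, SVM or gradient boosting) over an early-fused sensor
   subset, e.g. the wrist branches WB1 = {EDA, BVP, TEMP},
   WB2 = {sweat, EDA, BVP}, WB3 = {EDA, BVP}, or one of 28 registered
   chest combinations CB1–CB28. A *gate* trained on context features
   (motion for wrist, EMG for chest) emits branch probabilities
   p₁…p_B, and the threshold b ∈ [0, 1] activates
   {i : pᵢ ≥ (1 − b)·max(p)} — b = 0 keeps only the most probable branch,
   b = 1 all of them. Active branches' class-probability vectors are
   combined by late fusion (arithmetic mean; majority voting optional).
5. **Evaluation** — accuracy and macro F1
   (F1 macro = (1/n_c) Σᵢ 2·xᵢ·yᵢ/(xᵢ+yᵢ) over per-class precision xᵢ and
   recall yᵢ) under leave-one-subject-out (LOSO) cross-validation, for the
   two-class (stress vs. non-stress) and three-class tasks.

Because public wearable-stress corpora must be downloaded separately, the
package ships a seeded multimodal simulator whose state-dependent structure
(heart-rate shifts, skin-conductance-response rates, EMG bursts,
temperature drift) lets the full pipeline run and be tested end-to-end
offline. An importer for WESAD-format subject files is included for use
with the real dataset.

## Worked example

```python
import stresscare as sc
from stresscare.pipeline import ExperimentConfig, featurize_cohort, evaluate_cohort

cfg = ExperimentConfig(seed=0)                      # wrist, 2-class, b=0.5, LOSO
cohort = sc.generate_cohort(sc.SynthConfig(n_subjects=8, master_seed=0))
subjects = featurize_cohort(cohort, cfg)
report = evaluate_cohort(subjects, cfg)

print(f"gated ensemble: accuracy={report.accuracy:.4f} macro_F1={report.macro_f1:.4f}")
for bid, m in report.branch_metrics.items():
    print(f"  {bid}: accuracy={m['accuracy']:.4f} macro_F1={m['macro_f1']:.4f}")
```

prints

```
gated ensemble: accuracy=0.9062 macro_F1=0.8960
  WB1: accuracy=0.9077 macro_F1=0.8975
  WB2: accuracy=0.9122 macro_F1=0.9026
  WB3: accuracy=0.9062 macro_F1=0.8960
```

Each of the 8 simulated subjects contributes 84 windows (672 pooled
held-out predictions). The per-branch rows are solo LOSO scores of each
sensor subset; the gated row fuses the branches the context gate activates
at b = 0.5. Here WB2 — the branch that adds the sweat channel to EDA + BVP —
is the strongest single branch, and the gate, whose supervision prefers
the cheapest sufficient branch, tracks WB3.

The same run from the shell:

```bash
stresscare simulate --out bundles/ --seed 0
stresscare run --bundles bundles/ --out results/ --seed 0
```

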