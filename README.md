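# flowskill

Optical-flow based surgical skill assessment from endoscopic video.

Objective skill assessment is a bottleneck in minimally invasive surgery
(MIS) training: expert raters are scarce, and the kinematic signals that
drive most automated assessment methods are only available on robotic
platforms. `flowskill` implements a purely 2-D, video-only alternative: the
motion of the two surgical tools is summarised by sparse optical flow and
fed to a benchmark of time-series classifiers that label each trial as
**novice**, **intermediate** or **expert**.

## Pipeline

1. **Feature extraction** (`flowskill.flow`).  On a start frame where both
   tools are visible, each user-supplied tool ROI is preprocessed
   (grayscale → median blur → adaptive threshold) and seeded with the 30
   strongest Shi–Tomasi corners, ranked by the min-eigenvalue score
   min(λ₁, λ₂) of the local gradient structure tensor.  The seeds are
   tracked through the clip with a pyramidal Lucas–Kanade solver for the
   optical-flow constraint *I_x v_x + I_y v_y + I_t = 0* (brightness
   constancy, locally constant velocity).  Every frame after the first
   yields one row of **240 features** = 2 tools × 30 points × (x, y, dx, dy).
   Lost points are carried forward with zero displacement and logged.
2. **Windowing** (`flowskill.windows`).  Per-video feature matrices are cut
   into uniform W×240 sliding windows (default 60×30, i.e. window-size ×
   step-size); each window keeps its (subject, task, trial, skill) keys.
3. **Classification** (`flowskill.classifiers`).  Six benchmark methods,
   all scikit-learn style estimators over (n, W, 240) arrays:
   CNN (two 1-D conv/BN/ReLU blocks + global average pooling + softmax),
   LSTM (two peephole-gated blocks), CNN+LSTM, a three-block residual
   network, a convolutional autoencoder whose latent codes feed a linear
   SVM, and DFT/DCT top-F frequency peaks + SVM.  Every neural model also
   exposes an SVM head fitted on its penultimate features
   (`predict(X, head="svm")`).
4. **Evaluation** (`flowskill.evaluation`).  Leave-One-Super-Trial-Out
   cross-validation: fold *i* tests on repetition *i* of every subject and
   trains on the rest, repeated over 5 runs with independent seeds.
   Summaries follow the benchmark convention — Mean (average of per-run
   means), Standard Deviation, Best run, Best trial — plus per-fold
   confusion matrices and **expert recall** = expert true positives /
   number of experts in the trial.
5. **Synthetic cohorts** (`flowskill.synth`).  Because the reference
   dataset is registration-gated, the package ships a seeded generator of
   endoscopy-like clips: two textured, corner-rich tools over a noisy
   background, with skill expressed *only* through motion statistics
   (jitter, path directness, pauses), organised as subjects × trials so
   LOSO folds are well defined.

## Worked example

```python
import numpy as np
from flowskill import (generate_cohort, extract_features, Roi, WindowParams,
                       assemble, run_protocol, FrequencySVMClassifier)
from flowskill.windows import TWO_CLASS

items, manifest = generate_cohort(n_subjects=4, trials_per_subject=3, seed=7)
features = {}
for it in items:
    fm = extract_features(it.frames, Roi("left", *it.roi_left),
                          Roi("right", *it.roi_right))
    features[(it.subject, it.task, it.trial)] = fm.values
print("feature matrix shape:", fm.values.shape)

dataset = assemble(manifest, features, WindowParams(60, 30), TWO_CLASS)["knot_tying"]
print("windowed samples:", dataset.X.shape)

result = run_protocol(dataset, FrequencySVMClassifier("dct", n_peaks=10),
                      head="svm", n_runs=5, base_seed=0)
print(result.result_table().to_string(index=False))
print("mean expert recall:", result.mean_expert_recall())
```

Output:

```
feature matrix shape: (99, 240)
windowed samples: (24, 60, 240)
Parameters Evaluation  Mean  StandardDeviation  BestRun  BestTrial
                  SVM 100.0                0.0    100.0      100.0
mean expert recall: 1.0
```

Each 100-frame clip yields a 99×240 feature matrix (one row per tracked
frame transition) and two 60-frame windows; the 4-subject toy cohort is
easy, so the DCT+SVM separates novice from expert windows in every fold of
every run, and every expert window is recognised (recall 1.0).  On the full
default cohort the methods spread out — see below.

The same pipeline is available from the shell:

```bash
flowskill all --out runs/demo --seed 1 --method resnet --class-mode two
```

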