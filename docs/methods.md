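# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `flowskill`.

## Motion features

The feature extractor treats each surgical tool as a rigid, textured patch
whose apparent motion can be sampled at a fixed set of interest points.

**Preprocessing.**  Frames are converted to grayscale, median-blurred
(kernel 5) and binarised with an adaptive local-mean threshold (block 11,
offset 2 on the 8-bit scale).  The binary image is used *only* to seed the
corner detector — thresholding sharpens trackable structure — while
tracking itself runs on the raw grayscale frames (`track_on_binary`
switches this, since either reading of the original procedure is
defensible).

**Seeding.**  Inside each tool ROI the 30 highest Shi–Tomasi responses
(min-eigenvalue of the gradient structure tensor, σ = 1) are selected with
a 2 px minimum separation.  Thirty points per tool is the unique budget
consistent with a 240-wide feature row (2 tools × 30 × 4 values); it is
configurable, but 240 columns is the validated default.  Fewer detectable
corners than requested is an error, not a warning: the downstream feature
layout needs a full set.

**Tracking.**  A pyramidal Lucas–Kanade solver (3 levels, 15×15
integration window, ≤10 iterations per level, convergence ε = 0.03) solves
the optical-flow constraint per point, coarse to fine, with bilinear
sub-pixel sampling.  A point is declared lost when its window's structure
tensor has a per-pixel minimum eigenvalue below 10⁻⁴, when it leaves the
frame, or when the update is non-finite.  Lost points freeze at their last
position with zero displacement and are never re-detected; per-video loss
counts are logged.  Displacements are raw px/frame — the frame rate is
never applied — and are stored as the exact difference of stored
positions, so displacement/position consistency is bit-exact by
construction.

On rigidly translating synthetic scenes the tracker's median displacement
error is ~0.02 px (the test suite enforces ≤ 0.5 px).

## Windowing

Feature matrices are cut per video (never across videos) into W×240
windows at stride S; the count obeys ⌊(L−W)/S⌋+1 and trailing rows are
discarded, because the classifiers need uniformly sized inputs.  Defaults
W = 60, S = 30 give 2 windows per 100-frame synthetic clip.  In two-class
mode all windows of intermediate subjects are removed before any
train/test split.  Per-feature z-scoring with training-fold statistics is
applied inside the evaluation loop (not at windowing time), so no test
information leaks into normalisation; `normalize=False` disables it.

## Classifiers

All six methods consume (n, W, 240) arrays and are deterministic given
`random_state`.

* **CNN** — Conv1D(64, k7) → BN → ReLU → Conv1D(64, k5) → BN → ReLU →
  global average pooling → dense softmax.  Same padding throughout, so
  every conv layer's output length is ⌈L/stride⌉; the implementation
  records realised input/output lengths and the tests assert the shape law
  on every instantiated layer.
* **LSTM** — two stacked 16-unit blocks.  The cell follows the peephole
  formulation: the input and forget gates see c_{t−1}, the output gate
  sees the updated c_t, all through full weight matrices; a
  framework-standard cell without peepholes is available
  (`use_peepholes=False`).  Backpropagation through time is exact and
  finite-difference checked.
* **CNN+LSTM** — two conv blocks (32 filters) feeding the two LSTM blocks.
* **ResNet** — three residual blocks (k7/k5/k3 convs with BN, 32 filters,
  1×1-conv shortcut only when channel counts differ) → GAP → softmax.
* **Conv autoencoder** — encoder Conv(32, k5, stride 2) → ReLU →
  Conv(16, k3) → ReLU; decoder mirrors with nearest-neighbour upsampling;
  trained on mean squared reconstruction error; classification exclusively
  via a linear SVM on the flattened latent code.  The constructor rejects
  latent sizes that do not compress the input.
* **DFT/DCT + SVM** — each window is transposed to 240 univariate series;
  the row-wise DFT (Y_k = Σ x_l e^{−i2πkl/L}) or type-III DCT
  (Y_k = x₀/2 + Σ_{l≥1} x_l cos[πl(k+½)/L]) is reduced to the F = 10
  largest-magnitude coefficients per row ("highest peaks" read as largest
  |Y_k|, ties to the lower frequency), concatenated row-major and fed to a
  linear SVM.

**Training.**  Adam with L2 weight decay 10⁻⁴ (weights only), softmax
cross-entropy, early stopping on the training-loss plateau with
lowest-loss weight restore.  CNN/ResNet use lr 3·10⁻³, batch 16,
≤100/≤30 epochs; the LSTM-bearing models proved sensitive to training
noise and use a dedicated recipe — hidden 16, batch 8, lr 1.5·10⁻³,
forget-gate bias initialised to 1, global gradient-norm clipping at 5, and
plateau-triggered lr halving — chosen for stable convergence.  Every
neural model fits a linear SVM (C = 1) on its penultimate features
(GAP output, final hidden state, or latent code) so predictions can use
either the softmax head or the SVM head on identical features.

## Evaluation protocol

A *super-trial* is the i-th repetition of the task across all subjects.
`loso_split` builds T folds for T repetitions; fold i tests on repetition
i of every subject.  This measures generalisation across attempts while
every subject is seen in training — complementary to leave-one-user-out.
The full protocol runs the cross-validation `n_runs = 5` times, run r
seeded with `base_seed + r`.  Accuracy is per-window (each W×240 sample
votes independently); per-trial aggregation can be layered on top by the
caller.  Summaries: **Mean** = average of per-run mean accuracies, **SD**
over the run means, **Best run** = highest per-run mean, **Best trial** =
highest single-fold accuracy.  Expert recall is reported as missing (not
zero) for folds without expert samples, and `zero_tp_census` counts
confusion matrices with zero true/false positives per class — the
diagnostic that exposes classifiers that ignore the minority class.

## Synthetic data

The generator emulates the statistical structure the classifiers must
exploit, not the appearance of real endoscopy.  Each clip is 160×120 px ×
100 frames with two tools (radius 18 px) carrying a smooth sinusoidal
grid texture (period 4.5 px) whose binarised form is rich in Shi–Tomasi
corners; the background is uniform gray with Gaussian noise (σ = 0.02).
Trajectories follow goal-directed drift blended with a smoothly wandering
heading, plus Gaussian jitter and random pauses:

| skill        | jitter σ (px/frame) | directness | pause prob |
|--------------|--------------------:|-----------:|-----------:|
| novice       | 2.5                 | 0.35       | 0.15       |
| intermediate | 1.2                 | 0.65       | 0.07       |
| expert       | 0.4                 | 0.95       | 0.02       |

The ≥5× novice/expert jitter ratio makes the summed step-length
distributions disjoint (asserted over 50 seeds), so a correct pipeline
*should* separate the extreme classes nearly perfectly; the intermediate
class overlaps both neighbours by design.  The default cohort is 8
subjects (3/2/3 novice/intermediate/expert) × 5 trials of one task, one
skill per subject, mirroring the structure of real training cohorts.  All
outputs are pure functions of the seed.

What the generator does **not** model: occlusion, specular reflection,
smoke, camera motion, background tissue motion, tools entering or leaving
the field, appearance differences between skill levels.  Passing tests on
this data therefore certify the machinery (tracking fidelity, feature
layout, fold hygiene, trainability) — not clinical performance.  The
three-class problem stays genuinely hard here (~65% LOSO accuracy for
ResNet) because intermediate motion statistics overlap both neighbours,
echoing how intermediate surgeons are the dominant error source on real
data.

One empirically notable behaviour: training the conv autoencoder *longer*
degrades its downstream accuracy on this data, because reconstruction
under temporal compression progressively discards the high-frequency
jitter that carries the class signal.  The single-downsample encoder keeps
it competitive, but it remains the weakest method here (~0.6 two-class
accuracy), while the frequency methods — which measure exactly that
high-frequency energy — are the strongest (~1.0).  On real data this
ordering reportedly reverses; the synthetic cohort's signal is more
spectrally concentrated than real tool motion.

## Numerical choices and degenerate inputs

* Coordinates are 0-based pixels, x rightward, y downward, sub-pixel
  floats; ROIs are half-open `[x, x+w) × [y, y+h)`.
* Adaptive thresholding normalises float frames to the 8-bit scale so the
  offset parameter has fixed units.
* The LK structure tensor is inverted in closed form; singular tensors
  (det ≤ 10⁻¹²) freeze the update and flag the point.
* Frequency-peak ties break toward the lower frequency index (stable
  sort), making the reduction deterministic.
* Batch-norm running statistics use momentum 0.9 and are restored together
  with weights on early stopping.
* `slide` raises (naming L and W) rather than padding short matrices;
  ragged trial counts likewise abort fold planning.

## Limitations

* No re-detection or re-acquisition: a tool that leaves the frame stays
  lost, exactly like the procedure this package mirrors.
* No camera-motion compensation or semantic tool segmentation.
* Hyperparameters were fixed once for stable training on the synthetic
  cohort, not tuned per task; numeric parity with any external benchmark's
  published tables is out of scope because those hyperparameters are not
  published.
* MP4 input is supported through imageio when a suitable plugin is
  present; the PNG-frame-directory format is the tested, dependency-free
  path.
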