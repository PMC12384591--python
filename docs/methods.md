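# Methods

## Problem and pipeline

The package classifies short EEG windows into affective states and then asks
which electrodes the classifier actually relies on. The pipeline is:

1. **Baseline correction.** Each trial carries a 3 s pre-stimulus baseline
   (384 samples at 128 Hz). The baseline is cut into N consecutive
   channels × L segments (L = 128, so N = 3 for the native layout), averaged
   element-wise into a template matrix M, and M is subtracted from every
   channels × L block of the 60 s stimulus region. The correction removes
   stimulus-independent per-channel structure (DC offsets, slow drifts) that is
   shared between baseline and stimulus.
2. **Windowing and labelling.** The corrected stimulus is sliced into 60
   non-overlapping 32 × 128 windows, each inheriting its trial's label. Labels
   come from 1–9 self-ratings thresholded at 5 (≤ 5 low, > 5 high), giving
   binary arousal, binary valence, or four arousal × valence quadrants
   (LALV/HALV/LAHV/HAHV). The threshold is evaluated on the float rating, so
   a rating of exactly 5 is "low" and 5.01 is "high".
3. **Classification.** A 2-D CNN treats each window as a 128 (time) × 32
   (electrode) image: six 5 × 5 stride-1 zero-padded convolutions
   (32, 32, 64, 64, 64, 128 filters), (2,1) max pooling after conv3 and conv6
   (temporal axis 128 → 64 → 32; the electrode axis is never pooled), then a
   131,072-long flatten, a 512-unit fully connected layer, and an N-way
   softmax head. Regularisation: structured dropout (whole feature maps, keep
   probability 0.5) after conv1/conv3/conv4/conv6 and fc1; batch normalisation
   after conv2/conv4/conv5 and fc1; L2 weight decay in the loss; a learning
   rate of 1e-3 halved every 50 epochs; residual links conv1→conv3 and
   conv4→conv6; 10-fold cross-validation for evaluation. Training uses Adam
   with batch size 240 on softmax cross-entropy.
4. **Attribution.** Gradient-weighted class activation mapping on the final
   convolutional layer (conv6, before the second pooling, so feature maps are
   64 × 32 × 128): the gradient of the class **logit** (not the softmax
   probability) w.r.t. each feature map is global-average-pooled into a weight
   α_k = (1/Z) Σ_ij ∂y_c/∂A^k_ij with Z = H·W; the α-weighted sum of feature
   maps is ReLU-clipped and bilinearly upsampled to the 128 × 32 input grid.
5. **Channel scoring, selection, stability.** Each heatmap is averaged over
   time into one value per electrode; per class these are averaged over that
   class's windows and min-max scaled to [0, 1] (the Normalized Contribution
   Score). Electrodes scoring strictly above a per-task threshold (0.5 for
   quaternary and valence, 0.6 for arousal) in any class's vector are
   "high-contribution" (the reported channel list is the union over classes).
   Stability is probed by recomputing the per-class pipeline on random subsets
   drawn without replacement and reporting the Pearson correlation between the
   subset's stacked per-class score vectors and the full-data ones.

## Numerical and design choices

- **Numpy/numba network.** The network, its training loop and its gradients
  are implemented directly on numpy arrays, with the convolution inner loops
  compiled by numba (a pure-numpy fallback exists). This keeps the exact
  quantity Grad-CAM needs — ∂ logit/∂ conv6 activations — available from the
  same backward pass that trains the model, and the test suite verifies it
  against central finite differences at 1e-3 relative tolerance.
- **Residual projections.** The two skip connections join filter banks of
  different widths (32→64, 64→128), so the skip path uses a 1 × 1 convolution
  projection, added to the target convolution's output before its ReLU. The
  source of each skip is its block's output (after activation and dropout).
- **Block ordering** is conv → batch norm (where present) → ReLU → dropout
  (where present), the common convention; placements follow the architecture
  table, ordering is a package choice.
- **Dropout semantics.** "Keep probability 0.5" is retention probability; conv
  dropout uses noise shape (N, C, 1, 1) so entire feature maps deactivate.
- **Loss.** Softmax cross-entropy plus `l2_coeff · Σ‖W‖²` over conv/dense
  weight matrices (biases and batch-norm scales are not penalised). Defaults
  `l2_coeff = 1e-4`, `epochs = 200` (two decay steps) are package choices
  surfaced as configuration; weight init is fan-in-scaled He with a recorded
  seed.
- **Bilinear convention.** Upsampling uses half-pixel centers without corner
  alignment; a brute-force interpolation oracle in the tests pins this choice.
  Constants stay constant and non-negativity is preserved.
- **Normalization.** Min-max scaling is applied per class vector; a constant
  vector maps to all zeros and is flagged degenerate rather than raising.
  Whether to analyse per-class vectors or a pooled task vector is a genuine
  fork: the stability analysis stays per class (it reruns the per-class
  aggregate/normalize/select pipeline on each subset; pooling first would let
  one class's top-channel rescaling dominate), while the facade's `summary()`
  and default `select_channels()` use a pooled task vector — the mean of the
  per-class normalized vectors, re-scaled to [0, 1] — which reads better as a
  single ranking. Scores are invariant to any positive rescaling of the
  heatmaps, matching the scale covariance of the attribution map itself.
- **Selection** uses strict inequality (score > threshold). Subsets for the
  stability analysis are drawn without replacement from a seeded generator;
  the full-data row closes each report with PCC = 1 by construction.
- **Cross-validation** pools windows from all trials (seeded shuffle,
  `sklearn` K-fold); `group_by` trial/subject folds are available for the
  stricter leakage-free protocol. Fold accuracies aggregate with the
  arithmetic mean and the population (divide-by-n) standard deviation — the
  convention is pinned in the tests by reproducing the published summary rows
  from the published per-fold values (the n−1 convention fails that check).
- **DEAP reader.** The preprocessed per-subject pickle stores ratings with
  valence in column 0 and arousal in column 1 (dataset documentation); only
  the first 32 of 40 channels are EEG and are kept. The montage (channel index
  → 10–20 electrode name) ships as an editable CSV rather than code.

## The synthetic generator

Real DEAP data is access-gated, so every stage is exercised on synthetic
trials that copy the native layout exactly: 32 channels × 8064 samples at
128 Hz, the first 384 samples being baseline, ratings drawn so thresholding at
5 reproduces the intended quadrant (low ratings uniform on {1..5}, high on
{6..9}).

Class information is planted as band-limited oscillatory power on a chosen
channel subset (default F4 and FC6, i.e. indices 19 and 21): a 10 Hz sinusoid
whose amplitude encodes the arousal level and a 20 Hz sinusoid encoding the
valence level, added only after stimulus onset. The two carriers are assigned
round-robin across the planted channels (F4 gets the arousal code, FC6 the
valence code for the default pair; a single planted channel carries both), and
each channel draws its own random phase per trial. Both choices exist for
identifiability of the per-channel recovery claim: if every planted channel
carried the complete class code, a classifier could read one channel and
ignore the rest, and attribution to the ignored channels would rightly be
near zero; phase-locked duplicates would additionally be interchangeable.
Amplitudes are distinct and nonzero per level,
`1.5 · effect_size · noise_sd` for "high" and `0.5 · effect_size · noise_sd`
for "low", so every class (including the low/low quadrant) leaves
class-relevant band power on the planted channels and class-conditional
attribution is well-posed for all four quadrants. This sits
on white Gaussian noise (sd 1) everywhere and a per-channel DC offset (sd 1)
shared by baseline and stimulus — the latter makes baseline subtraction
demonstrably useful. `effect_size = 2` is the default study condition;
`effect_size = 0` removes the oscillations entirely and produces a null
dataset with no class information anywhere. A single root seed fans out to one
substream per trial, so datasets are bit-reproducible.

What the generator does **not** emulate: volume-conducted scalp topographies
(signal appears only on the planted channels, with no spatial spread), ocular
or muscle artifacts, 1/f background spectra, non-stationarity, inter-subject
variability, or the 8 peripheral physiological channels. Tests passing on this
generator therefore certify the arithmetic and the recovery machinery — that
planted discriminative channels are found — not performance on real EEG.

## Problem sizes used in tests and the acceptance script

The canonical architecture (Table-sized, 131,072-long flatten) is always built
and shape-checked, and the attribution equations are tested on it. Training
runs use a width-reduced spec with the same topology, pooling, residual links
and regularisers. The planted-recovery experiment uses filters
3, 3, 6, 6, 6, 12 with fc1 = 48: the attribution layer needs a minimum number
of feature maps — with very few (8 at width 2) the ReLU-clipped weighted sum
can collapse to a near-zero map on some training runs even when classification
is perfect, a small-K failure mode that the canonical 128 maps never shows.
It trains on 200 windows per class (from 5 trials per quadrant) for 30 epochs
at three seeds with batch size 120 — the published 240 is calibrated to runs
three orders of magnitude larger; on 800 windows it leaves only four optimizer
steps per epoch and training can stall inside the epoch budget — evaluates on
all 1200 windows, and runs the stability analysis at subset sizes
100/500/1000. The null control uses binary arousal, 5 trials
per quadrant, width 2, and 5-fold CV at 5 epochs with folds grouped by trial:
in null data the only exploitable structure is the baseline-template noise
shared by a trial's 60 windows, and window-level folds would let the network
convert that into trial-identity memorization (measurably above chance), which
is a property of the pooled protocol on trial-structured data, not class
leakage in the pipeline. Under these conditions the CNN reaches > 90 % window
accuracy, ranks both planted electrodes above the median non-planted score,
keeps them selected in every subset with PCC ≥ 0.8 against the full-data
vector, and stays within 5 points of chance when the effect size is zero.

## Known limitations

- Training accuracy recorded in the per-epoch history is measured in training
  mode (with dropout active); `accuracy()`/`predict()` evaluate in inference
  mode.
- The pooled-window CV protocol places windows of one trial in both train and
  test folds; with per-trial structure in real data this inflates accuracy.
  The `group_by` option exists for the conservative protocol.
- Max pooling and ReLU make the logit piecewise linear; at tie points the
  reported gradient is a one-sided subgradient (finite-difference checks avoid
  those measure-zero points).
- Determinism guarantees are per platform/BLAS build: the same seed reproduces
  the same run on the same machine.
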