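# eegcam

Interpretable EEG emotion classification: a 2-D convolutional network over
baseline-corrected EEG windows, explained with gradient-weighted class
activation mapping (Grad-CAM) to identify, select and stability-test the
electrodes that drive the classification.

## Who this is for

Researchers in affective computing / BCI who want, beyond a window-level
arousal/valence classifier, a quantitative answer to *which electrodes matter*
— e.g. to shrink a 32-channel montage to a wearable subset. The package
natively supports the preprocessed-DEAP trial layout (per subject: 40 trials ×
32 EEG channels × 8064 samples at 128 Hz, 3 s baseline + 60 s stimulus,
per-trial 1–9 arousal/valence ratings) and ships a synthetic generator that
emulates exactly that layout with class-discriminative signal planted on known
channels, so the whole pipeline is testable without any gated download.

## The method

**Preprocessing.** Per trial, the 32 × 384 baseline is split into three
32 × 128 segments and averaged into a template M; M is subtracted from each of
the sixty 32 × 128 stimulus windows. Labels threshold the ratings at 5
(≤ 5 low, > 5 high): binary arousal, binary valence, or four quadrants
(LALV/HALV/LAHV/HAHV).

**Network.** Windows are 128 (time) × 32 (electrode) images fed to six 5 × 5
convolutions (32, 32, 64, 64, 64, 128 filters) with (2,1) max pooling after
conv3 and conv6 (time 128 → 64 → 32), residual links conv1→conv3 and
conv4→conv6, a 131,072-long flatten, a 512-unit dense layer and an N-way
softmax head; structured dropout (keep 0.5), batch norm, L2 weight decay, Adam
at lr 1e-3 halved every 50 epochs, batch size 240, 10-fold cross-validation.

**Attribution.** For class *c*, Grad-CAM weights each conv6 feature map A^k by
the spatially averaged gradient of the pre-softmax logit,

    α_k^c = (1/Z) Σ_ij ∂y_c/∂A^k_ij ,   Z = H·W,
    L^c = ReLU( Σ_k α_k^c A^k ),

bilinearly upsampled to 128 × 32. Averaging L^c over time and over each
class's windows, then min-max scaling to [0, 1], gives each electrode a
**Normalized Contribution Score**; electrodes above a per-task threshold
(0.5 quaternary/valence, 0.6 arousal) form the selected subset, and Pearson
correlations between subset-recomputed and full-data score vectors quantify
the stability of that selection.

The CNN, its training loop and the exact logit gradients are implemented in
numpy with numba-compiled convolution kernels — the same backward pass that
trains the model supplies the gradients Grad-CAM needs, and the test suite
checks them against finite differences.

## Worked example

```python
from eegcam import EmotionClassifier, NetworkSpec, PlantSpec

plant = PlantSpec(planted_channels=(19, 21), effect_size=2.0, seed=1)  # F4, FC6
spec = NetworkSpec.scaled(4, width=3, batch_size=120)  # CPU-sized; NetworkSpec.canonical(4) is the full net
clf = EmotionClassifier.from_synthetic(plant, n_per_class=5, task="quaternary", spec=spec)
res = clf.fit(seed=0, epochs=30)
print(res.summary())
print("selected:", res.select_channels().channels)
```

prints (numbers from this exact run):

```
EEG emotion classifier (2D CNN + Grad-CAM attribution)
========================================================
task:            quaternary (4 classes)
windows:         1200 of shape 32x128 (channels x time)
conv filters:    [3, 3, 6, 6, 6, 12]  fc1: 48
epochs run:      30  final loss: 0.5026
accuracy:        100.00 % (training windows, inference mode)
top electrodes:  F8 (1.00), FC6 (0.88), Fz (0.77), Cz (0.72), F3 (0.69), P8 (0.67), F4 (0.65), F7 (0.58)
selected: ('F3', 'F7', 'Fz', 'F4', 'F8', 'FC6', 'FC2', 'Cz', 'P8')
```

Both planted electrodes (F4, FC6) clear the selection threshold and sit well
above the median score; immediate neighbours such as F8 absorb part of the
credit because 5 × 5 kernels mix adjacent channel columns — channel-level,
not single-electrode, localisation is what the method promises. The
`summary()` accuracy is window-level top-1 in inference mode. From `res` you
can also get `activation_maps()` (per-window 128 × 32 heatmaps),
`contributions()` (per-class scores), `subset_stability([100, 500, 1000])`
(channel lists + PCC per subset size, as a dataframe), and
`plot_contributions()`.

A command-line interface mirrors the library:
`eegcam simulate | preprocess | train | crossval | explain | attribute |
select | stability | reproduce-synthetic` (see `eegcam --help`). Real DEAP
subject files (`s01.dat`, …) are read with `eegcam.io.read_deap_subject`; the
benchmark run on DEAP itself requires the access-gated download and is a
documented manual workflow, not part of the test suite.

## Layout

```
src/eegcam/
  io.py           trial containers, DEAP reader, labelling, montage, CSV output
  synth.py        DEAP-layout synthetic trials with planted discriminative channels
  preprocess.py   baseline-template subtraction and windowing
  nn/             numpy/numba CNN: layers, architecture, training, persistence-ready
  gradcam.py      class activation maps (activations, gradients, pooling, upsampling)
  attribution.py  contribution scores, channel selection, subset stability
  pipeline.py     k-fold protocol, aggregation, manifests, model persistence
  model.py        EmotionClassifier / EmotionClassifierResults facade
  cli.py          command-line interface
docs/methods.md   model assumptions, numerical choices, limitations
```
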