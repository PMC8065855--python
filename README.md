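# hypnonet

Automatic sleep stage classification from raw single-channel EEG, built as
a tested, CPU-only Python library with a command-line interface.

Sleep scoring assigns one of the five AASM stages — W (wake), N1, N2, N3
and REM — to every 30-second epoch of an overnight EEG recording.  Manual
scoring is slow and rater-dependent; automatic scoring must cope with raw,
unfiltered microvolt signals, a heavy class imbalance (N2 and W dominate,
N1 is rare), and the fact that stages form long bouts whose *transitions*
carry diagnostic structure.  This package is aimed at sleep-research and
biosignal-ML practitioners who want a transparent, fully inspectable
implementation of a modern staging pipeline that runs end to end on a
laptop.

## The model

The classifier is a three-level hybrid network over raw 30-s epochs
(3000 samples at 100 Hz), trained with machinery chosen for sleep data:

* **Frame level** — two parallel 1-D convolutions with very different
  kernels (25 and 100 taps; short kernels resolve fast rhythms such as
  spindles, long kernels slow delta waves), each max-pooled so that
  `pool x stride` is equal across branches and both land on the same
  125-step time axis; their concatenation feeds a **multiscale atrous
  convolution block (MSACB)**: four branches of depth 1–4 whose dilated
  kernel-3 convolutions (rates 1, 2, 4) grow the receptive field to 15
  taps at almost no parameter cost.
* **Epoch level** — a CNN path (1x1 bottleneck to 128 channels, max-pool,
  kernel-3 convolution to 1024 channels, global average pooling) for
  time-invariant waveform features, in parallel with a Bi-GRU path (1x1
  bottleneck, avg-pool, 512 hidden units per direction) for time-varying
  structure.
* **Sequence level** — per-epoch features (1024 from a frame-level skip
  path + 1024 CNN + 1024 Bi-GRU = 3072) for a run of L = 25 epochs flow
  through a two-layer Bi-LSTM (512 hidden units per direction) with a
  pointwise residual full connection and a softmax head, modelling the
  hypnogram's stage-transition dynamics.

Every activation is Mish, `f(x) = x · tanh(log(1 + e^x))`.  Training is
two-staged: the frame and epoch levels are **pretrained** on i.i.d.
class-balanced, augmented epochs (random cyclic shift + mirror), then the
whole network is **fine-tuned** on transition-balanced sequences with the
subnetwork nearly frozen (learning rate 1e-6) while the sequence level
follows a decaying schedule (1e-3 → 1e-4 → 5e-5 → 1e-5 every 10 passes).
Both stages minimise the focal loss

```
FL(p) = − α_y · (1 − p_y)^γ · log(p_y),      γ = 2,  α ∝ 1 / class frequency
```

with the AMSGrad optimiser (β₁ = 0.9, β₂ = 0.99).  Evaluation pools
subject-wise k-fold predictions into one 5x5 confusion matrix and reports
per-class precision/recall/F1, overall accuracy (ACC), macro-F1 (MF1) and
Cohen's κ.

Because no deep-learning framework is assumed, the network runs on a
small NumPy reverse-mode autodiff engine included in `hypnonet.nn`, with
gradients verified against finite differences in the test suite.

A synthetic polysomnography generator (`hypnonet.synthetic`) produces
Markov hypnograms with realistic bout lengths and class imbalance plus
stage-dependent oscillatory EEG, written as Sleep-EDF-dialect EDF/EDF+
files, so the entire pipeline is exercisable with no data download.

## Worked example

Score the published pooled confusion matrix of a 20-fold sleep-cassette
benchmark run (Fpz-Cz channel; rows = true W, N1, N2, N3, REM):

```python
import numpy as np
from hypnonet.metrics import ConfusionMatrix, overall_metrics, per_class_metrics

cm = ConfusionMatrix(np.array([
    [6761,  781,   183,   21,  181],
    [ 250, 1582,   579,    4,  389],
    [ 184,  635, 15638,  507,  835],
    [  19,    8,   747, 4919,   10],
    [  51,  306,   900,    0, 6460],
]))
acc, mf1, kappa = overall_metrics(cm)
print(f"ACC {acc}  MF1 {mf1}  kappa {kappa}")
for stage, (pre, re, f1) in per_class_metrics(cm).items():
    print(f"{stage:>4}  Pre {pre:6.2f}  Re {re:6.2f}  F1 {f1:6.2f}")
```

```
ACC 84.29  MF1 79.81  kappa 0.78
   W  Pre  93.06  Re  85.29  F1  89.01
  N1  Pre  47.77  Re  56.42  F1  51.73
  N2  Pre  86.65  Re  87.86  F1  87.25
  N3  Pre  90.24  Re  86.25  F1  88.20
 REM  Pre  82.03  Re  83.71  F1  82.86
```

ACC is the fraction of correctly scored epochs, MF1 the unweighted mean of
the five F1 scores (so rare N1 counts as much as dominant N2), and κ the
agreement corrected for chance.  The low N1 row is the field's perennial
difficulty: N1 is rare and transitional.

Train the full pipeline at desk scale on synthetic nights (about a minute
on one CPU; `ModelConfig.tiny()` shrinks every width, the reference
architecture is the default `ModelConfig()`):

```python
from hypnonet import SleepStageClassifier
from hypnonet.io import load_recording, trim_wake
from hypnonet.model import ModelConfig
from hypnonet.sampling import SamplerConfig
from hypnonet.synthetic import generate_dataset
from hypnonet.train import TrainSchedule
from hypnonet.metrics import confusion_matrix, overall_metrics

paths = generate_dataset(4, 200, seed=0, out_dir="edf", pad_epochs=20)
recs = [load_recording(paths[2*i], paths[2*i+1], "EEG Fpz-Cz")
        for i in range(4)]

clf = SleepStageClassifier(
    config=ModelConfig.tiny(),
    pretrain_schedule=TrainSchedule.pretrain_default(passes_total=20,
                                                     batch_size=64, seed=0),
    finetune_schedule=TrainSchedule.finetune_default(passes_total=8,
                                                     batch_size=4, seed=0),
    sampler=SamplerConfig(seq_len=10, rng_seed=0),
    margin_minutes=5, seed=0,
).fit(recs[:3])

held_out = trim_wake(recs[3], 5)
acc, mf1, kappa = overall_metrics(
    confusion_matrix(clf.staged_labels([held_out]), clf.predict([held_out])))
print(f"held-out subject: ACC {acc}%  MF1 {mf1}  kappa {kappa}")
```

```
held-out subject: ACC 98.33%  MF1 76.98  kappa 0.97
```

The synthetic stages are separable by construction, so a tiny model scores
a held-out synthetic subject far above its 44% majority-class baseline;
this demonstrates the pipeline mechanics, not clinical performance.

The same steps are scriptable from the shell:

```bash
hypnonet synth --subjects 4 --epochs 200 --seed 0 --out edf/
hypnonet prepare --edf-dir edf/ --channel "EEG Fpz-Cz" --out epochs.npz
hypnonet pretrain --data epochs.npz --passes 20 --seed 0 --out pre.npz
hypnonet finetune --checkpoint pre.npz --edf-dir edf/ --seed 0 --out model.npz
hypnonet evaluate --counts confusion.csv
hypnonet summary
```

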