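# Methods

This note records the scientific and numerical choices behind the
package: the model and its assumptions, the parameters that matter, what
the synthetic data does and does not emulate, and the decisions taken
where the design was genuinely open.

## Signal model and levels

Raw single-channel EEG is treated at three nested time scales.  A *frame*
is the quasi-stationary sub-second window seen by a strided convolution
kernel; an *epoch* is the 30-s scoring unit (3000 samples at the 100 Hz
reference rate); a *sequence* is a run of consecutive epochs (reference
length L = 25) over which stage-transition structure is learned.  The
input contract is deliberately raw: no filtering, artifact rejection,
re-referencing or amplitude rescaling is applied anywhere — amplitudes
pass through in the microvolts stored in the EDF.

## Architecture

**Frame level.**  Two parallel convolutions with kernels 25 and 100 taps
capture fast and slow rhythms.  Kernel size and stride are positively
correlated (defaults 3 and 12) and each branch is max-pooled (8 and 2)
under the constraint `small_pool x small_stride == large_pool x
large_stride`.  With "same" padding and ceiling length division this
identity guarantees equal branch lengths for *any* input length (nested
ceilings collapse: ceil(ceil(T/s)/p) = ceil(T/(s·p))), so the constraint
is validated once at configuration time and can never fail at forward
time.  At 100 Hz both branches emit 125 time steps per epoch.  The
concatenation (128 channels) passes through dropout and the MSACB: four
branches of depth 1–4, each opened by a 1x1 convolution to N = 32
channels, deeper branches stacking kernel-3 dilated convolutions with
rates (1, 2, 4) in order.  The deepest branch therefore sees
1 + 2·(1+2+4) = 15 taps.  Branch outputs concatenate back to 128
channels; time length is always preserved.

The exact strides, pools, N and dilation rates are open parameters of the
architecture family; the defaults above were fixed once for this
implementation (they satisfy the equal-product rule and keep the time
axis long enough for the recurrent epoch branch) and are all exposed in
`ModelConfig`.

**Epoch level.**  The frame features split into a CNN branch (1x1 conv to
128 channels, max-pool 5, kernel-3 conv to 1024 channels, global average
pooling) and an RNN branch (separate 1x1 conv to 128, avg-pool 5, Bi-GRU
with 512 units per direction; the final step of the forward pass and the
final step of the backward pass concatenate to 1024).  Max-pooling feeds
the CNN the most salient evidence; avg-pooling preserves detail for the
recurrence.  The epoch-level pool size (5, giving the GRU 25 steps) is an
implementation choice, config-exposed; nothing forces the two pool sizes
equal, they simply share the default.

**Sequence level.**  A skip path (1x1 conv to 1024 + GAP on the frame
features) joins the two epoch-level vectors to a 3072-wide per-epoch
feature.  The skip serves two purposes: frame information reaches the
classifier directly, and sequence-loss gradients supervise the earliest
convolutions (asserted by a gradient-flow test).  Sequences of these
features pass through a two-layer Bi-LSTM (512 per direction → 1024 per
step), a residual 1024-unit full connection of the input added pointwise,
and a final full connection with softmax.  Dropout (keep 0.5) is applied
after the frame concatenation, after the 3072-wide feature, and between
the Bi-LSTM layers; it is disabled at inference, so evaluation passes are
deterministic.

**Activation.**  Mish, `x · tanh(softplus(x))`, after every convolution
(the residual full connection and the classifier heads stay linear).  The
softplus uses `logaddexp`, so the function is stable to |x| = 1e4 and
beyond.  Mish passes small negative values, which suits zero-mean raw
EEG.

**Initialisation.**  Variance-scaling normal for convolutions and full
connections, orthogonal recurrent kernels, zero biases, all drawn from a
single seed.  One adjustment: the two first-layer convolution weight
tensors are divided by `input_rms` (default 25, the nominal microvolt RMS
of scalp EEG) so first activations start O(1) despite the raw input scale.
This touches only the starting point of optimisation, not the data.

## Training machinery

**Imbalance.**  Pretraining upsamples every class (with replacement) to
the majority count.  Fine-tuning balances *transitions*: every candidate
length-L window receives a sequence label, classes are randomly
downsampled to `floor(min_count × sampling_factor)` windows, and each
retained window is replaced by one intercepted uniformly within
± L/2 epochs of its start (clipped at bounds).  Two points were open and
resolved here: the sequence label of a window is the stage of its *final*
epoch (the prediction anchor in sequence classification), and the emitted
window inherits its anchor's label for book-keeping, so per-class counts
stay exactly balanced while the signal content regains local variety.
Candidate windows overlap (all valid starts compete); `sampling_factor`
defaults to 1.0.

**Loss.**  Focal loss with γ = 2 and inverse-frequency α normalised to
mean 1, averaged over samples and sequence positions (averaging keeps
learning rates transferable across batch sizes).  The true-class
probability is floored at 1e-12 inside the log.  γ = 0 with unit α
recovers cross-entropy exactly, which the tests use as an oracle.

**Optimisation.**  AMSGrad (Adam keeping the running maximum of
second-moment estimates; β₁ = 0.9, β₂ = 0.99 — kept at 0.99 rather than
the conventional 0.999 by design, matching the reference protocol) with
Adam-style bias correction.  Gradients are clipped at global norm 5.0 as
a divergence guard (set `grad_clip=None` for the strict unguarded
protocol).  An L2 penalty (coefficient 1e-3, config-exposed) is applied
to both first-layer convolution weight tensors — they are the two
parallel halves of "the first layer".

**Protocol.**  Stage 1 pretrains frame + epoch levels under an i.i.d.
assumption through an auxiliary 3072 → 5 softmax head (discarded
afterwards): learning rate 1e-3 for 40 passes over the training set, then
1e-4 for 40 more; batch 256; cyclic-shift and mirror augmentation per
batch.  "Iterations"/"rounds" are read as full passes — any other reading
collapses the schedule to seconds of training.  Stage 2 fine-tunes the
whole network on sampled sequences with two parameter groups: the
pretrained subnetwork fixed at 1e-6 and the sequence level on
1e-3 → 1e-4 → 5e-5 → 1e-5, stepping every 10 passes; batch 10; no
augmentation (the sequence level must see genuine transition statistics).
Cross-validation splits subjects — never epochs — into k folds
(round-robin after a seeded shuffle), and fold predictions are pooled
into a single confusion matrix rather than averaging per-fold metrics.

## Evaluation conventions

Metrics are computed in full precision from integer counts and rounded
half-up to two decimals only at reporting.  A class absent from the
predictions takes precision 0 (hence F1 0).  κ = (p_o − p_e)/(1 − p_e);
p_e = 1 can only occur when both marginals concentrate on the same class,
which forces p_o = 1, so κ is reported as 1 there.  The engine is
cross-checked against scikit-learn on random matrices to 1e-10 and
reproduces every per-class and overall value of the two benchmark count
matrices exactly at the printed precision.

## Synthetic data

Hypnograms are first-order Markov chains parameterised by per-stage mean
bout lengths (p_self = 1 − 1/mean_bout; defaults 20, 4, 15, 10, 12 epochs
for W, N1, N2, N3, REM — minutes-long bouts, short N1 transitions) with a
jump distribution tuned so the stationary distribution approximates the
canonical sleep-cassette imbalance (W 19%, N1 7%, N2 42%, N3 14%,
REM 18%).  Signals are sums of band-limited sinusoids with stage-specific
bands (alpha-dominant W, theta N1, theta + 12–14 Hz spindle bursts in N2,
delta-dominant N3, mixed theta/beta REM), amplitude scale 20 µV, Gaussian
noise σ = 5 µV.  Files are written as 16-bit EDF (physical range
±250 µV, the Sleep-EDF quantisation) plus EDF+ hypnograms in the
Sleep-EDF annotation dialect; long N3 runs are written as S3 followed by
S4 so the legacy-label merge is always exercised; nights are book-ended
with wake so peripheral-wake trimming has work to do.

What passing tests on this generator show: the pipeline's plumbing,
balancing, optimisation and evaluation behave correctly on data with the
right *statistical shape*.  What they do not show: clinical accuracy.
The synthetic EEG has no artifacts, no waveform morphology beyond
sinusoids, no inter-subject variability, and its stages are separable by
construction.

## Degenerate inputs and edge rules

Movement/unknown epochs have no AASM class and are excluded via a
validity mask (kept out of training, sampling windows and scoring).
A trailing partial epoch is dropped with a logged warning; hypnogram vs
signal length disagreement beyond one trailing epoch is an error.  The
"30 min of peripheral wake" rule is 60 epochs of index arithmetic before
the first and after the last non-wake epoch, clipped at bounds; an all-
wake recording is an error.  Epoch indexing is 0-based with half-open
sample intervals.

## Problem sizes

The test suite and the acceptance script run the reference architecture
only for shape/parameter contracts and train the `tiny` configuration
(about 14k parameters) on small synthetic cohorts: 120 two-class epochs
for the separability check, 3–4 nights of 150–200 epochs for the
two-stage protocol, 30 or fewer passes.  These sizes were chosen so a
full verification runs in minutes on a single CPU core; the training
*dynamics* asserted (descent, held-out improvement, schedule traces) are
size-independent properties of the implementation.

## Known limitations

Single-channel input only; no attention, complex-valued or orthogonality-
constrained variants; no hyperparameter search, mixed precision or
distributed training; the NumPy autodiff engine is single-threaded and
sized for desk-scale experiments, not for reproducing full 20-fold
benchmarks on real recordings.  Reported benchmark-scale numbers in this
repository are always recomputed from published count matrices, never
from training runs.
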