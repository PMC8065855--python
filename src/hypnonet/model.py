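"""Three-level hybrid sleep-staging network.

The network reads a raw 30-s single-channel EEG epoch and classifies it
into one of the five AASM stages, using three nested time scales:

* **frame level** — two parallel strided convolutions with very different
  kernels (short kernels resolve fast rhythms, long kernels slow waves),
  each max-pooled so both branches land on the same time axis, followed by
  a multiscale atrous convolution block (MSACB) whose four branches of
  increasing depth grow the receptive field with dilated kernels;
* **epoch level** — a CNN path (1x1 bottleneck, max-pool, kernel-3 conv,
  global average pooling) extracting time-invariant waveform features and
  a parallel Bi-GRU path (1x1 bottleneck, avg-pool, recurrence) extracting
  time-varying structure;
* **sequence level** — a two-layer Bi-LSTM over a run of epochs with a
  pointwise residual full connection and a softmax head, modelling the
  stage-transition structure of the hypnogram.

A skip path (1x1 conv + GAP on the frame features) feeds the frame level
directly into the sequence level, so sequence-loss gradients supervise the
earliest convolutions directly.

Every activation is Mish, ``x * tanh(softplus(x))``: smooth, non-monotonic
and tolerant of the negative excursions that dominate raw EEG.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .nn import (
    BiGRU,
    BiLSTM,
    Conv1d,
    Dense,
    Dropout,
    Module,
    Tensor,
    avg_pool1d,
    concatenate,
    global_avg_pool,
    max_pool1d,
)

__all__ = [
    "ModelConfig", "FeatureMap", "ModelOutput", "SleepNet", "mish",
    "frame_cnn_forward", "msacb_forward", "epoch_hybrid_forward",
    "frame_skip_forward", "sequence_forward", "model_forward",
    "save_checkpoint", "load_checkpoint",
]


def mish(x):
    """Mish activation, elementwise ``x * tanh(log(1 + e^x))``.

    Accepts a plain array/scalar or an autograd :class:`Tensor`; the
    softplus is computed with ``logaddexp`` so the function is stable for
    arguments of magnitude up to at least 1e4.
    """
    if isinstance(x, Tensor):
        return x.mish()
    x = np.asarray(x, dtype=np.float64)
    out = x * np.tanh(np.logaddexp(0.0, x))
    return out if out.shape else float(out)


class ConfigError(ValueError):
    """Invalid architectural hyperparameters."""


@dataclass
class ModelConfig:
    """Every architectural hyperparameter of the network.

    The frame branches must satisfy ``small_pool * small_stride ==
    large_pool * large_stride``: with "same" padding and ceiling division
    this forces both branches to an identical number of time steps, which
    is what makes their channel-wise concatenation legal for any input
    length.  Violations are rejected here, at construction, never at
    forward time.
    """

    fs: float = 100.0
    # frame level
    small_kernel: int = 25
    large_kernel: int = 100
    small_stride: int = 3
    large_stride: int = 12
    small_pool: int = 8
    large_pool: int = 2
    frame_channels: int = 64
    msacb_branch_channels: int = 32
    msacb_dilations: tuple = (1, 2, 4)
    # epoch level
    epoch_bottleneck_channels: int = 128
    epoch_pool: int = 5
    epoch_cnn_channels: int = 1024
    gru_hidden: int = 512
    # frame -> sequence skip path
    skip_channels: int = 1024
    # sequence level
    lstm_hidden: int = 512
    lstm_layers: int = 2
    residual_fc_units: int = 1024
    n_classes: int = 5
    dropout_keep: float = 0.5
    #: Nominal RMS amplitude of the raw input, in the stored units
    #: (microvolts for EEG).  Only the *initialisation* of the two
    #: first-layer convolutions is divided by this, so early activations
    #: start O(1) even though the signal itself is fed in raw and
    #: unnormalised; the value is not a preprocessing step.
    input_rms: float = 25.0

    def __post_init__(self):
        counts = [
            self.small_kernel, self.large_kernel, self.small_stride,
            self.large_stride, self.small_pool, self.large_pool,
            self.frame_channels, self.msacb_branch_channels,
            self.epoch_bottleneck_channels, self.epoch_pool,
            self.epoch_cnn_channels, self.gru_hidden, self.skip_channels,
            self.lstm_hidden, self.lstm_layers, self.residual_fc_units,
            self.n_classes,
        ]
        if self.fs <= 0 or self.input_rms <= 0 or any(c <= 0 for c in counts):
            raise ConfigError("all sizes and the sampling rate must be positive")
        if self.small_pool * self.small_stride != self.large_pool * self.large_stride:
            raise ConfigError(
                "equal-product invariant violated: small_pool*small_stride = "
                f"{self.small_pool * self.small_stride} but large_pool*large_stride"
                f" = {self.large_pool * self.large_stride}; the two frame "
                "branches would disagree on time length"
            )
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ConfigError("dropout_keep must lie in (0, 1]")
        if len(self.msacb_dilations) < 3:
            raise ConfigError(
                "MSACB needs at least 3 dilation rates (deepest branch stacks "
                f"3 dilated convolutions); got {self.msacb_dilations!r}"
            )
        if self.residual_fc_units != 2 * self.lstm_hidden:
            raise ConfigError(
                "residual_fc_units must equal 2*lstm_hidden so the residual "
                "full connection can be added pointwise to the Bi-LSTM output"
            )
        self.msacb_dilations = tuple(int(d) for d in self.msacb_dilations)

    # ------------------------------------------------------------ derived
    @property
    def epoch_samples(self) -> int:
        return int(round(30 * self.fs))

    @property
    def frame_steps(self) -> int:
        """Time steps emitted by either frame branch for one epoch."""
        t = self.epoch_samples
        return -(-(-(-t // self.small_stride)) // self.small_pool)

    @property
    def msacb_channels(self) -> int:
        return 4 * self.msacb_branch_channels

    @property
    def feature_width(self) -> int:
        """Per-epoch feature fed to the sequence level: frame skip +
        epoch CNN + epoch Bi-GRU (both directions)."""
        return self.skip_channels + self.epoch_cnn_channels + 2 * self.gru_hidden

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """A desk-scale configuration for tests and demonstrations."""
        kw = dict(
            frame_channels=4,
            msacb_branch_channels=2,
            small_stride=6, small_pool=8, large_stride=24, large_pool=2,
            epoch_bottleneck_channels=8,
            epoch_pool=9,
            epoch_cnn_channels=16,
            gru_hidden=8,
            skip_channels=16,
            lstm_hidden=8,
            residual_fc_units=16,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        return cls(**d)


@dataclass
class FeatureMap:
    """Intermediate activation: (time-steps, channels) per batch item."""

    values: Tensor
    level: str  # frame | epoch | sequence


@dataclass
class ModelOutput:
    """Softmax probabilities and pre-softmax logits, (L, n_classes)."""

    probabilities: np.ndarray
    logits: np.ndarray


class _MSACB(Module):
    """Multiscale atrous convolution block.

    Four parallel branches of depth 1..4.  Branch 1 is a lone 1x1
    convolution; branches 2-4 prepend a 1x1 convolution and then stack
    depth-1 dilated kernel-3 convolutions whose dilation rates are taken
    in order from the configured list.  Every convolution is followed by
    Mish; the N-channel branch outputs are concatenated, so time length
    and (for 4N = input channels) width are preserved.
    """

    def __init__(self, in_channels: int, n: int, dilations, rng):
        self.branches = []
        for depth in range(1, 5):
            convs = [Conv1d(in_channels, n, 1, rng=rng)]
            for d in dilations[: depth - 1]:
                convs.append(Conv1d(n, n, 3, dilation=d, rng=rng))
            self.branches.append(convs)
        # expose for named_parameters traversal
        for i, convs in enumerate(self.branches):
            for j, conv in enumerate(convs):
                setattr(self, f"b{i + 1}_{j}", conv)

    def __call__(self, x: Tensor) -> Tensor:
        outs = []
        for convs in self.branches:
            h = x
            for conv in convs:
                h = conv(h).mish()
            outs.append(h)
        return concatenate(outs, axis=1)


class SleepNet(Module):
    """The full three-level network (see module docstring).

    All weights are drawn from ``numpy.random.default_rng(seed)``:
    variance-scaling for convolutions and full connections, orthogonal
    for recurrent kernels, zero biases.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        c = cfg
        self.conv_small = Conv1d(1, c.frame_channels, c.small_kernel,
                                 stride=c.small_stride, rng=rng)
        self.conv_large = Conv1d(1, c.frame_channels, c.large_kernel,
                                 stride=c.large_stride, rng=rng)
        # raw EEG arrives in tens of microvolts; rescale only the first
        # layer's *initial* weights so activations start O(1)
        self.conv_small.weight.data /= c.input_rms
        self.conv_large.weight.data /= c.input_rms
        self.frame_dropout = Dropout(c.dropout_keep)
        self.msacb = _MSACB(2 * c.frame_channels, c.msacb_branch_channels,
                            c.msacb_dilations, rng)
        mc = c.msacb_channels
        self.skip_conv = Conv1d(mc, c.skip_channels, 1, rng=rng)
        self.ecnn_bottleneck = Conv1d(mc, c.epoch_bottleneck_channels, 1, rng=rng)
        self.ecnn_conv = Conv1d(c.epoch_bottleneck_channels,
                                c.epoch_cnn_channels, 3, rng=rng)
        self.ernn_bottleneck = Conv1d(mc, c.epoch_bottleneck_channels, 1, rng=rng)
        self.ernn_gru = BiGRU(c.epoch_bottleneck_channels, c.gru_hidden, rng)
        self.feature_dropout = Dropout(c.dropout_keep)
        self.pretrain_head = Dense(c.feature_width, c.n_classes, rng=rng)
        self.seq_fc = Dense(c.feature_width, c.residual_fc_units, rng=rng)
        self.lstm_layers = []
        width = c.feature_width
        for _ in range(c.lstm_layers):
            self.lstm_layers.append(BiLSTM(width, c.lstm_hidden, rng))
            width = 2 * c.lstm_hidden
        self.lstm_dropout = Dropout(c.dropout_keep)
        self.out_fc = Dense(c.residual_fc_units, c.n_classes, rng=rng)

    # ----------------------------------------------------------- components
    def frame_cnn(self, x: Tensor, train=False, rng=None) -> Tensor:
        """(B, 1, 30*fs) raw signal -> (B, 4N, frame_steps) frame features."""
        small = max_pool1d(self.conv_small(x).mish(), self.cfg.small_pool)
        large = max_pool1d(self.conv_large(x).mish(), self.cfg.large_pool)
        if small.shape[2] != large.shape[2]:  # pragma: no cover - guarded by cfg
            raise ConfigError(
                "frame branches disagree on time length "
                f"({small.shape[2]} vs {large.shape[2]}); the equal-product "
                "invariant small_pool*small_stride == large_pool*large_stride "
                "is violated"
            )
        h = concatenate([small, large], axis=1)
        h = self.frame_dropout(h, train, rng)
        return self.msacb(h)

    def frame_skip(self, frame: Tensor) -> Tensor:
        """Frame features -> (B, skip_channels) via 1x1 conv + GAP."""
        return global_avg_pool(self.skip_conv(frame).mish())

    def epoch_hybrid(self, frame: Tensor) -> tuple[Tensor, Tensor]:
        """Frame features -> (CNN 1024-vector, Bi-GRU 1024-vector)."""
        c = self.cfg
        h = max_pool1d(self.ecnn_bottleneck(frame).mish(), c.epoch_pool)
        cnn_feat = global_avg_pool(self.ecnn_conv(h).mish())
        h = avg_pool1d(self.ernn_bottleneck(frame).mish(), c.epoch_pool)
        _, rnn_feat = self.ernn_gru(h.transpose(0, 2, 1))
        return cnn_feat, rnn_feat

    def epoch_features(self, x: Tensor, train=False, rng=None) -> Tensor:
        """(B, 1, samples) -> (B, feature_width) per-epoch feature."""
        frame = self.frame_cnn(x, train, rng)
        skip = self.frame_skip(frame)
        cnn_feat, rnn_feat = self.epoch_hybrid(frame)
        feat = concatenate([skip, cnn_feat, rnn_feat], axis=1)
        return self.feature_dropout(feat, train, rng)

    def sequence_head(self, feats: Tensor, train=False, rng=None) -> Tensor:
        """(B, L, feature_width) -> (B, L, n_classes) logits."""
        if feats.shape[2] != self.cfg.feature_width:
            raise ValueError(
                f"sequence input width {feats.shape[2]} != configured "
                f"feature width {self.cfg.feature_width}"
            )
        h = feats
        for i, layer in enumerate(self.lstm_layers):
            h = layer(h)
            if i + 1 < len(self.lstm_layers):
                h = self.lstm_dropout(h, train, rng)
        res = self.seq_fc(feats)
        return self.out_fc(h + res)

    # -------------------------------------------------------------- forwards
    def forward_pretrain(self, x: Tensor, train=False, rng=None) -> Tensor:
        """Per-epoch logits through the auxiliary pretraining head."""
        return self.pretrain_head(self.epoch_features(x, train, rng))

    def forward_full(self, x: Tensor, train=False, rng=None) -> Tensor:
        """(B, L, samples) -> (B, L, n_classes) logits through the
        sequence level."""
        b, l, s = x.shape
        feats = self.epoch_features(x.reshape(b * l, 1, s), train, rng)
        feats = feats.reshape(b, l, self.cfg.feature_width)
        return self.sequence_head(feats, train, rng)


# --------------------------------------------------------------- functional
def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))


def frame_cnn_forward(epoch_signal, model: SleepNet) -> FeatureMap:
    """Run the frame-level CNN on one 30-s epoch (1-D array)."""
    x = _as_tensor(epoch_signal).reshape(1, 1, -1)
    if x.shape[2] != model.cfg.epoch_samples:
        raise ValueError(
            f"epoch must hold 30*fs = {model.cfg.epoch_samples} samples, "
            f"got {x.shape[2]}"
        )
    return FeatureMap(model.frame_cnn(x), level="frame")


def msacb_forward(f: FeatureMap, model: SleepNet) -> FeatureMap:
    return FeatureMap(model.msacb(f.values), level="frame")


def frame_skip_forward(f: FeatureMap, model: SleepNet) -> np.ndarray:
    return model.frame_skip(f.values).data[0]


def epoch_hybrid_forward(f: FeatureMap, model: SleepNet):
    cnn_feat, rnn_feat = model.epoch_hybrid(f.values)
    return cnn_feat.data[0], rnn_feat.data[0]


def sequence_forward(epoch_feats, model: SleepNet) -> ModelOutput:
    """(L, feature_width) epoch features -> per-epoch class probabilities."""
    feats = _as_tensor(epoch_feats)
    logits = model.sequence_head(feats.reshape(1, *feats.shape))
    probs = logits.softmax(axis=-1)
    return ModelOutput(probabilities=probs.data[0], logits=logits.data[0])


def model_forward(sequences, model: SleepNet, mode: str = "full") -> ModelOutput:
    """End-to-end forward pass on a batch of sequences.

    ``sequences`` is (n_seq, L, 30*fs).  In ``full`` mode the per-epoch
    features flow through the sequence-level Bi-LSTM; in ``pretrain`` mode
    they go through the auxiliary per-epoch head instead, so the frame and
    epoch levels can be trained under an i.i.d. assumption.
    """
    x = _as_tensor(sequences)
    if x.ndim == 2:
        x = x.reshape(1, *x.shape)
    if mode == "full":
        logits = model.forward_full(x)
    elif mode == "pretrain":
        b, l, s = x.shape
        logits = model.forward_pretrain(x.reshape(b * l, 1, s)).reshape(b, l, -1)
    else:
        raise ValueError(f"mode must be 'pretrain' or 'full', got {mode!r}")
    probs = logits.softmax(axis=-1)
    return ModelOutput(probabilities=probs.data, logits=logits.data)


# -------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: SleepNet, extra: dict | None = None):
    """Weights + embedded config in one ``.npz`` container."""
    meta = {"config": dataclasses.asdict(model.cfg), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, cfg: ModelConfig | None = None, seed: int = 0):
    """Rebuild a :class:`SleepNet` from a checkpoint; returns (model, extra)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    saved_cfg = ModelConfig(**meta["config"])
    if cfg is not None and dataclasses.asdict(cfg) != dataclasses.asdict(saved_cfg):
        raise ValueError("checkpoint/config mismatch: configs differ")
    model = SleepNet(saved_cfg, seed=seed)
    model.load_state_dict(state)
    return model, meta["extra"]
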