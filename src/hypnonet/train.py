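"""Two-stage training: focal loss, AMSGrad, schedules, subject-wise folds.

The network is trained in two stages.  **Pretraining** fits the frame- and
epoch-level subnetworks alone, under an i.i.d.-epochs assumption, on a
class-balanced epoch dataset with signal augmentation, through an
auxiliary per-epoch softmax head that is discarded afterwards.
**Fine-tuning** then trains the whole network on transition-balanced
sequences: the pretrained subnetwork moves at a small fixed learning rate
(1e-6) while the sequence level follows a decaying schedule
(1e-3 -> 1e-4 -> 5e-5 -> 1e-5, stepping every 10 passes), with no
augmentation so the sequence level sees genuine transition statistics.

Both stages minimise the focal loss

    FL(p) = -alpha_y * (1 - p_y)^gamma * log(p_y)

averaged over samples (and sequence positions), where ``p_y`` is the
predicted probability of the true class, ``alpha`` reweights rare classes
(typically inverse class frequency) and ``gamma`` (default 2) shrinks the
contribution of easy samples so the scarce, difficult ones — N1 above
all — dominate the gradient.  The optimiser is AMSGrad (Adam that keeps
the running *maximum* of second-moment estimates) with beta1=0.9 and
beta2=0.99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import EpochDataset, Recording
from .model import ModelConfig, SleepNet
from .nn import Tensor
from .sampling import SamplerConfig, augment_batch, sequence_balance_sample
from .stages import N_STAGES

__all__ = [
    "FocalLossParams", "TrainSchedule", "FoldSpec", "AMSGrad",
    "focal_loss", "focal_loss_tensor", "make_alpha_from_frequencies",
    "subject_kfold_split", "pretrain", "finetune", "TrainResult",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class FocalLossParams:
    """alpha: per-class nonnegative weights; gamma: difficulty exponent."""

    alpha: np.ndarray = field(default_factory=lambda: np.ones(N_STAGES))
    gamma: float = 2.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.isfinite(self.alpha).all() or (self.alpha < 0).any():
            raise ValueError("alpha weights must be finite and nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


_P_FLOOR = 1e-12


def focal_loss_tensor(probs: Tensor, labels: np.ndarray,
                      params: FocalLossParams) -> Tensor:
    """Differentiable focal loss; ``probs`` is (..., n_classes) with valid
    probability rows, ``labels`` integer classes of matching leading shape.
    Returns the mean over all samples."""
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = probs.shape[-1]
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    onehot = np.zeros(labels.shape + (n_classes,))
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    p_true = (probs * Tensor(onehot)).sum(axis=-1)
    alpha_y = Tensor(params.alpha[labels])
    log_p = p_true.clip_min(_P_FLOOR).log()
    if params.gamma == 0:
        per_sample = -(alpha_y * log_p)
    else:
        per_sample = -(alpha_y * (1.0 - p_true) ** params.gamma * log_p)
    return per_sample.mean()


def focal_loss(probs, true_labels, params: FocalLossParams) -> float:
    """Focal loss as a plain number.  ``probs`` may be a probability array
    or a :class:`~hypnonet.model.ModelOutput`."""
    arr = getattr(probs, "probabilities", probs)
    return float(focal_loss_tensor(Tensor(np.asarray(arr, float)),
                                   true_labels, params).data)


def make_alpha_from_frequencies(class_counts) -> np.ndarray:
    """Inverse-frequency class weights, normalised to average 1.

    ``alpha[c] = (total / count[c])``, rescaled so ``alpha.mean() == 1``;
    the rarest class receives the largest weight.
    """
    counts = np.asarray(class_counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError(
            "every class needs a positive count to define inverse-frequency "
            f"weights; got {counts}"
        )
    alpha = counts.sum() / counts
    return alpha / alpha.mean()


@dataclass
class TrainSchedule:
    """Optimisation schedule for one training stage.

    ``lr_steps`` is a list of ``(after_pass, new_rate)`` pairs: the rate
    drops to ``new_rate`` once that many full passes over the training set
    are complete.  Rates must be non-increasing.  ``l2_first_conv``
    penalises the first frame-level convolution weights (both parallel
    kernels); ``grad_clip`` is a global-norm divergence guard that can be
    disabled with ``None``.
    """

    stage: str = "pretrain"
    lr_initial: float = 1e-3
    lr_steps: tuple = ()
    batch_size: int = 256
    passes_total: int = 80
    optimizer: str = "AMSGrad"
    beta1: float = 0.9
    beta2: float = 0.99
    l2_first_conv: float = 1e-3
    subnet_lr: float = 1e-6
    grad_clip: float | None = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("pretrain", "finetune"):
            raise ValueError("stage must be 'pretrain' or 'finetune'")
        if self.lr_initial <= 0:
            raise ValueError("learning rate must be positive")
        prev = self.lr_initial
        for after, rate in self.lr_steps:
            if rate <= 0 or rate > prev:
                raise ValueError(
                    "lr_steps rates must be positive and non-increasing; "
                    f"got {rate} after {prev}"
                )
            prev = rate
        if self.lr_steps and self.passes_total < self.lr_steps[-1][0]:
            raise ValueError("passes_total must reach the last lr step")
        if self.batch_size < 1 or self.passes_total < 1:
            raise ValueError("batch_size and passes_total must be >= 1")

    def lr_at(self, pass_index: int) -> float:
        """Learning rate during 1-based pass ``pass_index``."""
        lr = self.lr_initial
        for after, rate in self.lr_steps:
            if pass_index > after:
                lr = rate
        return lr

    @classmethod
    def pretrain_default(cls, **overrides) -> "TrainSchedule":
        """1e-3 for 40 passes, then 1e-4 for the next 40; batch 256."""
        kw = dict(stage="pretrain", lr_initial=1e-3, lr_steps=((40, 1e-4),),
                  passes_total=80, batch_size=256)
        kw.update(overrides)
        return cls(**_drop_unreached_steps(kw))

    @classmethod
    def finetune_default(cls, **overrides) -> "TrainSchedule":
        """Sequence level 1e-3 -> 1e-4 -> 5e-5 -> 1e-5 every 10 passes;
        subnetwork fixed at 1e-6; batch 10."""
        kw = dict(stage="finetune", lr_initial=1e-3,
                  lr_steps=((10, 1e-4), (20, 5e-5), (30, 1e-5)),
                  passes_total=40, batch_size=10, subnet_lr=1e-6)
        kw.update(overrides)
        return cls(**_drop_unreached_steps(kw))


def _drop_unreached_steps(kw: dict) -> dict:
    """When a default schedule is shortened, discard lr steps the run
    would never reach (keeps the passes_total >= last-step invariant)."""
    kw = dict(kw)
    kw["lr_steps"] = tuple(
        (after, rate) for after, rate in kw.get("lr_steps", ())
        if after <= kw["passes_total"]
    )
    return kw


@dataclass
class FoldSpec:
    """Subject-wise fold assignment for k-fold cross-validation."""

    k: int
    assignments: dict  # subject_id -> fold index

    def fold_subjects(self, fold: int):
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def split(self, fold: int):
        """(train_subjects, test_subjects) for one fold."""
        test = set(self.fold_subjects(fold))
        train = sorted(set(self.assignments) - test)
        return train, sorted(test)


def subject_kfold_split(subject_ids, k: int, seed: int) -> FoldSpec:
    """Shuffle subjects by ``seed`` and deal them round-robin into ``k``
    folds, so no subject ever appears in two folds."""
    subjects = sorted(set(map(str, subject_ids)))
    if k < 1 or k > len(subjects):
        raise ValueError(
            f"k must lie in 1..{len(subjects)} (number of subjects), got {k}"
        )
    order = np.random.default_rng(seed).permutation(len(subjects))
    return FoldSpec(
        k=k,
        assignments={subjects[j]: i % k for i, j in enumerate(order)},
    )


class AMSGrad:
    """AMSGrad: Adam with a running maximum of second-moment estimates.

    The maximum makes the effective per-parameter step size non-increasing,
    which is the property that repairs Adam's convergence counterexamples.
    Bias correction follows the Adam convention.  ``groups`` is a list of
    ``{"params": [...], "lr": rate}`` dicts; rates may be updated between
    steps (learning-rate schedules mutate them in place).
    """

    def __init__(self, groups, beta1: float = 0.9, beta2: float = 0.99,
                 eps: float = 1e-8):
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        self._vhat = {}
        for g in groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)
                self._vhat[id(p)] = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for g in self.groups:
            lr = g["lr"] * correction
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                vhat = self._vhat[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                np.maximum(vhat, v, out=vhat)
                p.data -= lr * m / (np.sqrt(vhat) + self.eps)

    def max_second_moment(self):
        """Per-parameter vhat snapshots (monotonicity is asserted in tests)."""
        return {k: v.copy() for k, v in self._vhat.items()}


def _clip_gradients(params, max_norm: float | None):
    if max_norm is None:
        return
    total = math.sqrt(sum(
        float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


@dataclass
class TrainResult:
    """Fitted model plus per-pass training diagnostics."""

    model: SleepNet
    loss_trace: list
    acc_trace: list
    lr_trace: list  # per pass: dict group name -> lr


def _first_conv_penalty(model: SleepNet, coef: float) -> Tensor:
    pen = (model.conv_small.weight ** 2).sum() + (model.conv_large.weight ** 2).sum()
    return pen * coef


def pretrain(train_ds: EpochDataset, cfg: ModelConfig, sched: TrainSchedule,
             loss: FocalLossParams, model: SleepNet | None = None) -> TrainResult:
    """Stage 1: train frame+epoch subnetworks on i.i.d. balanced epochs.

    Expects a class-balanced dataset (apply
    :func:`~hypnonet.sampling.class_balance_upsample` first).  Each batch
    is augmented with a random cyclic shift and random mirror; the focal
    loss plus an L2 penalty on the first frame-level convolutions is
    minimised with AMSGrad under the schedule's learning rates.
    """
    if len(train_ds) == 0:
        raise ValueError("cannot pretrain on an empty dataset")
    rng = np.random.default_rng(sched.seed)
    if model is None:
        model = SleepNet(cfg, seed=sched.seed)
    opt = AMSGrad([{"params": model.parameters(), "lr": sched.lr_initial}],
                  beta1=sched.beta1, beta2=sched.beta2)
    loss_trace, acc_trace, lr_trace = [], [], []
    n = len(train_ds)
    for p in range(1, sched.passes_total + 1):
        lr = sched.lr_at(p)
        opt.groups[0]["lr"] = lr
        order = rng.permutation(n)
        tot_loss = tot_correct = 0
        for lo in range(0, n, sched.batch_size):
            idx = order[lo: lo + sched.batch_size]
            xb = augment_batch(train_ds.epochs[idx], rng)
            yb = train_ds.labels[idx]
            x = Tensor(xb[:, None, :])
            logits = model.forward_pretrain(x, train=True, rng=rng)
            probs = logits.softmax(axis=-1)
            batch_loss = focal_loss_tensor(probs, yb, loss)
            if sched.l2_first_conv:
                batch_loss = batch_loss + _first_conv_penalty(
                    model, sched.l2_first_conv)
            lval = float(batch_loss.data)
            if not np.isfinite(lval):
                raise DivergenceError(
                    f"non-finite loss at pass {p}, batch starting {lo} "
                    f"(labels {np.bincount(yb, minlength=N_STAGES)})"
                )
            batch_loss.backward()
            _clip_gradients(model.parameters(), sched.grad_clip)
            opt.step()
            tot_loss += lval * len(idx)
            tot_correct += int((probs.data.argmax(-1) == yb).sum())
        loss_trace.append(tot_loss / n)
        acc_trace.append(tot_correct / n)
        lr_trace.append({"all": lr})
    return TrainResult(model, loss_trace, acc_trace, lr_trace)


def _param_groups(model: SleepNet):
    """(subnetwork, sequence-level) parameter split for fine-tuning.

    The auxiliary pretraining head is excluded entirely — it is discarded
    after stage 1.
    """
    seq_names = ("seq_fc.", "lstm", "out_fc.")
    subnet, seq = [], []
    for name, p in model.named_parameters():
        if name.startswith("pretrain_head."):
            continue
        (seq if name.startswith(seq_names) else subnet).append(p)
    return subnet, seq


def finetune(recs: list[Recording], model: SleepNet, sched: TrainSchedule,
             loss: FocalLossParams, sampler: SamplerConfig) -> TrainResult:
    """Stage 2: train the full network on transition-balanced sequences.

    The pretrained subnetwork (frame + epoch levels) moves at the fixed
    ``sched.subnet_lr`` while the sequence level follows the decaying
    ``lr_steps`` schedule.  Sequences are redrawn each pass through
    :func:`~hypnonet.sampling.sequence_balance_sample`; no augmentation is
    applied.  The focal loss is averaged over every position of every
    sequence.
    """
    rng = np.random.default_rng(sched.seed)
    subnet, seq = _param_groups(model)
    opt = AMSGrad(
        [{"params": subnet, "lr": sched.subnet_lr},
         {"params": seq, "lr": sched.lr_initial}],
        beta1=sched.beta1, beta2=sched.beta2,
    )
    loss_trace, acc_trace, lr_trace = [], [], []
    for p in range(1, sched.passes_total + 1):
        seq_lr = sched.lr_at(p)
        opt.groups[1]["lr"] = seq_lr
        batch_cfg = SamplerConfig(
            seq_len=sampler.seq_len,
            sampling_factor=sampler.sampling_factor,
            neighborhood_len=sampler.neighborhood_len,
            replacements_per_window=sampler.replacements_per_window,
            rng_seed=int(np.random.default_rng(
                [sampler.rng_seed, p]).integers(2**31)),
        )
        batch = sequence_balance_sample(recs, batch_cfg)
        n = len(batch)
        tot_loss = tot_correct = tot_pos = 0
        for lo in range(0, n, sched.batch_size):
            xb = batch.sequences[lo: lo + sched.batch_size]
            yb = batch.labels[lo: lo + sched.batch_size]
            logits = model.forward_full(Tensor(xb), train=True, rng=rng)
            probs = logits.softmax(axis=-1)
            batch_loss = focal_loss_tensor(probs, yb, loss)
            lval = float(batch_loss.data)
            if not np.isfinite(lval):
                raise DivergenceError(
                    f"non-finite loss at pass {p}, batch starting {lo}")
            batch_loss.backward()
            _clip_gradients(subnet + seq, sched.grad_clip)
            opt.step()
            tot_loss += lval * yb.size
            tot_correct += int((probs.data.argmax(-1) == yb).sum())
            tot_pos += yb.size
        loss_trace.append(tot_loss / tot_pos)
        acc_trace.append(tot_correct / tot_pos)
        lr_trace.append({"subnet": sched.subnet_lr, "sequence": seq_lr})
    return TrainResult(model, loss_trace, acc_trace, lr_trace)
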