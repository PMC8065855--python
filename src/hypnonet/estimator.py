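"""Scikit-learn style estimator facade over the two-stage pipeline.

:class:`SleepStageClassifier` bundles trimming, segmentation, balancing,
pretraining and fine-tuning behind ``fit``/``predict``/``predict_proba``,
with fitted state in trailing-underscore attributes and constructor
arguments exposed through ``get_params``/``set_params`` so the estimator
clones cleanly.  ``X`` is a list of :class:`~hypnonet.io.Recording`
objects (one per subject/night); ``y`` is implicit in their hypnograms.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import Recording, segment_epochs, trim_wake
from .metrics import confusion_matrix, overall_metrics
from .model import ModelConfig, SleepNet
from .nn import Tensor
from .sampling import SamplerConfig, class_balance_upsample
from .stages import N_STAGES
from .train import (
    FocalLossParams,
    TrainSchedule,
    finetune,
    make_alpha_from_frequencies,
    pretrain,
)

__all__ = ["SleepStageClassifier"]


def _concat_datasets(datasets):
    from .io import EpochDataset

    return EpochDataset(
        epochs=np.concatenate([d.epochs for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        subject_ids=np.concatenate([d.subject_ids for d in datasets]),
    )


class SleepStageClassifier(BaseEstimator, ClassifierMixin):
    """Five-class sleep stager over raw single-channel EEG recordings.

    Parameters
    ----------
    config : ModelConfig or None
        Network architecture; ``None`` uses the reference configuration
        (use ``ModelConfig.tiny()`` for desk-scale experiments).
    pretrain_schedule, finetune_schedule : TrainSchedule or None
        Stage schedules; ``None`` uses the reference protocols
        (1e-3 -> 1e-4 over 80 passes; sequence level 1e-3 stepping down
        every 10 passes with the subnetwork fixed at 1e-6).
    sampler : SamplerConfig or None
        Transition-balancing sequence sampler for fine-tuning.
    gamma : float
        Focal-loss difficulty exponent.
    alpha : "auto", "uniform" or array
        Focal-loss class weights; ``"auto"`` derives inverse-frequency
        weights from the training class counts.
    margin_minutes : float
        Peripheral wake retained on each side of sleep before training.
    class_balance : bool
        Upsample epoch classes to parity before pretraining.
    seed : int
        Master seed for weights, balancing, augmentation and sampling.
    """

    def __init__(self, config=None, pretrain_schedule=None,
                 finetune_schedule=None, sampler=None, gamma: float = 2.0,
                 alpha="auto", margin_minutes: float = 30.0,
                 class_balance: bool = True, seed: int = 0):
        self.config = config
        self.pretrain_schedule = pretrain_schedule
        self.finetune_schedule = finetune_schedule
        self.sampler = sampler
        self.gamma = gamma
        self.alpha = alpha
        self.margin_minutes = margin_minutes
        self.class_balance = class_balance
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        """Two-stage training on a list of :class:`Recording` objects."""
        recs = [trim_wake(r, self.margin_minutes) for r in X]
        ds = _concat_datasets([segment_epochs(r) for r in recs])
        counts = ds.class_counts()
        if isinstance(self.alpha, str) and self.alpha == "auto":
            present = counts > 0
            alpha = np.ones(N_STAGES)
            alpha[present] = make_alpha_from_frequencies(counts[present])
        elif isinstance(self.alpha, str):
            alpha = np.ones(N_STAGES)
        else:
            alpha = np.asarray(self.alpha, dtype=float)
        loss = FocalLossParams(alpha=alpha, gamma=self.gamma)

        cfg = self.config or ModelConfig()
        pre_sched = self.pretrain_schedule or TrainSchedule.pretrain_default(
            seed=self.seed)
        fin_sched = self.finetune_schedule or TrainSchedule.finetune_default(
            seed=self.seed)
        sampler = self.sampler or SamplerConfig(rng_seed=self.seed)

        if self.class_balance:
            ds = class_balance_upsample(ds, rng_seed=self.seed)
        pre = pretrain(ds, cfg, pre_sched, loss)
        fin = finetune(recs, pre.model, fin_sched, loss, sampler)

        self.model_ = fin.model
        self.config_ = cfg
        self.loss_params_ = loss
        self.classes_ = np.arange(N_STAGES)
        self.pretrain_result_ = pre
        self.finetune_result_ = fin
        self.seq_len_ = sampler.seq_len
        return self

    # ------------------------------------------------------------- predict
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def _predict_recording(self, rec: Recording) -> np.ndarray:
        """Per-epoch class probabilities for one recording, tiling it
        into length-L windows (the final window is anchored at the end,
        overlapping probabilities are averaged)."""
        model: SleepNet = self.model_
        L = self.seq_len_
        spe = rec.samples_per_epoch
        n = rec.n_epochs
        if n < L:
            raise ValueError(
                f"recording {rec.subject_id!r} has {n} epochs, fewer than "
                f"the sequence length {L}"
            )
        starts = list(range(0, n - L + 1, L))
        if starts[-1] != n - L:
            starts.append(n - L)
        probs = np.zeros((n, N_STAGES))
        hits = np.zeros(n)
        for s in starts:
            window = rec.signal[s * spe:(s + L) * spe].reshape(1, L, spe)
            logits = model.forward_full(Tensor(window))
            probs[s:s + L] += logits.softmax(axis=-1).data[0]
            hits[s:s + L] += 1
        return probs / hits[:, None]

    def predict_proba(self, X) -> np.ndarray:
        """Concatenated per-epoch probabilities for every valid epoch."""
        self._check_fitted()
        out = []
        for rec in X:
            p = self._predict_recording(rec)
            out.append(p[rec.valid_mask])
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    @staticmethod
    def staged_labels(X) -> np.ndarray:
        """True labels of every valid epoch, aligned with ``predict``."""
        return np.concatenate([r.epoch_labels[r.valid_mask] for r in X])

    def score(self, X, y=None) -> float:
        """Overall accuracy (fraction) against the recordings' hypnograms."""
        self._check_fitted()
        true = self.staged_labels(X) if y is None else np.asarray(y)
        pred = self.predict(X)
        acc, _, _ = overall_metrics(confusion_matrix(true, pred), rounded=False)
        return acc / 100.0
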