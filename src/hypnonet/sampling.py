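"""Data balancing and augmentation.

Sleep data are imbalanced at two granularities.  Per-epoch class counts
are skewed (N2 and W dominate; N1 is rare), which the pretraining stage
counters by random upsampling with replacement until every class matches
the majority count.  The *transitions* between stages are also skewed —
long self-transition runs of W and N2 swamp the rare stage changes — so
fine-tuning draws its training sequences through a two-step sampler:
first every candidate length-L window gets a *sequence label* and the
windows are randomly downsampled per label class to the minority count
times a sampling factor; then each retained window is replaced by a
window randomly intercepted from its neighbourhood, which restores local
variety without undoing the balance.

Two cheap signal augmentations (random cyclic shift, random time mirror)
are provided for the pretraining stage only; the fine-tuning stage must
see unaugmented signals so the sequence level learns real transition
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochDataset, Recording
from .stages import N_STAGES

__all__ = [
    "SamplerConfig", "SequenceBatch", "class_balance_upsample",
    "sequence_balance_sample", "augment_cyclic_shift", "augment_mirror",
    "sequence_label_entropy",
]


@dataclass
class SamplerConfig:
    """Knobs of the transition-balancing sequence sampler.

    ``seq_len`` is the sequence length L in epochs; ``sampling_factor``
    scales the per-class target count (1.0 keeps exactly the minority
    count, larger values allow overlap between re-drawn windows);
    ``neighborhood_len`` is the span, in epochs, from which replacement
    windows are intercepted — by default the sequence length itself.
    """

    seq_len: int = 25
    sampling_factor: float = 1.0
    neighborhood_len: int | None = None
    replacements_per_window: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.sampling_factor < 1.0:
            raise ValueError("sampling_factor must be >= 1")
        if self.neighborhood_len is None:
            self.neighborhood_len = self.seq_len
        if self.neighborhood_len < 1:
            raise ValueError("neighborhood_len must be >= 1")
        if self.replacements_per_window < 1:
            raise ValueError("replacements_per_window must be >= 1")


@dataclass
class SequenceBatch:
    """Contiguous runs of L epochs with per-epoch labels.

    ``sequence_label`` is the balancing label each emitted window
    inherited from its anchor window (the stage of the anchor's final
    epoch); ``sources`` records ``(recording_index, start_epoch)`` so
    contiguity is auditable.
    """

    sequences: np.ndarray  # (n_seq, L, 30*fs)
    labels: np.ndarray  # (n_seq, L)
    sequence_label: np.ndarray  # (n_seq,)
    seq_len: int
    sources: np.ndarray = None  # (n_seq, 2)

    def __len__(self):
        return len(self.sequence_label)


def class_balance_upsample(ds: EpochDataset, rng_seed: int) -> EpochDataset:
    """Random upsampling with replacement until all present classes match
    the majority class count.  Original rows are all retained, in order,
    with the resampled rows appended."""
    if len(ds) == 0:
        raise ValueError("cannot balance an empty dataset")
    rng = np.random.default_rng(rng_seed)
    counts = ds.class_counts()
    target = counts.max()
    extra_idx = []
    for c in range(len(counts)):
        if counts[c] == 0:
            continue
        deficit = target - counts[c]
        if deficit:
            pool = np.flatnonzero(ds.labels == c)
            extra_idx.append(rng.choice(pool, size=deficit, replace=True))
    if not extra_idx:
        return ds
    extra = np.concatenate(extra_idx)
    return EpochDataset(
        epochs=np.concatenate([ds.epochs, ds.epochs[extra]]),
        labels=np.concatenate([ds.labels, ds.labels[extra]]),
        subject_ids=np.concatenate([ds.subject_ids, ds.subject_ids[extra]]),
    )


def _candidate_windows(recs: list[Recording], seq_len: int):
    """All (rec_idx, start) windows of L contiguous valid epochs."""
    cands = []
    for r, rec in enumerate(recs):
        n = rec.n_epochs
        if n < seq_len:
            raise ValueError(
                f"recording {rec.subject_id!r} has {n} epochs, shorter than "
                f"the configured sequence length {seq_len}"
            )
        ok = rec.valid_mask
        run_ok = np.ones(n - seq_len + 1, dtype=bool)
        # window valid iff every epoch inside is valid
        for off in range(seq_len):
            run_ok &= ok[off: off + n - seq_len + 1]
        for start in np.flatnonzero(run_ok):
            cands.append((r, int(start)))
    return cands


def sequence_balance_sample(recs: list[Recording],
                            cfg: SamplerConfig) -> SequenceBatch:
    """Transition-balancing sequence sampler (downsample, then intercept).

    Step 1: every possible length-L window of valid epochs is a candidate;
    its sequence label is the stage of its final epoch (the prediction
    anchor).  Candidates are randomly downsampled per label class to
    ``floor(min_class_count * sampling_factor)`` windows.

    Step 2: each retained window is replaced by ``replacements_per_window``
    windows whose start is drawn uniformly within +/- neighborhood_len/2
    epochs of the original start, clipped to the valid range.  The emitted
    window keeps the anchor's sequence label for book-keeping, so per-class
    counts stay exactly balanced while the signal content regains local
    variety.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    L = cfg.seq_len
    cands = _candidate_windows(recs, L)
    if not cands:
        raise ValueError("no valid candidate windows")
    anchor_label = np.array(
        [int(recs[r].epoch_labels[s + L - 1]) for r, s in cands]
    )
    counts = np.bincount(anchor_label, minlength=N_STAGES)
    present = np.flatnonzero(counts)
    target = int(np.floor(counts[present].min() * cfg.sampling_factor))
    target = max(target, 1)

    half = cfg.neighborhood_len // 2
    chosen_src, chosen_lab = [], []
    for c in present:
        pool = np.flatnonzero(anchor_label == c)
        # with sampling_factor > 1 a class may hold fewer candidates than
        # the target; draw with replacement then so counts still equalise
        keep = rng.choice(pool, size=target, replace=target > pool.size)
        for k in keep:
            r, s = cands[k]
            n = recs[r].n_epochs
            for _ in range(cfg.replacements_per_window):
                off = int(rng.integers(-half, half + 1))
                start = int(np.clip(s + off, 0, n - L))
                chosen_src.append((r, start))
                chosen_lab.append(int(c))

    order = rng.permutation(len(chosen_src))
    seqs = np.empty((len(order), L, recs[0].samples_per_epoch))
    labs = np.empty((len(order), L), dtype=np.int64)
    srcs = np.empty((len(order), 2), dtype=np.int64)
    for i, j in enumerate(order):
        r, s = chosen_src[j]
        rec = recs[r]
        spe = rec.samples_per_epoch
        seqs[i] = rec.signal[s * spe: (s + L) * spe].reshape(L, spe)
        labs[i] = rec.epoch_labels[s: s + L]
        srcs[i] = (r, s)
    return SequenceBatch(
        sequences=seqs,
        labels=labs,
        sequence_label=np.array(chosen_lab)[order],
        seq_len=L,
        sources=srcs,
    )


def sequence_label_entropy(labels: np.ndarray) -> float:
    """Shannon entropy (nats) of a label distribution; the sampler's
    balance audit compares this before and after sampling."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=N_STAGES)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def augment_cyclic_shift(epoch: np.ndarray, rng_seed: int | None = None,
                         offset: int | None = None) -> np.ndarray:
    """Rotate the signal by a uniformly random offset in [0, len).

    The multiset of sample values is preserved exactly.  ``offset`` forces
    a specific rotation (used by tests); otherwise it is drawn from
    ``rng_seed``.
    """
    epoch = np.asarray(epoch)
    if epoch.size == 0:
        raise ValueError("cannot shift an empty signal")
    if offset is None:
        offset = int(np.random.default_rng(rng_seed).integers(epoch.size))
    return np.roll(epoch, offset)


def augment_mirror(epoch: np.ndarray, rng_seed: int | None = None,
                   flip: bool | None = None) -> np.ndarray:
    """Return the time-reversed signal with probability 0.5, else a copy."""
    epoch = np.asarray(epoch)
    if epoch.size == 0:
        raise ValueError("cannot mirror an empty signal")
    if flip is None:
        flip = bool(np.random.default_rng(rng_seed).random() < 0.5)
    return epoch[::-1].copy() if flip else epoch.copy()


def augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply cyclic shift + mirror independently per row (pretraining only)."""
    out = np.empty_like(batch)
    n = batch.shape[1]
    offsets = rng.integers(0, n, size=len(batch))
    flips = rng.random(len(batch)) < 0.5
    for i in range(len(batch)):
        row = np.roll(batch[i], offsets[i])
        out[i] = row[::-1] if flips[i] else row
    return out
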