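"""Reading polysomnography: EDF signals, EDF+ hypnograms, epoch segmentation.

The pipeline here mirrors standard sleep-cassette handling: read one EEG
channel raw (no filtering, no re-referencing, no rescaling — amplitudes
pass through as stored, in microvolts), expand the hypnogram annotations
to one AASM label per 30-s epoch, mask movement/unknown epochs, trim the
long wake stretches at the edges of the night down to a 30-min margin,
and cut the signal into a (n_epochs, 30*fs) array ready for training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stages import (
    EXCLUDED,
    StageLabel,
    annotation_to_rk,
    map_rk_to_aasm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Recording", "EpochDataset", "ChannelNotFoundError", "AlignmentError",
    "NoSleepError", "load_recording", "trim_wake", "segment_epochs",
    "save_epoch_dataset", "load_epoch_dataset",
]

EPOCH_SECONDS = 30


class ChannelNotFoundError(KeyError):
    """Requested channel absent from the EDF header."""


class AlignmentError(ValueError):
    """Hypnogram and signal disagree by more than one trailing epoch."""


class NoSleepError(ValueError):
    """Recording contains no non-wake epoch, so there is nothing to trim to."""


@dataclass
class Recording:
    """One subject's continuous EEG plus aligned per-epoch stage labels.

    ``epoch_labels`` holds integer :class:`StageLabel` codes; epochs whose
    annotation was movement/unknown keep a placeholder code and are marked
    ``valid_mask=False``.
    """

    subject_id: str
    channel: str
    fs: float
    signal: np.ndarray
    epoch_labels: np.ndarray
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.epoch_labels = np.asarray(self.epoch_labels, dtype=np.int64)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.epoch_labels), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.valid_mask) != len(self.epoch_labels):
            raise ValueError("valid_mask and epoch_labels lengths differ")
        if len(self.signal) < self.samples_per_epoch * len(self.epoch_labels):
            raise AlignmentError(
                f"signal holds {len(self.signal)} samples but "
                f"{len(self.epoch_labels)} epochs need at least "
                f"{self.samples_per_epoch * len(self.epoch_labels)}"
            )

    @property
    def samples_per_epoch(self) -> int:
        return int(round(EPOCH_SECONDS * self.fs))

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_labels)

    def epoch_signal(self, i: int) -> np.ndarray:
        """Samples of epoch ``i`` (0-based, half-open interval)."""
        spe = self.samples_per_epoch
        return self.signal[spe * i: spe * (i + 1)]


@dataclass
class EpochDataset:
    """Flat (n_epochs, 30*fs) array of labelled epochs for pretraining."""

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        if not (len(self.epochs) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("epochs, labels and subject_ids must align")
        if self.epochs.size and not np.isfinite(self.epochs).all():
            raise ValueError("epoch signals contain non-finite values")

    def __len__(self):
        return len(self.labels)

    def class_counts(self, n_classes: int = len(StageLabel)) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)


def _read_hypnogram(hypnogram_path) -> list[tuple[float, float, str]]:
    import mne

    ann = mne.read_annotations(str(hypnogram_path))
    return [
        (float(o), float(d), str(desc))
        for o, d, desc in zip(ann.onset, ann.duration, ann.description)
    ]


def load_recording(edf_path, hypnogram_path, channel: str,
                   subject_id: str | None = None) -> Recording:
    """Load one EDF signal + EDF+ hypnogram pair into a :class:`Recording`.

    The signal is returned raw — unfiltered and unnormalised, in the
    microvolt amplitudes stored in the file.  Each hypnogram annotation is
    expanded to ``duration/30`` epoch labels, R&K names are mapped to AASM
    (S3 and S4 merge into N3) and movement/unknown epochs are masked out.

    Raises
    ------
    ChannelNotFoundError
        If ``channel`` is not in the EDF header (the message names the
        channels that are available).
    AlignmentError
        If hypnogram and signal lengths disagree by more than one
        trailing epoch.
    """
    import mne

    edf_path, hypnogram_path = Path(edf_path), Path(hypnogram_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(edf_path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not found in {edf_path.name}; "
            f"available channels: {raw.ch_names}"
        )
    raw = raw.pick([channel])
    fs = float(raw.info["sfreq"])
    signal = raw.get_data(units="uV")[0]

    spe = int(round(EPOCH_SECONDS * fs))
    labels, mask = [], []
    for onset, duration, desc in _read_hypnogram(hypnogram_path):
        if duration % EPOCH_SECONDS:
            raise AlignmentError(
                f"annotation {desc!r} at {onset:g}s has duration {duration:g}s,"
                f" not a multiple of {EPOCH_SECONDS}s"
            )
        stage = map_rk_to_aasm(annotation_to_rk(desc))
        n = int(round(duration / EPOCH_SECONDS))
        if stage is EXCLUDED:
            labels.extend([int(StageLabel.W)] * n)  # placeholder code
            mask.extend([False] * n)
        else:
            labels.extend([int(stage)] * n)
            mask.extend([True] * n)

    n_sig_epochs, rem = divmod(len(signal), spe)
    if rem:
        logger.warning(
            "%s: dropping trailing partial epoch of %d samples", edf_path.name, rem
        )
    if len(labels) > n_sig_epochs + 1 or n_sig_epochs > len(labels) + 1:
        raise AlignmentError(
            f"hypnogram scores {len(labels)} epochs but the signal holds "
            f"{n_sig_epochs}; mismatch exceeds one trailing epoch"
        )
    n_epochs = min(len(labels), n_sig_epochs)
    return Recording(
        subject_id=subject_id or edf_path.stem,
        channel=channel,
        fs=fs,
        signal=signal[: n_epochs * spe],
        epoch_labels=np.array(labels[:n_epochs]),
        valid_mask=np.array(mask[:n_epochs]),
    )


def trim_wake(rec: Recording, margin_minutes: float = 30) -> Recording:
    """Crop peripheral wake down to ``margin_minutes`` on each side.

    Keeps every epoch from 60 epochs (for the default 30-min margin)
    before the first non-wake epoch to 60 epochs after the last one,
    clipped at the recording bounds; the signal is cropped consistently.
    Non-wake epochs are never removed.
    """
    valid_non_w = rec.valid_mask & (rec.epoch_labels != int(StageLabel.W))
    idx = np.flatnonzero(valid_non_w)
    if idx.size == 0:
        raise NoSleepError(
            f"recording {rec.subject_id!r} contains no non-wake epoch"
        )
    margin = int(round(margin_minutes * 60 / EPOCH_SECONDS))
    lo = max(int(idx[0]) - margin, 0)
    hi = min(int(idx[-1]) + margin, rec.n_epochs - 1)
    spe = rec.samples_per_epoch
    return Recording(
        subject_id=rec.subject_id,
        channel=rec.channel,
        fs=rec.fs,
        signal=rec.signal[lo * spe: (hi + 1) * spe].copy(),
        epoch_labels=rec.epoch_labels[lo: hi + 1].copy(),
        valid_mask=rec.valid_mask[lo: hi + 1].copy(),
    )


def segment_epochs(rec: Recording) -> EpochDataset:
    """Cut a recording into its valid labelled epochs, one row each."""
    spe = rec.samples_per_epoch
    keep = np.flatnonzero(rec.valid_mask)
    rows = np.empty((keep.size, spe), dtype=float)
    for r, i in enumerate(keep):
        rows[r] = rec.signal[spe * i: spe * (i + 1)]
    return EpochDataset(
        epochs=rows,
        labels=rec.epoch_labels[keep],
        subject_ids=np.array([rec.subject_id] * keep.size, dtype=object),
    )


def save_epoch_dataset(path, ds: EpochDataset):
    """Store as a compressed array container with the labels/subjects
    sidecar embedded."""
    np.savez_compressed(
        path,
        epochs=ds.epochs,
        labels=ds.labels,
        subject_ids=np.asarray(ds.subject_ids, dtype="U64"),
    )


def load_epoch_dataset(path) -> EpochDataset:
    with np.load(path, allow_pickle=False) as z:
        return EpochDataset(
            epochs=z["epochs"], labels=z["labels"],
            subject_ids=z["subject_ids"].astype(object),
        )
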