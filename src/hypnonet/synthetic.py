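"""Synthetic polysomnography with the statistical structure real sleep has.

The generator emulates exactly the features the pipeline's machinery is
built to handle, so the whole system is testable without downloading any
recordings:

* **hypnograms** are first-order Markov chains with per-stage mean bout
  lengths (self-transition ``p = 1 - 1/mean_bout``), so stage runs last
  minutes-to-hours as they do in real nights, and with a stationary
  distribution tuned near the canonical sleep-cassette class imbalance
  (W 19%, N1 7%, N2 42%, N3 14%, REM 18%);
* **signals** are sums of band-limited sinusoids with stage-specific
  spectral signatures (alpha-dominant wake, theta N1, theta + sigma
  spindle bursts in N2, delta-dominant N3, mixed theta/beta REM) plus
  Gaussian noise — separable by construction, physiologically naive;
* **files** are written in the Sleep-EDF dialect: a 16-bit EDF signal
  file (physical range +/-250 uV) and an EDF+ hypnogram with R&K
  annotations (N3 bouts alternate between ``Sleep stage 3`` and ``Sleep
  stage 4`` so the S3/S4 merge is exercised), padded with leading and
  trailing wake so peripheral-wake trimming has work to do.

This is test scaffolding with realistic statistics, not a physiological
EEG simulator: there are no artifacts, no K-complex morphology, no
EOG/EMG channels and no inter-subject variability beyond the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import edf
from .stages import N_STAGES, StageLabel, rk_to_annotation

__all__ = [
    "HypnogramModel", "StageSignalModel", "default_hypnogram_model",
    "generate_hypnogram", "generate_epoch_signal", "generate_recording_arrays",
    "generate_dataset",
]

#: Canonical sleep-cassette stage proportions the default chain targets.
TARGET_PROPORTIONS = np.array([0.19, 0.07, 0.42, 0.14, 0.18])


@dataclass
class HypnogramModel:
    """First-order Markov model of a night's stage sequence."""

    initial: np.ndarray
    transition: np.ndarray
    mean_bout_epochs: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.mean_bout_epochs = np.asarray(self.mean_bout_epochs, dtype=float)
        if self.transition.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition must be 5x5")
        if (self.transition < 0).any() or np.abs(
                self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must be probabilities summing to 1")
        if np.abs(self.initial.sum() - 1) > 1e-9 or (self.initial < 0).any():
            raise ValueError("initial must be a probability vector")
        expected_self = 1.0 - 1.0 / self.mean_bout_epochs
        if np.abs(np.diag(self.transition) - expected_self).max() > 1e-9:
            raise ValueError(
                "self-transition probabilities inconsistent with "
                "mean_bout_epochs (need p_self = 1 - 1/mean_bout)"
            )

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left unit eigenvector)."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def default_hypnogram_model(
    mean_bouts=(20.0, 4.0, 15.0, 10.0, 12.0),
    proportions: np.ndarray = TARGET_PROPORTIONS,
) -> HypnogramModel:
    """Chain with given mean bout lengths whose stationary distribution
    approximates the target stage proportions.

    The jump chain (where does a bout go when it ends) sends stage ``i``
    to ``j`` with probability proportional to ``proportions[j] /
    mean_bouts[j]`` — the rate at which ``j``-bouts must be entered for
    ``j`` to hold its share of epochs.
    """
    b = np.asarray(mean_bouts, dtype=float)
    if (b < 1).any():
        raise ValueError("mean bout lengths must be >= 1 epoch")
    entry_rate = np.asarray(proportions, float) / b
    T = np.zeros((N_STAGES, N_STAGES))
    for i in range(N_STAGES):
        jump = entry_rate.copy()
        jump[i] = 0.0
        jump = jump / jump.sum()
        T[i] = jump / b[i]
        T[i, i] = 1.0 - 1.0 / b[i]
    init = np.zeros(N_STAGES)
    init[StageLabel.N1] = 1.0  # nights enter sleep through N1
    return HypnogramModel(initial=init, transition=T, mean_bout_epochs=b)


def generate_hypnogram(model: HypnogramModel, n_epochs: int,
                       seed: int) -> np.ndarray:
    """Sample a stage sequence of length ``n_epochs``; deterministic in
    ``seed``."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_epochs, dtype=np.int64)
    state = int(rng.choice(N_STAGES, p=model.initial))
    for i in range(n_epochs):
        out[i] = state
        state = int(rng.choice(N_STAGES, p=model.transition[state]))
    return out


@dataclass
class StageSignalModel:
    """Stage-dependent oscillatory signature of the synthetic EEG.

    ``bands`` maps each stage to ``(f_lo Hz, f_hi Hz, relative_power)``
    triples; each band contributes a sinusoid of amplitude
    ``amp_scale * sqrt(relative_power)`` at a frequency drawn uniformly
    from the band.  ``spindle_rate`` adds that many 1-s Hann-windowed
    12-14 Hz bursts per N2 epoch.
    """

    bands: dict = field(default_factory=lambda: {
        int(StageLabel.W): [(8.0, 13.0, 1.0), (15.0, 25.0, 0.3)],
        int(StageLabel.N1): [(4.0, 8.0, 1.0)],
        int(StageLabel.N2): [(4.0, 8.0, 0.8), (0.5, 2.0, 0.3)],
        int(StageLabel.N3): [(0.5, 2.0, 1.5), (4.0, 8.0, 0.3)],
        int(StageLabel.REM): [(4.0, 8.0, 0.7), (15.0, 25.0, 0.5)],
    })
    noise_sd: float = 5.0
    spindle_rate: float = 2.0
    spindle_band: tuple = (12.0, 14.0)
    amp_scale: float = 20.0

    def __post_init__(self):
        for stage, triples in self.bands.items():
            for lo, hi, power in triples:
                if not 0 < lo <= hi or power < 0:
                    raise ValueError(
                        f"invalid band ({lo}, {hi}, {power}) for stage {stage}"
                    )


def generate_epoch_signal(stage: int, model: StageSignalModel, fs: float,
                          seed: int) -> np.ndarray:
    """One 30-s epoch of synthetic EEG (microvolts) for ``stage``."""
    rng = np.random.default_rng(seed)
    n = int(round(30 * fs))
    t = np.arange(n) / fs
    for lo, hi, _ in model.bands.get(int(stage), []):
        if hi >= fs / 2:
            raise ValueError(f"band ({lo}, {hi}) exceeds Nyquist for fs={fs}")
    sig = np.zeros(n)
    for lo, hi, power in model.bands.get(int(stage), []):
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        sig += model.amp_scale * np.sqrt(power) * np.sin(2 * np.pi * f * t + phase)
    if int(stage) == int(StageLabel.N2) and model.spindle_rate > 0:
        n_bursts = rng.poisson(model.spindle_rate)
        for _ in range(n_bursts):
            f = rng.uniform(*model.spindle_band)
            start = rng.uniform(0, 29.0)
            dur = 1.0
            mask = (t >= start) & (t < start + dur)
            env = np.hanning(int(mask.sum())) if mask.any() else None
            if env is not None:
                sig[mask] += (model.amp_scale * env
                              * np.sin(2 * np.pi * f * t[mask]))
    if model.noise_sd > 0:
        sig += rng.normal(0, model.noise_sd, size=n)
    return sig


def _pad_wake(labels: np.ndarray, pad: int) -> np.ndarray:
    w = np.full(pad, int(StageLabel.W), dtype=np.int64)
    return np.concatenate([w, labels, w])


def generate_recording_arrays(
    n_epochs: int, seed: int, fs: float = 100.0,
    hyp_model: HypnogramModel | None = None,
    sig_model: StageSignalModel | None = None,
    pad_epochs: int = 70,
):
    """(signal, labels) arrays for one synthetic night.

    The Markov section is book-ended with ``pad_epochs`` wake epochs on
    each side (shrunk if ``n_epochs`` is too small to leave at least 20
    sleep epochs), exercising peripheral-wake trimming downstream.
    """
    hyp_model = hyp_model or default_hypnogram_model()
    sig_model = sig_model or StageSignalModel()
    pad = min(pad_epochs, max((n_epochs - 20) // 2, 0))
    core = generate_hypnogram(hyp_model, n_epochs - 2 * pad, seed)
    labels = _pad_wake(core, pad)
    spe = int(round(30 * fs))
    signal = np.empty(len(labels) * spe)
    seeds = np.random.default_rng([seed, 1]).integers(2**31, size=len(labels))
    for i, stage in enumerate(labels):
        signal[i * spe:(i + 1) * spe] = generate_epoch_signal(
            int(stage), sig_model, fs, int(seeds[i]))
    return signal, labels


def _labels_to_rk_runs(labels: np.ndarray):
    """Compress stage codes into (onset_s, duration_s, R&K annotation) runs.

    N3 carries both of the legacy deep-sleep labels: a run of two or more
    epochs is written as an S3 stretch followed by an S4 stretch (the
    night deepens through S3 into S4), so the S3/S4 -> N3 merge is always
    exercised on re-load; single-epoch N3 runs alternate between the two.
    """
    runs = []
    start = 0
    n3_toggle = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            stage = StageLabel(int(labels[start]))
            length = i - start
            if stage is StageLabel.N3:
                if length >= 2:
                    first = (length + 1) // 2
                    runs.append((start * 30.0, first * 30.0,
                                 rk_to_annotation("S3")))
                    runs.append(((start + first) * 30.0,
                                 (length - first) * 30.0,
                                 rk_to_annotation("S4")))
                else:
                    rk = "S3" if n3_toggle % 2 == 0 else "S4"
                    n3_toggle += 1
                    runs.append((start * 30.0, 30.0, rk_to_annotation(rk)))
            else:
                rk = {"W": "W", "N1": "S1", "N2": "S2",
                      "REM": "REM"}[stage.name]
                runs.append((start * 30.0, length * 30.0,
                             rk_to_annotation(rk)))
            start = i
    return runs


def generate_dataset(n_subjects: int, epochs_per_subject: int, seed: int,
                     out_dir, fs: float = 100.0,
                     hyp_model: HypnogramModel | None = None,
                     sig_model: StageSignalModel | None = None,
                     pad_epochs: int = 70) -> list:
    """Write one EDF + EDF+ hypnogram pair per synthetic subject.

    Returns the flat list of created paths (2 per subject).  Files
    round-trip through :func:`hypnonet.io.load_recording`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(n_subjects):
        sub_seed = int(np.random.default_rng([seed, s]).integers(2**31))
        signal, labels = generate_recording_arrays(
            epochs_per_subject, sub_seed, fs=fs,
            hyp_model=hyp_model, sig_model=sig_model, pad_epochs=pad_epochs)
        sid = f"SYN{s:02d}"
        psg = out_dir / f"{sid}-PSG.edf"
        hyp = out_dir / f"{sid}-Hypnogram.edf"
        try:
            edf.write_edf_signal(psg, signal, fs, "EEG Fpz-Cz")
            onsets, durs, descs = zip(*_labels_to_rk_runs(labels))
            edf.write_edf_annotations(hyp, onsets, durs, descs)
        except OSError as e:
            raise OSError(f"failed writing synthetic files for {sid}: {e}") from e
        paths.extend([psg, hyp])
    return paths
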