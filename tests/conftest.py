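"""Shared fixtures: synthetic nights, recordings and desk-scale configs.

Everything is generated programmatically at test time; sizes are chosen so
the whole suite runs in minutes on one CPU.
"""

import numpy as np
import pytest

from hypnonet.io import EpochDataset, Recording
from hypnonet.model import ModelConfig
from hypnonet.stages import StageLabel
from hypnonet.synthetic import (
    StageSignalModel,
    default_hypnogram_model,
    generate_dataset,
    generate_epoch_signal,
    generate_recording_arrays,
)


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """Three synthetic subjects written as EDF + hypnogram pairs."""
    out = tmp_path_factory.mktemp("edf")
    generate_dataset(3, 200, seed=11, out_dir=out)
    return out


@pytest.fixture(scope="session")
def recordings(synth_dir):
    from hypnonet.io import load_recording

    recs = []
    for psg in sorted(synth_dir.glob("*-PSG.edf")):
        hyp = psg.with_name(psg.name.replace("-PSG.edf", "-Hypnogram.edf"))
        recs.append(load_recording(psg, hyp, "EEG Fpz-Cz"))
    return recs


@pytest.fixture(scope="session")
def tiny_cfg():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def separable_two_class_ds():
    """Alpha-wave W epochs vs delta-wave N3 epochs: separable by design."""
    sm = StageSignalModel()
    X, y = [], []
    for i in range(60):
        X.append(generate_epoch_signal(int(StageLabel.W), sm, 100, 1000 + i))
        y.append(int(StageLabel.W))
        X.append(generate_epoch_signal(int(StageLabel.N3), sm, 100, 2000 + i))
        y.append(int(StageLabel.N3))
    return EpochDataset(np.array(X), np.array(y),
                        np.array(["synthetic"] * len(y), dtype=object))


def make_label_recording(labels, subject_id="toy", fs=4.0, seed=0):
    """Recording whose signal content is irrelevant (noise); used by
    sampler tests that only look at labels and indices.  A low sampling
    rate keeps the arrays small."""
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    spe = int(30 * fs)
    return Recording(subject_id, "EEG Fpz-Cz", fs,
                     rng.normal(size=spe * len(labels)), labels)


@pytest.fixture(scope="session")
def wake_dominated_recordings():
    """Markov hypnograms with very long W self-transition runs — the
    skew the transition-balancing sampler exists to counter."""
    model = default_hypnogram_model(
        mean_bouts=(60.0, 3.0, 20.0, 8.0, 10.0),
        proportions=np.array([0.55, 0.05, 0.25, 0.07, 0.08]),
    )
    from hypnonet.synthetic import generate_hypnogram

    recs = []
    for s in range(3):
        labels = generate_hypnogram(model, 400, seed=50 + s)
        recs.append(make_label_recording(labels, subject_id=f"W{s}", seed=s))
    return recs


@pytest.fixture(scope="session")
def small_training_recordings():
    """Four in-memory synthetic nights for desk-scale training tests."""
    recs = []
    for s in range(4):
        sig, lab = generate_recording_arrays(150, 100 + s, pad_epochs=10)
        recs.append(Recording(f"S{s}", "EEG Fpz-Cz", 100.0, sig, lab))
    return recs
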