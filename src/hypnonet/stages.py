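"""Sleep stage vocabulary and label mapping.

The whole package uses one fixed class order — W, N1, N2, N3, REM with
integer codes 0..4 — for loss weights, softmax outputs and confusion-matrix
axes alike.  Recordings scored under the older R&K convention (S1..S4) are
mapped onto the AASM five-class scheme, merging S3 and S4 into N3.
"""

from __future__ import annotations

import enum


class StageLabel(enum.IntEnum):
    """AASM sleep stage with a stable integer code."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


N_STAGES = len(StageLabel)

#: Marker returned for scored-but-unusable epochs (movement, unknown).
EXCLUDED = "excluded"

# R&K vocabulary -> AASM stage (or EXCLUDED).  Keys are canonical short
# names; annotation strings from EDF+ hypnograms are normalised before
# lookup (see ``normalize_annotation``).
_RK_TO_AASM = {
    "W": StageLabel.W,
    "S1": StageLabel.N1,
    "S2": StageLabel.N2,
    "S3": StageLabel.N3,
    "S4": StageLabel.N3,
    "REM": StageLabel.REM,
    "MOVEMENT": EXCLUDED,
    "UNKNOWN": EXCLUDED,
}

# Sleep-EDF dialect annotation descriptions.
_ANNOTATION_TO_RK = {
    "SLEEP STAGE W": "W",
    "SLEEP STAGE 1": "S1",
    "SLEEP STAGE 2": "S2",
    "SLEEP STAGE 3": "S3",
    "SLEEP STAGE 4": "S4",
    "SLEEP STAGE R": "REM",
    "SLEEP STAGE ?": "UNKNOWN",
    "MOVEMENT TIME": "MOVEMENT",
}


class LabelError(ValueError):
    """Raised for an unrecognised stage label string."""


def map_rk_to_aasm(rk_label: str):
    """Map an R&K stage name to a :class:`StageLabel` or :data:`EXCLUDED`.

    S1 -> N1, S2 -> N2, S3/S4 -> N3, W and REM pass through; movement and
    unknown epochs have no AASM class and return :data:`EXCLUDED`.

    Raises
    ------
    LabelError
        If ``rk_label`` is not in the R&K vocabulary.
    """
    key = rk_label.strip().upper()
    if key in ("MOVEMENT TIME", "MT"):
        key = "MOVEMENT"
    if key == "?":
        key = "UNKNOWN"
    if key == "R":
        key = "REM"
    try:
        return _RK_TO_AASM[key]
    except KeyError:
        raise LabelError(
            f"unrecognised R&K label {rk_label!r}; expected one of "
            f"{sorted(_RK_TO_AASM)}"
        ) from None


def annotation_to_rk(description: str) -> str:
    """Translate a Sleep-EDF annotation description to an R&K short name."""
    key = description.strip().upper()
    try:
        return _ANNOTATION_TO_RK[key]
    except KeyError:
        raise LabelError(
            f"unrecognised hypnogram annotation {description!r}"
        ) from None


_RK_TO_ANNOTATION = {
    "W": "Sleep stage W",
    "S1": "Sleep stage 1",
    "S2": "Sleep stage 2",
    "S3": "Sleep stage 3",
    "S4": "Sleep stage 4",
    "REM": "Sleep stage R",
    "UNKNOWN": "Sleep stage ?",
    "MOVEMENT": "Movement time",
}


def rk_to_annotation(rk: str) -> str:
    """Inverse of :func:`annotation_to_rk` (Sleep-EDF dialect)."""
    try:
        return _RK_TO_ANNOTATION[rk.upper()]
    except KeyError:
        raise LabelError(f"no Sleep-EDF annotation for R&K label {rk!r}") from None
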