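"""Minimal EDF / EDF+ writers (Sleep-EDF dialect).

Only what the synthetic-data generator needs: a single-channel 16-bit EDF
signal file and an annotation-only EDF+ hypnogram whose time-stamped
annotation lists (TALs) carry ``Sleep stage ...`` events.  Reading goes
through :mod:`mne` (see :mod:`hypnonet.io`); these writers exist because
writing EDF is not covered by the installed readers, and they are kept
strict enough that their output round-trips through ``mne.io.read_raw_edf``
and ``mne.read_annotations``.
"""

from __future__ import annotations

import numpy as np

#: Physical amplitude range written to EDF headers, in microvolts.
DEFAULT_PHYS_RANGE = 250.0

_RECORD_SECONDS = 30


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise ValueError(f"EDF header field too long: {s!r} > {n} bytes")
    return b + b" " * (n - len(b))


def write_edf_signal(path, signal, fs: float, channel: str,
                     phys_range: float = DEFAULT_PHYS_RANGE):
    """Write a one-channel EDF file (16-bit, 30-s data records).

    ``signal`` is in physical units (microvolts); samples outside
    ``[-phys_range, +phys_range]`` are clipped.  Trailing samples that do
    not fill a whole data record are dropped.
    """
    signal = np.asarray(signal, dtype=float)
    spr = int(round(fs * _RECORD_SECONDS))
    ndr = len(signal) // spr
    if ndr == 0:
        raise ValueError(f"signal shorter than one {_RECORD_SECONDS}-s record")
    digital = np.clip(
        np.round(signal[: ndr * spr] / phys_range * 32767), -32768, 32767
    ).astype("<i2")
    hdr = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2001 X X X", 80),
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * 2), 8),
        _pad("", 44),
        _pad(str(ndr), 8),
        _pad(str(_RECORD_SECONDS), 8),
        _pad("1", 4),
        _pad(channel, 16),
        _pad("AgAgCl electrode", 80),
        _pad("uV", 8),
        _pad(str(-phys_range), 8),
        _pad(str(phys_range), 8),
        _pad("-32768", 8),
        _pad("32767", 8),
        _pad("", 80),
        _pad(str(spr), 8),
        _pad("", 32),
    ])
    with open(path, "wb") as f:
        f.write(hdr)
        f.write(digital.tobytes())


def _fmt(x: float) -> str:
    return f"{x:g}"


def write_edf_annotations(path, onsets, durations, descriptions):
    """Write an annotation-only EDF+C file (one ``EDF Annotations`` signal,
    one data record holding every TAL)."""
    tals = b"+0\x14\x14\x00"
    for onset, dur, desc in zip(onsets, durations, descriptions):
        tals += (
            f"+{_fmt(onset)}\x15{_fmt(dur)}\x14{desc}\x14\x00".encode("ascii")
        )
    nsamp = (len(tals) + 1) // 2
    payload = tals + b"\x00" * (nsamp * 2 - len(tals))
    hdr = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2001 X X X", 80),
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * 2), 8),
        _pad("EDF+C", 44),
        _pad("1", 8),
        _pad("0", 8),
        _pad("1", 4),
        _pad("EDF Annotations", 16),
        _pad("", 80),
        _pad("", 8),
        _pad("0", 8),
        _pad("1", 8),
        _pad("-32768", 8),
        _pad("32767", 8),
        _pad("", 80),
        _pad(str(nsamp), 8),
        _pad("", 32),
    ])
    with open(path, "wb") as f:
        f.write(hdr)
        f.write(payload)
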