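"""Single-channel EEG recording and label-track I/O.

Recordings travel as :class:`EEGRecording` (samples in microvolts plus
acquisition metadata). Two on-disk formats are supported:

* a self-describing CSV dialect — a ``#``-prefixed header block carrying
  ``fs``, ``channel``, ``bits``, ``subject_id`` and ``group``, then one
  sample per line in microvolts; diff-able and convenient as a fixture;
* EDF (European Data Format), read through :mod:`mne` and written with a
  minimal built-in single-signal 16-bit writer.

Per-second attention labels travel as :class:`LabelTrack`: one token per
second drawn from ``{attentive, inattentive, discard}`` (``A``/``I``/``X``
accepted as shorthand on disk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ATTENTIVE = "attentive"
INATTENTIVE = "inattentive"
DISCARD = "discard"
LABELS = (ATTENTIVE, INATTENTIVE, DISCARD)

#: accepted on-disk spellings for each label
_LABEL_ALIASES = {
    "a": ATTENTIVE,
    "attentive": ATTENTIVE,
    "i": INATTENTIVE,
    "inattentive": INATTENTIVE,
    "x": DISCARD,
    "d": DISCARD,
    "discard": DISCARD,
}


class FormatError(ValueError):
    """A file failed to parse in its declared format."""


@dataclass
class EEGRecording:
    """A single-channel sampled voltage series with acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz (the reference device samples at 512 Hz).
    bits : int
        Quantization depth of the acquisition hardware.
    channel : str
        Sensor site in 10-20 nomenclature; the reference device uses Fp1.
    subject_id : str
        Opaque subject identifier.
    group : str
        Categorical metadata used to train separate classifiers
        (typically gender, ``M``/``F``/``unknown``).
    """

    samples: np.ndarray
    fs: float
    bits: int = 16
    channel: str = "Fp1"
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Length in seconds (= n_samples / fs)."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        """Copy of this recording with the voltage series replaced."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class LabelTrack:
    """Per-second attention labels for one recording."""

    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [self._canon(t) for t in self.labels]

    @staticmethod
    def _canon(token: str) -> str:
        key = str(token).strip().lower()
        if key not in _LABEL_ALIASES:
            raise FormatError(f"unknown label token {token!r}")
        return _LABEL_ALIASES[key]

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def __iter__(self):
        return iter(self.labels)

    def validate_against(self, rec: EEGRecording) -> None:
        """Check this track covers the recording, one label per whole second."""
        need = math.floor(rec.duration)
        if len(self.labels) != need:
            raise ValueError(
                f"label track has {len(self.labels)} entries but the recording "
                f"spans {need} whole seconds"
            )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("fs", "channel", "bits", "subject_id", "group")


def _write_csv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs: {rec.fs:g}\n")
        fh.write(f"# channel: {rec.channel}\n")
        fh.write(f"# bits: {rec.bits}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# group: {rec.group}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def _read_csv(path: Path) -> EEGRecording:
    header: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip().lower()] = val.strip()
                continue
            try:
                values.append(float(line.split(",")[0]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not a sample value: {line!r}") from exc
    if "fs" not in header:
        raise FormatError(f"{path}: missing required 'fs' header")
    if not values:
        raise FormatError(f"{path}: no samples")
    return EEGRecording(
        samples=np.array(values),
        fs=float(header["fs"]),
        bits=int(header.get("bits", 16)),
        channel=header.get("channel", "Fp1"),
        subject_id=header.get("subject_id", ""),
        group=header.get("group", "unknown"),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path, channel: str | None = None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    if channel is None:
        if len(names) != 1:
            raise FormatError(
                f"{path}: multi-channel EDF; pick one of {names} via the "
                "channel option"
            )
        channel = names[0]
    elif channel not in names:
        raise FormatError(f"{path}: channel {channel!r} not in {names}")
    data = raw.get_data(picks=[channel])[0] * 1e6  # mne loads volts; we keep μV
    info = _parse_edf_patient_field(path)
    name = channel[4:] if channel.startswith("EEG ") else channel
    return EEGRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        bits=16,
        channel=name,
        subject_id=info.get("subject_id", ""),
        group=info.get("group", "unknown"),
    )


def _parse_edf_patient_field(path: Path) -> dict[str, str]:
    # local-recording field, bytes 88..168 of the fixed EDF header
    with open(path, "rb") as fh:
        fh.seek(8 + 80)
        rec_field = fh.read(80).decode("ascii", errors="replace")
    out: dict[str, str] = {}
    for tok in rec_field.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            out[k] = v
    return out


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: one signal, 1-second data records, 16-bit."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = math.ceil(rec.n_samples / spr)
    x = np.zeros(n_rec * spr)
    x[: rec.n_samples] = rec.samples

    phys_min, phys_max = float(x.min()), float(x.max())
    if phys_max - phys_min < 1e-12:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii", errors="replace")[:width]
        return b + b" " * (width - len(b))

    recording_field = f"Startdate X subject_id={rec.subject_id or 'X'} group={rec.group}"
    header = b"".join(
        [
            f("0", 8),
            f(rec.subject_id or "X", 80),
            f(recording_field, 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 + 256), 8),  # header bytes: fixed + one signal header
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),  # record duration, seconds
            f("1", 4),  # number of signals
            # per-signal header fields, one signal each
            f(f"EEG {rec.channel}", 16),
            f("AgAgCl dry electrode", 80),
            f("uV", 8),
            f(f"{phys_min:.6g}", 8),
            f(f"{phys_max:.6g}", 8),
            f(str(dig_min), 8),
            f(str(dig_max), 8),
            f("LP:50Hz", 80),
            f(str(spr), 8),
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("edf", "csv"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "csv"


def read_recording(path, format: str | None = None, channel: str | None = None) -> EEGRecording:
    """Read a single-channel recording from CSV or EDF.

    ``format`` defaults from the file extension. For a multi-channel EDF a
    ``channel`` name must be given; the error lists the channels found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path, channel)
    return _read_csv(path)


def write_recording(rec: EEGRecording, path, format: str | None = None) -> None:
    """Write a recording to CSV (exact decimal text) or EDF (16-bit)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_csv(rec, path)


def read_label_track(path) -> LabelTrack:
    """Read per-second labels, one token per line (or first CSV column).

    Lines may be ``attentive``/``inattentive``/``discard`` or the short
    forms ``A``/``I``/``X``. An unknown token raises :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    tokens: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split(",")[-1].strip()
            try:
                tokens.append(LabelTrack._canon(tok))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return LabelTrack(tokens)


def write_label_track(track: LabelTrack | Sequence[str], path) -> None:
    labels = list(track)
    with open(path, "w") as fh:
        for tok in labels:
            fh.write(LabelTrack._canon(tok) + "\n")
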