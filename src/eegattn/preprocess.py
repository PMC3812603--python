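"""Filtering and windowing of raw recordings.

The reference pipeline low-pass filters the raw trace at 50 Hz and cuts it
into 512-sample windows advanced by 256 samples (at 512 Hz: 1-second
windows, half-second hop). Each window inherits an attention label from
the per-second label track; a window whose seconds disagree — or that
touches a discarded second — is itself discarded (unanimity rule), which
mirrors the exclusion of ambiguous data during label curation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import DISCARD, EEGRecording, LabelTrack

logger = logging.getLogger(__name__)

#: window length in samples (1 s at the 512 Hz device rate)
WINDOW = 512
#: hop between consecutive windows in samples
HOP = 256


@dataclass
class Segment:
    """One analysis window: ``win`` consecutive samples plus its label."""

    samples: np.ndarray
    start_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be 1-D")


def lowpass(
    rec: EEGRecording,
    cutoff: float = 50.0,
    order: int = 4,
    family: str = "butter",
) -> EEGRecording:
    """Zero-phase low-pass filter.

    A Butterworth filter of the given order is applied forward and backward
    (``sosfiltfilt``), so the passband is maximally flat and the net phase
    shift is zero. Output length equals input length.
    """
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={rec.fs / 2:g}), got {cutoff}"
        )
    if family != "butter":
        raise ValueError(f"unsupported filter family {family!r}")
    sos = sps.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(filtered)


def make_segments(
    rec: EEGRecording, win: int = WINDOW, hop: int = HOP
) -> list[Segment]:
    """Cut a recording into overlapping fixed-length windows.

    Windows start at 0, hop, 2·hop, …; the count is
    ``floor((n - win)/hop) + 1``. Trailing samples that cannot fill a
    window are dropped — no padding, so every window feeds the FFT exactly
    ``win`` points.
    """
    if win <= 0 or hop <= 0:
        raise ValueError("win and hop must be positive")
    n = rec.n_samples
    if n < win:
        logger.warning(
            "recording of %d samples is shorter than one %d-sample window; "
            "no segments produced",
            n,
            win,
        )
        return []
    count = (n - win) // hop + 1
    return [
        Segment(samples=rec.samples[i * hop : i * hop + win], start_index=i * hop)
        for i in range(count)
    ]


def label_segment(seg: Segment, track: LabelTrack, fs: float) -> str:
    """Label one window from the per-second track (unanimity rule).

    The window spans ``[start/fs, (start + len)/fs)`` seconds; it takes the
    common label of every second it touches, or ``discard`` if the touched
    seconds disagree or any of them is itself discarded.
    """
    first = math.floor(seg.start_index / fs)
    last = math.ceil((seg.start_index + seg.samples.size) / fs) - 1
    if last >= len(track):
        raise ValueError(
            f"label track of {len(track)} s does not cover a window ending "
            f"at second {last}"
        )
    touched = {track[s] for s in range(first, last + 1)}
    if len(touched) == 1:
        return touched.pop()
    return DISCARD


def label_segments(
    segments: list[Segment], track: LabelTrack, fs: float
) -> list[Segment]:
    """Assign a label to every window in place and return the list."""
    for seg in segments:
        seg.label = label_segment(seg, track, fs)
    return segments
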