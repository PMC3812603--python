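"""Band-power features from 512-point spectra.

Each window's power spectral density is the periodogram of the unwindowed
(rectangular) 512-point FFT,

    P(n) = |F(n)|^2 / N,   N = 512,

where bin ``n`` sits at frequency ``n · fs/N`` Hz (0-based, bin 0 = DC;
at fs = 512 Hz and N = 512 the resolution is exactly 1 Hz per bin). With
this normalisation the spectrum obeys Parseval's identity
``Σ_n P(n) = Σ_t x(t)^2`` exactly, which the tests exploit.

Five features describe a window: the one-sided band energies E_alpha
(8–13 Hz), E_beta (14–30 Hz), E_theta (4–7 Hz), E_delta (1–3 Hz), and the
ratio R = E_alpha/E_beta, a standard relaxation-vs-arousal index. Band
energies sum positive-frequency bins only, without the conventional
factor 2 — the features are used comparatively and in a ratio, so a global
constant is irrelevant. The delta band nominally starts at 0.5 Hz, but
1-Hz bins have no 0.5 Hz bin, so delta sums bins 1–3; DC is excluded
because it carries sensor offset, not brain rhythm. The gamma band
(31–50 Hz) exists in the signal model but is never featurized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DISCARD, EEGRecording, LabelTrack
from .preprocess import HOP, WINDOW, Segment, label_segments, lowpass, make_segments

logger = logging.getLogger(__name__)

N_FFT = 512

#: inclusive band edges in Hz, keyed by band name
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

#: feature-column order used throughout the package
FEATURE_COLUMNS = ["E_alpha", "E_beta", "E_theta", "E_delta", "R"]

DATASET_COLUMNS = [
    "subject_id",
    "group",
    "start_index",
    "E_alpha",
    "E_beta",
    "E_theta",
    "E_delta",
    "R",
    "label",
]


class DegenerateSegmentError(ValueError):
    """A window with zero beta energy; its alpha/beta ratio is undefined."""


@dataclass
class PowerSpectrum:
    """Two-sided periodogram of one window: ``P[n] = |F(n)|²/N``."""

    P: np.ndarray
    bin_hz: float

    def frequency(self, n: int) -> float:
        return n * self.bin_hz


def compute_psd(seg: Segment | np.ndarray, fs: float = 512.0, taper: str | None = None) -> PowerSpectrum:
    """Periodogram of a 512-sample window.

    ``taper=None`` (default) uses the plain rectangular FFT; ``"hann"``
    applies a Hann window for users sensitive to spectral leakage (the
    Parseval identity then holds for the tapered series).
    """
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=np.float64)
    if x.shape != (N_FFT,):
        raise ValueError(f"segment must have exactly {N_FFT} samples, got {x.shape}")
    if taper == "hann":
        x = x * np.hanning(N_FFT)
    elif taper not in (None, "none"):
        raise ValueError(f"unknown taper {taper!r}")
    F = np.fft.fft(x)
    P = (F * F.conj()).real / N_FFT
    return PowerSpectrum(P=P, bin_hz=fs / N_FFT)


def band_energy(ps: PowerSpectrum, band: str) -> float:
    """One-sided sum of PSD bins whose center frequency lies in ``band``."""
    if band not in BAND_EDGES:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BAND_EDGES)}")
    lo, hi = BAND_EDGES[band]
    n = ps.P.size
    nyquist_bin = n // 2
    freqs = np.arange(nyquist_bin + 1) * ps.bin_hz
    mask = (freqs >= lo) & (freqs <= hi)
    return float(ps.P[: nyquist_bin + 1][mask].sum())


def alpha_beta_ratio(Ea: float, Eb: float) -> float:
    """R = E_alpha / E_beta; raises on a degenerate window.

    A window is degenerate when E_beta vanishes — exactly zero, or below
    1e-9 of E_alpha, which is numerically indistinguishable from zero for
    a 512-point double-precision periodogram.
    """
    if Ea < 0 or Eb < 0:
        raise ValueError("band energies must be non-negative")
    if Eb == 0 or Eb <= 1e-9 * Ea:
        raise DegenerateSegmentError("E_beta vanishes; alpha/beta ratio undefined")
    return Ea / Eb


def extract_features(
    seg: Segment,
    fs: float = 512.0,
    group: str = "unknown",
    subject_id: str = "",
    taper: str | None = None,
) -> dict:
    """Featurize one labeled window into the five-number description."""
    ps = compute_psd(seg, fs=fs, taper=taper)
    Ea = band_energy(ps, "alpha")
    Eb = band_energy(ps, "beta")
    Et = band_energy(ps, "theta")
    Ed = band_energy(ps, "delta")
    return {
        "subject_id": subject_id,
        "group": group,
        "start_index": seg.start_index,
        "E_alpha": Ea,
        "E_beta": Eb,
        "E_theta": Et,
        "E_delta": Ed,
        "R": alpha_beta_ratio(Ea, Eb),
        "label": seg.label,
    }


class BandPowerExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer from raw windows to the five band-power features.

    Accepts an ``(n_windows, 512)`` array and returns ``(n_windows, 5)``
    columns in :data:`FEATURE_COLUMNS` order. Windows are assumed already
    filtered; use :func:`extract_dataset` for the full recording-level
    pipeline. Fitting only records the input dimension.
    """

    def __init__(self, fs: float = 512.0, taper: str | None = None):
        self.fs = fs
        self.taper = taper

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != N_FFT:
            raise ValueError(f"X must be (n_windows, {N_FFT}), got {X.shape}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != N_FFT:
            raise ValueError(f"X must be (n_windows, {N_FFT}), got {X.shape}")
        out = np.empty((X.shape[0], 5))
        for i, row in enumerate(X):
            ps = compute_psd(row, fs=self.fs, taper=self.taper)
            Ea = band_energy(ps, "alpha")
            Eb = band_energy(ps, "beta")
            out[i] = (
                Ea,
                Eb,
                band_energy(ps, "theta"),
                band_energy(ps, "delta"),
                alpha_beta_ratio(Ea, Eb),
            )
        return out


def extract_dataset(
    recs: Iterable[tuple[EEGRecording, LabelTrack]],
    cutoff: float = 50.0,
    filter_order: int = 4,
    win: int = WINDOW,
    hop: int = HOP,
    taper: str | None = None,
) -> pd.DataFrame:
    """Filter, window, label and featurize a collection of recordings.

    Windows labeled ``discard`` (including label-straddling windows) and
    degenerate windows (zero beta energy) are dropped; kept/dropped counts
    are logged. Returns a DataFrame with :data:`DATASET_COLUMNS`.
    """
    rows: list[dict] = []
    n_discard = 0
    n_degenerate = 0
    for rec, track in recs:
        track.validate_against(rec)
        filtered = lowpass(rec, cutoff=cutoff, order=filter_order)
        segments = label_segments(make_segments(filtered, win=win, hop=hop), track, rec.fs)
        for seg in segments:
            if seg.label == DISCARD:
                n_discard += 1
                continue
            try:
                rows.append(
                    extract_features(
                        seg,
                        fs=rec.fs,
                        group=rec.group,
                        subject_id=rec.subject_id,
                        taper=taper,
                    )
                )
            except DegenerateSegmentError:
                n_degenerate += 1
    logger.info(
        "extract_dataset: kept %d windows, dropped %d discarded, %d degenerate",
        len(rows),
        n_discard,
        n_degenerate,
    )
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "group": str, "label": str})
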