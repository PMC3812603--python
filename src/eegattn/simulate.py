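"""Synthetic single-channel EEG with a controllable attention effect.

Real attentive/inattentive recordings from classroom studies are not
publicly deposited, so the pipeline is exercised on simulated Fp1-style
traces. Each one-second stretch of signal is a sum of five band-limited
random-phase components (δ 0.5–3, θ 4–7, α 8–13, β 14–30, γ 31–50 Hz),
plus broadband Gaussian sensor noise and, optionally, transient
motion-artifact bursts typical of dry electrodes.

Each band's per-second amplitude is drawn uniformly from the
conventional resting ranges (δ 100–200, θ 10–30, α 30–50, β 5–20,
γ 5–10 μV, expressed as sinusoid-equivalent amplitude = RMS·√2) and then
multiplied by a per-state gain. The default gains encode the
qualitative physiology of attention — frontal β rises when a subject is
attentive while θ and α fall — as amplitude factors:

    attentive:   β ×1.5, θ ×0.7, α ×0.8, δ ×1.0, γ ×1.0
    inattentive: all ×1.0

These are directional settings, not measured effect sizes; setting both
states' gains equal yields a null dataset on which any classifier should
sit at chance. Components are phase-continuous across seconds within a
state block, and everything is reproducible from (seed, config,
schedule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import ATTENTIVE, INATTENTIVE, EEGRecording, LabelTrack

logger = logging.getLogger(__name__)

#: per band: (low Hz, high Hz, low amplitude μV, high amplitude μV)
DEFAULT_BAND_TABLE: dict[str, tuple[float, float, float, float]] = {
    "delta": (0.5, 3.0, 100.0, 200.0),
    "theta": (4.0, 7.0, 10.0, 30.0),
    "alpha": (8.0, 13.0, 30.0, 50.0),
    "beta": (14.0, 30.0, 5.0, 20.0),
    "gamma": (31.0, 50.0, 5.0, 10.0),
}

DEFAULT_STATE_GAIN: dict[str, dict[str, float]] = {
    ATTENTIVE: {"delta": 1.0, "theta": 0.7, "alpha": 0.8, "beta": 1.5, "gamma": 1.0},
    INATTENTIVE: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
}


def null_state_gain() -> dict[str, dict[str, float]]:
    """Gains with no attentive/inattentive difference (chance-level data)."""
    unit = {b: 1.0 for b in DEFAULT_BAND_TABLE}
    return {ATTENTIVE: dict(unit), INATTENTIVE: dict(unit)}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the standard conditions."""

    fs: float = 512.0
    band_table: dict = field(default_factory=lambda: dict(DEFAULT_BAND_TABLE))
    state_gain: dict = field(default_factory=lambda: {s: dict(g) for s, g in DEFAULT_STATE_GAIN.items()})
    noise_sigma: float = 5.0  # μV, broadband sensor noise
    artifact_rate: float = 0.0  # expected bursts per minute
    artifact_magnitude: float = 300.0  # μV
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fs / 2
        for band, (lo, hi, a_lo, a_hi) in self.band_table.items():
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band {band}: range [{lo}, {hi}] outside (0, {nyq})")
            if not 0 <= a_lo <= a_hi:
                raise ValueError(f"band {band}: bad amplitude range [{a_lo}, {a_hi}]")
        for state, gains in self.state_gain.items():
            if any(g <= 0 for g in gains.values()):
                raise ValueError(f"state {state}: gains must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def with_null_effect(self) -> "SyntheticConfig":
        return replace(self, state_gain=null_state_gain())


def _bandlimited_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS random-phase oscillation confined to [lo, hi] Hz."""
    white = rng.standard_normal(n + 2 * int(fs))  # pad to wash out filter edges
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[int(fs) : int(fs) + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_band_component(
    band_range: tuple[float, float],
    amplitude: float,
    duration: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One band-limited component with the given sinusoid-equivalent amplitude.

    The output is white noise band-passed to ``band_range`` and rescaled so
    RMS·√2 equals ``amplitude`` exactly; ≥95 % of its spectral power lies
    inside the band.
    """
    lo, hi = band_range
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band [{lo}, {hi}] must lie inside (0, Nyquist)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    if amplitude == 0:
        return np.zeros(n)
    return _bandlimited_noise(n, lo, hi, fs, rng) * (amplitude / np.sqrt(2))


def _state_blocks(schedule: list[str]) -> list[tuple[int, int, str]]:
    """Contiguous (start_second, n_seconds, state) runs of a schedule."""
    blocks = []
    start = 0
    for i in range(1, len(schedule) + 1):
        if i == len(schedule) or schedule[i] != schedule[start]:
            blocks.append((start, i - start, schedule[start]))
            start = i
    return blocks


def generate_recording(
    state_schedule: list[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
    group: str = "unknown",
) -> tuple[EEGRecording, LabelTrack]:
    """Simulate one labeled recording from a per-second state schedule.

    Per second, each band's amplitude is drawn uniformly from its baseline
    range times the state gain; within a contiguous state block each band
    component is a single phase-continuous band-limited noise process whose
    per-second RMS is set to the drawn amplitude/√2. Broadband Gaussian
    noise and (if configured) artifact bursts are added on top.
    """
    if not state_schedule:
        raise ValueError("state schedule must be nonempty")
    for s in state_schedule:
        if s not in cfg.state_gain:
            raise ValueError(f"unknown state token {s!r}; expected {sorted(cfg.state_gain)}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    spr = int(round(cfg.fs))  # samples per second
    n_total = len(state_schedule) * spr
    x = np.zeros(n_total)

    for start_s, n_s, state in _state_blocks(state_schedule):
        gains = cfg.state_gain[state]
        for band, (lo, hi, a_lo, a_hi) in cfg.band_table.items():
            base = _bandlimited_noise(n_s * spr, lo, hi, cfg.fs, rng)
            amps = rng.uniform(a_lo, a_hi, size=n_s) * gains.get(band, 1.0)
            for j in range(n_s):
                chunk = base[j * spr : (j + 1) * spr]
                rms = np.sqrt(np.mean(chunk**2))
                scale = (amps[j] / np.sqrt(2)) / rms if rms > 0 else 0.0
                sl = slice((start_s + j) * spr, (start_s + j + 1) * spr)
                x[sl] += chunk * scale

    if cfg.noise_sigma > 0:
        x += rng.normal(0, cfg.noise_sigma, size=n_total)

    rec = EEGRecording(
        samples=x, fs=cfg.fs, bits=16, channel="Fp1", subject_id=subject_id, group=group
    )
    if cfg.artifact_rate > 0:
        rec = inject_artifacts(rec, cfg.artifact_rate, cfg.artifact_magnitude, rng)
    return rec, LabelTrack(list(state_schedule))


def alternating_schedule(seconds_per_state: int, block_seconds: int | None = None) -> list[str]:
    """Attentive/inattentive blocks totalling ``seconds_per_state`` each."""
    block = block_seconds or seconds_per_state
    schedule: list[str] = []
    remaining = {ATTENTIVE: seconds_per_state, INATTENTIVE: seconds_per_state}
    state = ATTENTIVE
    while any(remaining.values()):
        take = min(block, remaining[state])
        schedule.extend([state] * take)
        remaining[state] -= take
        other = INATTENTIVE if state == ATTENTIVE else ATTENTIVE
        state = other if remaining[other] > 0 else state
        if remaining[state] == 0 and not any(remaining.values()):
            break
    return schedule


def generate_dataset(
    n_subjects: int,
    seconds_per_state: int,
    cfg: SyntheticConfig | None = None,
    group_assignment: list[str] | None = None,
    block_seconds: int | None = None,
) -> list[tuple[EEGRecording, LabelTrack]]:
    """Simulate a cohort: one recording per subject, alternating states.

    Each subject gets an independent stream seeded counter-style from
    (cfg.seed, subject index), so growing the cohort never reshuffles
    existing subjects. Groups default to alternating M/F.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    cfg = cfg or SyntheticConfig()
    if group_assignment is None:
        group_assignment = ["M" if i % 2 == 0 else "F" for i in range(n_subjects)]
    schedule = alternating_schedule(seconds_per_state, block_seconds)
    out = []
    for i in range(n_subjects):
        rng = np.random.default_rng([cfg.seed, i])
        rec, track = generate_recording(
            schedule,
            cfg,
            rng=rng,
            subject_id=f"S{i:02d}",
            group=group_assignment[i % len(group_assignment)],
        )
        out.append((rec, track))
    return out


def inject_artifacts(
    rec: EEGRecording,
    rate: float,
    magnitude: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> EEGRecording:
    """Add Poisson-placed transient bursts mimicking dry-electrode motion.

    Bursts are one-sided exponential decays of ~100 ms (25 ms time
    constant) with random sign, ``rate`` expected events per minute. The
    burst count and sample positions are logged; pass ``events`` to also
    collect them as ``(position, sign)`` tuples.
    """
    if rate < 0 or magnitude < 0:
        raise ValueError("rate and magnitude must be non-negative")
    if rate == 0:
        return rec
    n = rec.n_samples
    count = rng.poisson(rate * (n / rec.fs) / 60.0)
    x = rec.samples.copy()
    burst_len = int(round(0.1 * rec.fs))
    t = np.arange(burst_len) / rec.fs
    shape = np.exp(-t / 0.025)
    positions = []
    for _ in range(count):
        pos = int(rng.integers(0, max(1, n - burst_len)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        end = min(n, pos + burst_len)
        x[pos:end] += sign * magnitude * shape[: end - pos]
        positions.append((pos, sign))
        if events is not None:
            events.append((pos, sign))
    logger.info("injected %d artifact bursts at %s", count, [p for p, _ in positions])
    return rec.with_samples(x)
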