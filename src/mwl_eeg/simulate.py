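"""Synthetic EEG recordings and NASA-TLX surveys with the statistical
structure the workload-detection analysis assumes.

The study's own recordings are private, so every downstream stage is
exercised on simulated data: 5-channel 1/f background noise carrying
band-limited oscillations whose per-region amplitudes depend on the mental
workload level of the flight phase, transient eye-blink-like artifacts on
the frontal channels, and TLX subscale ratings drawn around published
phase-wise means.

Oscillations are narrowband-filtered Gaussian noise: complex Gaussian
spectral coefficients shaped by a Tukey-tapered envelope confined to the
band, so essentially all oscillation power lies inside the band while PSD
estimates keep realistic chi-squared variance (a pure tone would make
band-power tests degenerate). The 1/f background is synthesized the same
way with an f^(-exponent/2) amplitude envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows

from .core import (
    CHANNEL_REGION,
    DEFAULT_CHANNELS,
    MWL_LEVELS,
    PHASE_LEVEL,
    PHASES,
    Annotation,
    Recording,
)
from .features import DEFAULT_BANDS
from .labeling import N_PAIRWISE, SUBSCALES, TLXRecord, tlx_weighted_score

# ---------------------------------------------------------------------------
# EEG generation

#: Oscillation RMS amplitude (μV) per workload level x region x band.
#: The pattern follows the qualitative picture of workload-dependent band
#: power: slow-wave (δ/θ) and frontal power grow with workload, the
#: occipital α rhythm dominates at rest (low workload), and the largest
#: amplitudes reach twice the default background RMS of 5 μV.
DEFAULT_BAND_GAIN: dict[str, dict[str, dict[str, float]]] = {
    "low": {
        "frontal":   {"δ": 2.5, "θ": 2.5, "α": 4.0, "β1": 2.5, "β2": 2.5, "γ": 2.0},
        "temporal":  {"δ": 2.5, "θ": 2.5, "α": 4.0, "β1": 2.5, "β2": 2.5, "γ": 2.0},
        "occipital": {"δ": 3.0, "θ": 3.0, "α": 7.0, "β1": 3.0, "β2": 2.5, "γ": 2.0},
    },
    "middle": {
        "frontal":   {"δ": 5.0, "θ": 6.0, "α": 6.0, "β1": 4.0, "β2": 4.0, "γ": 3.0},
        "temporal":  {"δ": 4.5, "θ": 5.0, "α": 5.5, "β1": 4.0, "β2": 3.5, "γ": 3.0},
        "occipital": {"δ": 3.5, "θ": 4.0, "α": 5.0, "β1": 3.5, "β2": 3.0, "γ": 2.5},
    },
    "high": {
        "frontal":   {"δ": 10.0, "θ": 8.0, "α": 7.0, "β1": 5.0, "β2": 6.0, "γ": 4.5},
        "temporal":  {"δ": 8.0, "θ": 7.0, "α": 6.0, "β1": 6.0, "β2": 5.0, "γ": 4.0},
        "occipital": {"δ": 4.5, "θ": 4.5, "α": 5.0, "β1": 4.5, "β2": 4.0, "γ": 3.5},
    },
}

DEFAULT_PHASE_DURATIONS: dict[str, float] = {p: 60.0 for p in PHASES}


@dataclass
class SimConfig:
    """Configuration of one synthetic EEG recording.

    Amplitudes are RMS values in μV; ``band_gain[level][region][band]`` sets
    the oscillation amplitude for epochs of a given workload level. The
    sampling rate must exceed twice the highest band edge (40 Hz).
    """

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    channel_regions: dict[str, str] = field(default_factory=lambda: dict(CHANNEL_REGION))
    fs: float = 128.0
    phase_durations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS)
    )
    phase_levels: dict[str, str] = field(default_factory=lambda: dict(PHASE_LEVEL))
    band_gain: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            lvl: {reg: dict(bands) for reg, bands in regs.items()}
            for lvl, regs in DEFAULT_BAND_GAIN.items()
        }
    )
    noise_amp: float = 5.0
    noise_exponent: float = 1.0
    artifact_rate: float = 4.0  # transients per minute, frontal channels
    artifact_amp: float = 150.0  # peak μV
    artifact_duration_s: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        highest_edge = max(b.high_hz for b in DEFAULT_BANDS)
        if self.fs <= 2 * highest_edge:
            raise ValueError(f"fs {self.fs} must exceed 2 x {highest_edge} Hz")
        if self.noise_amp < 0 or self.artifact_amp < 0 or self.artifact_rate < 0:
            raise ValueError("amplitudes and rates must be >= 0")
        for phase, dur in self.phase_durations.items():
            if dur < 2.0:
                raise ValueError(
                    f"phase {phase!r} duration {dur} s shorter than one 2-s window"
                )
        for lvl, regs in self.band_gain.items():
            if lvl not in MWL_LEVELS:
                raise ValueError(f"unknown workload level {lvl!r}")
            for reg, bands in regs.items():
                for band, g in bands.items():
                    if g < 0:
                        raise ValueError(f"band_gain[{lvl}][{reg}][{band}] < 0")
        for ch in self.channel_names:
            if ch not in self.channel_regions:
                raise ValueError(f"channel {ch!r} has no region")


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  envelope: np.ndarray, target_rms: float) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral amplitude envelope,
    scaled to a target RMS. Always consumes the same number of draws so the
    RNG stream is independent of amplitude settings."""
    n_bins = n // 2 + 1
    coeffs = (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) * envelope
    coeffs[0] = 0.0
    x = np.fft.irfft(coeffs, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0 or target_rms == 0.0:
        return np.zeros(n)
    return x * (target_rms / rms)


def _band_envelope(n: int, fs: float, low_hz: float, high_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    env = np.zeros(len(freqs))
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    n_in = int(mask.sum())
    if n_in == 0:
        return env
    env[mask] = windows.tukey(n_in, alpha=0.5) if n_in > 1 else 1.0
    return env


def _pink_envelope(n: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    env = np.zeros(len(freqs))
    env[1:] = freqs[1:] ** (-exponent / 2.0)
    return env


def generate_recording(config: SimConfig) -> Recording:
    """Generate one contiguous annotated recording covering the three flight
    phases. Deterministic for a fixed (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    phase_order = [p for p in PHASES if p in config.phase_durations]
    frontal = [ch for ch in config.channel_names
               if config.channel_regions[ch] == "frontal"]

    blocks: list[np.ndarray] = []
    annotations: list[Annotation] = []
    t0 = 0.0
    for phase in phase_order:
        dur = config.phase_durations[phase]
        n = round(dur * fs)
        level = config.phase_levels[phase]
        gains = config.band_gain.get(level, {})
        pink_env = _pink_envelope(n, fs, config.noise_exponent)
        block = np.zeros((len(config.channel_names), n))
        for ci, ch in enumerate(config.channel_names):
            region = config.channel_regions[ch]
            sig = _shaped_noise(rng, n, fs, pink_env, config.noise_amp)
            for band in DEFAULT_BANDS:
                g = gains.get(region, {}).get(band.name, 0.0)
                env = _band_envelope(n, fs, band.low_hz, band.high_hz)
                sig = sig + _shaped_noise(rng, n, fs, env, g)
            block[ci] = sig
        # eye-blink-like transients: low-frequency high-amplitude pulses on
        # frontal channels only
        n_pulse = round(config.artifact_duration_s * fs)
        pulse = np.hanning(n_pulse)
        for ch in frontal:
            ci = list(config.channel_names).index(ch)
            n_events = rng.poisson(config.artifact_rate * dur / 60.0)
            starts = rng.uniform(0, max(dur - config.artifact_duration_s, 0), n_events)
            for s in starts:
                i0 = round(s * fs)
                seg = slice(i0, min(i0 + n_pulse, n))
                block[ci, seg] += config.artifact_amp * pulse[: seg.stop - seg.start]
        blocks.append(block)
        annotations.append(Annotation(phase=phase, start_s=t0, end_s=t0 + dur))
        t0 += dur

    return Recording(
        samples=np.concatenate(blocks, axis=1),
        fs=fs,
        channel_names=list(config.channel_names),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# TLX generation

#: Published phase-wise subscale means (0-100 scale).
DEFAULT_TLX_MEANS: dict[str, dict[str, float]] = {
    "take-off": {"mental": 64, "physical": 42, "temporal": 68,
                 "effort": 50, "frustration": 32, "performance": 70},
    "cruise": {"mental": 46, "physical": 41, "temporal": 51,
               "effort": 45, "frustration": 25, "performance": 78},
    "landing": {"mental": 74, "physical": 43, "temporal": 64,
                "effort": 52, "frustration": 36, "performance": 64},
}

#: Published dispersions (the ± values accompanying the means).
DEFAULT_TLX_DISPERSIONS: dict[str, dict[str, float]] = {
    "take-off": {"mental": 1.29, "physical": 1.56, "temporal": 1.31,
                 "effort": 1.33, "frustration": 1.40, "performance": 1.32},
    "cruise": {"mental": 1.53, "physical": 1.36, "temporal": 1.56,
               "effort": 1.46, "frustration": 1.26, "performance": 1.48},
    "landing": {"mental": 1.14, "physical": 1.69, "temporal": 1.50,
                "effort": 0.91, "frustration": 1.48, "performance": 1.79},
}

#: Default pairwise-comparison tallies (sum = 15). The flight task loads the
#: mental / effort / frustration subscales most heavily.
DEFAULT_TLX_WEIGHTS: dict[str, float] = {
    "mental": 5, "effort": 4, "frustration": 3,
    "physical": 2, "temporal": 1, "performance": 0,
}


@dataclass
class TLXConfig:
    """Generator settings for synthetic TLX surveys.

    The published dispersions are printed as "mean ± value" without saying
    whether the value is a standard deviation or a standard error of the
    21-participant mean; ``dispersion_kind`` exposes both readings. Under the
    default ``"se"``, per-participant SD = value x sqrt(n_reference).
    """

    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_TLX_MEANS.items()}
    )
    dispersions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_TLX_DISPERSIONS.items()}
    )
    dispersion_kind: str = "se"  # "se" or "sd"
    n_reference: int = 21
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TLX_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion_kind not in ("se", "sd"):
            raise ValueError("dispersion_kind must be 'se' or 'sd'")
        for phase, subs in self.means.items():
            for s, mu in subs.items():
                if not 0.0 <= mu <= 100.0:
                    raise ValueError(f"mean {phase}/{s}={mu} outside [0, 100]")
        total = sum(self.weights.get(s, 0.0) for s in SUBSCALES)
        if not np.isclose(total, N_PAIRWISE):
            raise ValueError(f"weight tallies sum to {total}, expected {N_PAIRWISE}")

    def participant_sd(self, phase: str, subscale: str) -> float:
        d = self.dispersions[phase][subscale]
        if self.dispersion_kind == "se":
            return d * np.sqrt(self.n_reference)
        return d


def generate_tlx(config: TLXConfig, n_participants: int) -> list[TLXRecord]:
    """Draw one TLX record per participant x phase, ratings truncated to
    [0, 100]; deterministic for a fixed (config, seed)."""
    config.validate()
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(config.seed)
    records: list[TLXRecord] = []
    for pid in range(n_participants):
        for phase in PHASES:
            if phase not in config.means:
                continue
            ratings = {}
            for s in SUBSCALES:
                mu = config.means[phase][s]
                sd = config.participant_sd(phase, s)
                ratings[s] = float(np.clip(mu + sd * rng.standard_normal(), 0.0, 100.0))
            rec = TLXRecord(
                participant=pid, phase=phase,
                ratings=ratings, weights=dict(config.weights),
            )
            rec.weighted_score = tlx_weighted_score(rec)
            records.append(rec)
    return records


def config_for_level_contrast(contrast: float = 2.0, **kwargs) -> SimConfig:
    """Convenience: a SimConfig whose strongest level-dependent gain equals
    ``contrast`` x the background noise RMS (scales the default gain table)."""
    cfg = SimConfig(**kwargs)
    peak = max(
        g for regs in cfg.band_gain.values() for bands in regs.values()
        for g in bands.values()
    )
    target_peak = contrast * cfg.noise_amp
    scale = target_peak / peak if peak > 0 else 1.0
    cfg = replace(
        cfg,
        band_gain={
            lvl: {reg: {b: g * scale for b, g in bands.items()}
                  for reg, bands in regs.items()}
            for lvl, regs in cfg.band_gain.items()
        },
    )
    return cfg
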