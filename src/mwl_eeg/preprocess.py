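"""Recording → clean epochs: filtering, bad-channel removal, segmentation,
artifact rejection.

The cleaning chain mirrors a standard portable-EEG workflow: remove channels
that are flat or clipped, low-pass to the analysis band (<= 40 Hz), cut the
signal into 2-s windows with 50 % overlap aligned to each annotated flight
phase, and drop windows whose peak-to-peak amplitude betrays ocular or motion
artifacts. Windows never span a phase boundary, so phase labels stay pure.

The low-pass is a zero-phase FIR (Hamming-window design) whose cutoff sits in
the middle of the transition band [high_cut - 2, high_cut + 10] Hz; this
meets a <1 dB passband / >20 dB stopband contract that a low-order IIR
cannot under forward-backward filtering, and keeps epochs time-aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import Recording

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    """One fixed-length analysis window."""

    samples: np.ndarray  # (channels, window_length) μV
    start_s: float
    phase: str
    quality: str = "pass"  # "pass" or "fail"
    reason: str = ""


@dataclass
class EpochSet:
    """Ordered epochs plus the provenance of how they were produced."""

    epochs: list[Epoch]
    fs: float
    channel_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_pass(self) -> int:
        return sum(1 for e in self.epochs if e.quality == "pass")

    def phases(self) -> list[str]:
        return [e.phase for e in self.epochs]


def _design_lowpass(high_cut_hz: float, fs: float, n_times: int,
                    numtaps: int = 385) -> np.ndarray:
    # cutoff centered in the transition band [high_cut - 2, high_cut + 10];
    # taps clamped so filtfilt's padding fits short recordings
    cutoff = high_cut_hz + 4.0
    if cutoff >= fs / 2.0:
        cutoff = (high_cut_hz + fs / 2.0) / 2.0
    max_taps = (n_times - 2) // 3
    numtaps = min(numtaps, max_taps)
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 9:
        raise ValueError("recording too short to filter")
    return signal.firwin(numtaps, cutoff, fs=fs)


def lowpass_filter(recording: Recording, high_cut_hz: float = 40.0) -> Recording:
    """Zero-phase low-pass; passband ripple < 1 dB up to high_cut - 2 Hz,
    stopband attenuation > 20 dB from high_cut + 10 Hz."""
    if high_cut_hz >= recording.fs / 2.0:
        raise ValueError(
            f"high_cut {high_cut_hz} Hz >= Nyquist {recording.fs / 2} Hz"
        )
    b = _design_lowpass(high_cut_hz, recording.fs, recording.n_times)
    filtered = signal.filtfilt(b, [1.0], recording.samples, axis=1)
    return recording.copy_with(samples=filtered)


def highpass_filter(recording: Recording, low_cut_hz: float = 0.5) -> Recording:
    """Optional zero-phase drift-removal high-pass (off by default in the
    pipeline); first-order Butterworth applied forward-backward."""
    if low_cut_hz <= 0 or low_cut_hz >= recording.fs / 2.0:
        raise ValueError("low_cut must be in (0, Nyquist)")
    sos = signal.butter(1, low_cut_hz, btype="highpass", fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.copy_with(samples=filtered)


def drop_bad_channels(
    recording: Recording,
    flat_var_uV2: float = 0.01,
    clip_uV: float = 500.0,
) -> Recording:
    """Remove flatlined (variance below threshold) or clipped (|sample| above
    threshold) channels; raise if nothing survives."""
    if flat_var_uV2 <= 0 or clip_uV <= 0:
        raise ValueError("thresholds must be positive")
    keep, dropped = [], []
    for i, name in enumerate(recording.channel_names):
        x = recording.samples[i]
        if np.var(x) < flat_var_uV2:
            dropped.append((name, "flat"))
        elif np.max(np.abs(x)) > clip_uV:
            dropped.append((name, "clipped"))
        else:
            keep.append(i)
    if not keep:
        raise ValueError(
            "all channels removed: "
            + ", ".join(f"{n} ({why})" for n, why in dropped)
        )
    for name, why in dropped:
        logger.info("dropping channel %s (%s)", name, why)
    return recording.copy_with(
        samples=recording.samples[keep],
        channel_names=[recording.channel_names[i] for i in keep],
    )


def segment_epochs(
    recording: Recording, window_s: float = 2.0, overlap: float = 0.5
) -> EpochSet:
    """Cut each annotated phase into windows of ``window_s`` seconds starting
    every ``window_s * (1 - overlap)`` seconds from the phase start; trailing
    partial windows are discarded. An integer-length phase of n seconds at the
    defaults yields n - 1 epochs."""
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap {overlap} outside [0, 1)")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    fs = recording.fs
    win = round(window_s * fs)
    step_s = window_s * (1.0 - overlap)
    epochs: list[Epoch] = []
    for ann in sorted(recording.annotations, key=lambda a: a.start_s):
        if ann.duration_s + 1e-9 < window_s:
            logger.warning(
                "phase %s (%.2f s) shorter than one window; zero epochs",
                ann.phase, ann.duration_s,
            )
            continue
        n_starts = math.floor((ann.duration_s - window_s) / step_s + 1e-9) + 1
        for k in range(n_starts):
            start_s = ann.start_s + k * step_s
            i0 = round(start_s * fs)
            epochs.append(
                Epoch(
                    samples=recording.samples[:, i0 : i0 + win].copy(),
                    start_s=start_s,
                    phase=ann.phase,
                )
            )
    return EpochSet(
        epochs=epochs,
        fs=fs,
        channel_names=list(recording.channel_names),
        provenance={"window_s": window_s, "overlap": overlap},
    )


def reject_epochs(epoch_set: EpochSet, ptp_uV: float = 150.0) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude on any channel exceeds
    ``ptp_uV`` as failed; raise if every epoch fails."""
    if ptp_uV <= 0:
        raise ValueError("ptp threshold must be positive")
    kept: list[Epoch] = []
    n_fail = 0
    for ep in epoch_set.epochs:
        ptp = float(np.max(np.max(ep.samples, axis=1) - np.min(ep.samples, axis=1)))
        if ptp > ptp_uV:
            n_fail += 1
            kept.append(
                Epoch(ep.samples, ep.start_s, ep.phase, quality="fail",
                      reason=f"ptp {ptp:.1f} μV > {ptp_uV} μV")
            )
        else:
            kept.append(ep)
    if n_fail == len(epoch_set.epochs) and n_fail > 0:
        raise ValueError(f"all {n_fail} epochs exceed ptp threshold {ptp_uV} μV")
    logger.info("rejected %d / %d epochs (ptp > %.0f μV)", n_fail, len(kept), ptp_uV)
    prov = dict(epoch_set.provenance)
    prov["ptp_uV"] = ptp_uV
    prov["n_rejected"] = n_fail
    return EpochSet(
        epochs=kept, fs=epoch_set.fs,
        channel_names=list(epoch_set.channel_names), provenance=prov,
    )
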