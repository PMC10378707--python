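"""Core containers shared across the pipeline.

The headset montage is fixed by the hardware: five semi-dry electrodes of the
10-20 system grouped into three scalp regions. All signal amplitudes are in
microvolts (μV) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default montage of the 5-channel wireless headset.
DEFAULT_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "T7", "T8", "Pz")

#: Scalp region for each default channel.
CHANNEL_REGION: dict[str, str] = {
    "AF3": "frontal",
    "AF4": "frontal",
    "T7": "temporal",
    "T8": "temporal",
    "Pz": "occipital",
}

REGIONS: tuple[str, ...] = ("frontal", "temporal", "occipital")

#: Flight phases in task order.
PHASES: tuple[str, ...] = ("take-off", "cruise", "landing")

#: Workload levels, low to high.
MWL_LEVELS: tuple[str, ...] = ("low", "middle", "high")

#: Workload level induced by each flight phase (recovered from the survey data
#: by :func:`mwl_eeg.labeling.test_phase_differences`; this constant is the
#: expected outcome used by the synthetic generator).
PHASE_LEVEL: dict[str, str] = {
    "take-off": "middle",
    "cruise": "low",
    "landing": "high",
}


@dataclass(frozen=True)
class Annotation:
    """A labeled, contiguous stretch of the recording (one flight phase)."""

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"annotation {self.phase}: end {self.end_s} <= start {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Multichannel EEG time series with phase annotations.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in μV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    annotations : list of Annotation
        Non-overlapping, within the signal duration.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, times) matrix")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.duration_s
        prev_end = -np.inf
        for ann in sorted(self.annotations, key=lambda a: a.start_s):
            if ann.start_s < prev_end - 1e-9:
                raise ValueError(f"annotations overlap at {ann.phase}")
            if ann.end_s > dur + 1e-9:
                raise ValueError(f"annotation {ann.phase} extends past signal end ({dur:.3f} s)")
            prev_end = ann.end_s

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def copy_with(self, samples: np.ndarray | None = None,
                  channel_names: list[str] | None = None) -> "Recording":
        return Recording(
            samples=self.samples.copy() if samples is None else samples,
            fs=self.fs,
            channel_names=list(self.channel_names if channel_names is None else channel_names),
            annotations=list(self.annotations),
        )
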