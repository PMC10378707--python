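"""Per-epoch feature extraction: band powers, time-domain statistics, entropies.

Each 2-s epoch yields, per channel, 6 band powers from the FFT periodogram,
10 time-domain features (mean, variance, standard deviation, peak-to-peak
amplitude, skewness, kurtosis, RMS, zero crossings, Hjorth mobility, Hjorth
complexity) and 2 regularity measures (sample entropy, approximate entropy):
18 features per channel, 90 for the 5-channel headset.

Conventions
-----------
* PSD: one-sided periodogram of the rectangular-windowed epoch,
  ``|f_k|^2 / (fs * N)`` with doubling of non-DC/non-Nyquist bins; band power
  integrates PSD x bin-width over bins whose frequency lies inside the closed
  band interval. An optional Hann taper is exposed.
* Band edges follow the printed integer limits; frequencies in the gaps
  between bands (e.g. 3.5 Hz) belong to no band.
* Entropies use embedding m=2 and tolerance r = 0.2 x epoch standard deviation
  unless overridden.
* Zero-variance (degenerate) inputs yield 0 for the scale-free features, with
  a flag, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .preprocess import EpochSet


@dataclass(frozen=True)
class BandDefinition:
    """A closed frequency interval [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.high_hz <= self.low_hz:
            raise ValueError(f"band {self.name}: high {self.high_hz} <= low {self.low_hz}")


#: The six canonical bands, as printed: δ 1-3, θ 4-7, α 8-11, β1 12-20,
#: β2 21-29, γ 30-40 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("δ", 1.0, 3.0),
    BandDefinition("θ", 4.0, 7.0),
    BandDefinition("α", 8.0, 11.0),
    BandDefinition("β1", 12.0, 20.0),
    BandDefinition("β2", 21.0, 29.0),
    BandDefinition("γ", 30.0, 40.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

TIME_DOMAIN_NAMES: tuple[str, ...] = (
    "mean", "vari", "std", "ptp-amp", "skewness", "kurtosis", "rms", "zc", "hm", "hc",
)

ENTROPY_NAMES: tuple[str, ...] = ("se", "ae")

#: Per-channel feature order: 6 band powers, 10 time-domain, 2 entropy.
FEATURE_NAMES: tuple[str, ...] = BAND_NAMES + TIME_DOMAIN_NAMES + ENTROPY_NAMES


@dataclass
class Spectrum:
    """DFT of one epoch channel: complex coefficients f_k for k = 0..N-1."""

    coefficients: np.ndarray
    fs: float

    @property
    def n(self) -> int:
        return len(self.coefficients)

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.fftfreq(self.n, d=1.0 / self.fs)


def fft_spectrum(x: np.ndarray, fs: float, taper: str | None = None) -> Spectrum:
    """Discrete Fourier transform of a single-channel epoch.

    ``taper="hann"`` applies a Hann window before the transform (amplitude-
    normalized so a flat spectrum keeps its mean level); default is the
    rectangular window, i.e. the raw FFT of the samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    if taper == "hann":
        w = np.hanning(len(x))
        x = x * w / np.sqrt(np.mean(w**2))
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    return Spectrum(coefficients=np.fft.fft(x), fs=fs)


def periodogram_psd(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (freqs, PSD in μV²/Hz) from a Spectrum."""
    n = spectrum.n
    n_one = n // 2 + 1
    freqs = np.abs(spectrum.freqs[:n_one])
    if n % 2 == 0:
        freqs[-1] = spectrum.fs / 2.0
    psd = np.abs(spectrum.coefficients[:n_one]) ** 2 / (spectrum.fs * n)
    # double everything except DC (and Nyquist for even n)
    last = n_one - 1 if n % 2 == 0 else n_one
    psd[1:last] *= 2.0
    return freqs, psd


def band_powers(
    spectrum: Spectrum, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Integrated band power (μV²) per band: sum of PSD x bin-width over bins
    inside the closed interval [low_hz, high_hz]."""
    freqs, psd = periodogram_psd(spectrum)
    df = spectrum.fs / spectrum.n
    out: dict[str, float] = {}
    for band in bands:
        if band.high_hz >= spectrum.fs / 2.0 + df:
            raise ValueError(f"band {band.name} exceeds Nyquist ({spectrum.fs / 2} Hz)")
        mask = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
        if not mask.any():
            raise ValueError(
                f"band {band.name} contains no bins at resolution {df:.4g} Hz"
            )
        out[band.name] = float(np.sum(psd[mask]) * df)
    return out


def total_power(spectrum: Spectrum) -> float:
    """Total periodogram power (μV²), i.e. mean squared amplitude (Parseval)."""
    _, psd = periodogram_psd(spectrum)
    return float(np.sum(psd) * spectrum.fs / spectrum.n)


def zero_crossings(x: np.ndarray) -> int:
    """Count strict sign changes between consecutive samples; exact zeros
    inherit the previous sample's sign."""
    s = np.sign(np.asarray(x, dtype=float))
    # forward-fill zero signs
    filled = s.copy()
    for i in range(1, len(filled)):
        if filled[i] == 0.0:
            filled[i] = filled[i - 1]
    nz = filled[filled != 0.0]
    if len(nz) < 2:
        return 0
    return int(np.sum(nz[1:] != nz[:-1]))


def hjorth_mobility(x: np.ndarray) -> float:
    """sqrt(var(dx) / var(x)) with dx the first difference; 0 if var(x)=0."""
    x = np.asarray(x, dtype=float)
    v = np.var(x)
    if v == 0.0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def time_domain_features(x: np.ndarray) -> tuple[dict[str, float], bool]:
    """The 10 time-domain features; returns (values, degenerate_flag).

    Degenerate (zero-variance) inputs give 0 for skewness, kurtosis, Hjorth
    mobility and complexity, flagged rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    v = float(np.var(x))
    degenerate = v == 0.0
    feats = {
        "mean": float(np.mean(x)),
        "vari": v,
        "std": float(np.sqrt(v)),
        "ptp-amp": float(np.max(x) - np.min(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "zc": float(zero_crossings(x)),
    }
    if degenerate:
        feats.update({"skewness": 0.0, "kurtosis": 0.0, "hm": 0.0, "hc": 0.0})
    else:
        hm = hjorth_mobility(x)
        hm_d = hjorth_mobility(np.diff(x))
        feats.update(
            {
                "skewness": float(stats.skew(x)),
                "kurtosis": float(stats.kurtosis(x)),  # excess kurtosis
                "hm": hm,
                "hc": float(hm_d / hm) if hm > 0 else 0.0,
            }
        )
    ordered = {name: feats[name] for name in TIME_DOMAIN_NAMES}
    return ordered, degenerate


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def entropy_features(
    x: np.ndarray, m: int = 2, r: float | None = None
) -> tuple[float, float, bool]:
    """Sample entropy and approximate entropy of one epoch channel.

    SampEn = -ln(A/B) with A, B the counts of (m+1)- and m-length template
    pairs within Chebyshev distance r, self-matches excluded. ApEn is the
    standard Phi_m - Phi_{m+1} with self-matches included. ``r`` defaults to
    0.2 x std(x). Returns (sampen, apen, capped_flag); when no matches exist
    SampEn is capped at the maximum resolvable value ln(B_pairs) instead of
    raising.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    sd = np.std(x)
    if r is None:
        r = 0.2 * sd
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    if sd == 0.0:
        # constant signal: every template matches
        return 0.0, 0.0, False

    capped = False

    # --- sample entropy: N-m templates for both lengths, no self-matches
    t_m = _embed(x, m)[: n - m]
    t_m1 = _embed(x, m + 1)
    d_m = cdist(t_m, t_m, metric="chebyshev")
    d_m1 = cdist(t_m1, t_m1, metric="chebyshev")
    iu = np.triu_indices(n - m, k=1)
    b = int(np.sum(d_m[iu] <= r))
    a = int(np.sum(d_m1[iu] <= r))
    if b == 0 or a == 0:
        max_pairs = (n - m) * (n - m - 1) / 2
        sampen = float(np.log(max_pairs)) if max_pairs > 0 else 0.0
        capped = True
    else:
        sampen = float(-np.log(a / b))

    # --- approximate entropy: self-matches included
    def _phi(mm: int) -> float:
        t = _embed(x, mm)
        d = cdist(t, t, metric="chebyshev")
        c = np.mean(d <= r, axis=1)  # includes self-match, so c > 0
        return float(np.mean(np.log(c)))

    apen = _phi(m) - _phi(m + 1)
    return sampen, float(apen), capped


def feature_columns(channel_names: list[str]) -> list[str]:
    """The documented column order: per channel, bands then time-domain then
    entropies, channels in montage order; names are ``<channel>-<feature>``."""
    return [f"{ch}-{feat}" for ch in channel_names for feat in FEATURE_NAMES]


def psd_columns(channel_names: list[str]) -> list[str]:
    return [f"{ch}-{b}" for ch in channel_names for b in BAND_NAMES]


def calculative_columns(channel_names: list[str]) -> list[str]:
    """All non-PSD features (time-domain + entropy), the 'calculative' pool."""
    return [
        f"{ch}-{feat}"
        for ch in channel_names
        for feat in TIME_DOMAIN_NAMES + ENTROPY_NAMES
    ]


def extract_feature_table(
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    m: int = 2,
    r_factor: float = 0.2,
    taper: str | None = None,
) -> pd.DataFrame:
    """Compute the full feature table: one row per pass-quality epoch,
    ``18 x n_channels`` feature columns plus ``phase`` and ``start_s``.

    Degenerate-channel flags are recorded in ``df.attrs["degenerate_epochs"]``.
    """
    good = [e for e in epochs.epochs if e.quality == "pass"]
    if not good:
        raise ValueError("no pass-quality epochs")
    cols = feature_columns(epochs.channel_names)
    rows = []
    degenerate_log: list[tuple[int, str, str]] = []
    for idx, ep in enumerate(good):
        row: dict[str, float] = {}
        for ci, ch in enumerate(epochs.channel_names):
            sig = ep.samples[ci]
            spec = fft_spectrum(sig, epochs.fs, taper=taper)
            row.update({f"{ch}-{k}": v for k, v in band_powers(spec, bands).items()})
            td, deg_td = time_domain_features(sig)
            row.update({f"{ch}-{k}": v for k, v in td.items()})
            se, ae, capped = entropy_features(sig, m=m, r=r_factor * np.std(sig))
            row[f"{ch}-se"] = se
            row[f"{ch}-ae"] = ae
            if deg_td:
                degenerate_log.append((idx, ch, "zero-variance"))
            if capped:
                degenerate_log.append((idx, ch, "sampen-capped"))
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df["phase"] = [e.phase for e in good]
    df["start_s"] = [e.start_s for e in good]
    df.attrs["degenerate_epochs"] = degenerate_log
    df.attrs["bands"] = [(b.name, b.low_hz, b.high_hz) for b in bands]
    df.attrs["entropy"] = {"m": m, "r_factor": r_factor}
    df.attrs["taper"] = taper
    return df
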