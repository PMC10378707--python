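"""File formats: EDF and CSV for recordings, CSV for annotations, TLX
records, epochs and feature tables.

EDF writing is a minimal standard 16-bit EDF encoder (1-s data records,
per-channel physical scaling); reading goes through MNE's EDF reader, which
also serves as an independent round-trip check on the writer. The CSV
dialects are long-format and documented in each function.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Annotation, Recording
from .labeling import SUBSCALES, TLXRecord
from .preprocess import Epoch, EpochSet

# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as standard 16-bit EDF with 1-second data records.

    The signal is zero-padded to a whole number of records. Physical range is
    symmetric around zero per channel; digital range is the full int16 span.
    Annotations are not embedded (plain EDF); use
    :func:`write_annotations_csv` alongside.
    """
    path = Path(path)
    fs = recording.fs
    spr = round(fs)  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = recording.n_channels
    n_records = int(np.ceil(recording.n_times / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, : recording.n_times] = recording.samples

    phys_max = np.maximum(np.max(np.abs(padded), axis=1), 1e-3)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate X X X X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + ns)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)

    def field(vals, width):
        return b"".join(_pad(str(v), width) for v in vals)

    header += field(recording.channel_names, 16)
    header += field([""] * ns, 80)
    header += field(["uV"] * ns, 8)
    header += field([f"{v:.6g}" for v in phys_min], 8)
    header += field([f"{v:.6g}" for v in phys_max], 8)
    header += field([dig_min] * ns, 8)
    header += field([dig_max] * ns, 8)
    header += field([""] * ns, 80)
    header += field([spr] * ns, 8)
    header += field([""] * ns, 32)

    # digital conversion per channel
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            seg = digital[:, r * spr : (r + 1) * spr]
            fh.write(seg.tobytes())  # channel-sequential within each record
    return path


def read_recording_edf(path: str | Path,
                       annotations: list[Annotation] | None = None) -> Recording:
    """Read an EDF file via MNE; returns samples in μV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        samples=raw.get_data() * 1e6,  # MNE loads volts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=annotations or [],
    )


# ---------------------------------------------------------------------------
# CSV: recording + annotations


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Long format: ``time_s, channel, value_uV``."""
    path = Path(path)
    n = recording.n_times
    t = np.arange(n) / recording.fs
    frames = [
        pd.DataFrame({"time_s": t, "channel": ch, "value_uV": recording.samples[i]})
        for i, ch in enumerate(recording.channel_names)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_recording_csv(path: str | Path, fs: float,
                       annotations: list[Annotation] | None = None) -> Recording:
    df = pd.read_csv(path)
    channels = list(dict.fromkeys(df["channel"]))
    mats = [df.loc[df["channel"] == ch, "value_uV"].to_numpy() for ch in channels]
    return Recording(samples=np.vstack(mats), fs=fs, channel_names=channels,
                     annotations=annotations or [])


def write_annotations_csv(annotations: list[Annotation], path: str | Path) -> Path:
    """``phase, start_s, end_s`` per row."""
    path = Path(path)
    pd.DataFrame(
        [{"phase": a.phase, "start_s": a.start_s, "end_s": a.end_s}
         for a in annotations]
    ).to_csv(path, index=False)
    return path


def read_annotations_csv(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [Annotation(r["phase"], float(r["start_s"]), float(r["end_s"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# CSV: TLX


def write_tlx_csv(records: list[TLXRecord], ratings_path: str | Path,
                  weights_path: str | Path) -> None:
    """Ratings long format ``participant, phase, subscale, rating``; weights
    table ``participant, subscale, weight``."""
    rating_rows, weight_rows = [], []
    for rec in records:
        for s in SUBSCALES:
            rating_rows.append({"participant": rec.participant, "phase": rec.phase,
                                "subscale": s, "rating": rec.ratings[s]})
        for s in SUBSCALES:
            weight_rows.append({"participant": rec.participant, "subscale": s,
                                "weight": rec.weights.get(s, 0.0)})
    pd.DataFrame(rating_rows).to_csv(ratings_path, index=False)
    (pd.DataFrame(weight_rows).drop_duplicates()
     .to_csv(weights_path, index=False))


def read_tlx_csv(ratings_path: str | Path, weights_path: str | Path) -> list[TLXRecord]:
    ratings = pd.read_csv(ratings_path)
    weights = pd.read_csv(weights_path)
    w_by_p = {
        pid: dict(zip(grp["subscale"], grp["weight"]))
        for pid, grp in weights.groupby("participant")
    }
    records = []
    for (pid, phase), grp in ratings.groupby(["participant", "phase"], sort=False):
        records.append(
            TLXRecord(
                participant=int(pid), phase=str(phase),
                ratings=dict(zip(grp["subscale"], grp["rating"])),
                weights=w_by_p[pid],
            )
        )
    return records


# ---------------------------------------------------------------------------
# epochs and feature tables


def write_epochs(epoch_set: EpochSet, out_dir: str | Path) -> Path:
    """One CSV per epoch (columns = channels) plus a manifest
    ``epoch_id, phase, start_s, quality``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, ep in enumerate(epoch_set.epochs):
        name = f"epoch_{i:05d}.csv"
        pd.DataFrame(ep.samples.T, columns=epoch_set.channel_names).to_csv(
            out_dir / name, index=False
        )
        manifest.append({"epoch_id": i, "phase": ep.phase,
                         "start_s": ep.start_s, "quality": ep.quality})
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"fs": epoch_set.fs, "channels": epoch_set.channel_names,
                   **epoch_set.provenance}, fh, indent=2)
    return out_dir


def read_epochs(in_dir: str | Path) -> EpochSet:
    in_dir = Path(in_dir)
    with open(in_dir / "provenance.json") as fh:
        prov = json.load(fh)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    epochs = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(in_dir / f"epoch_{int(row['epoch_id']):05d}.csv")
        epochs.append(Epoch(samples=df.to_numpy().T, start_s=float(row["start_s"]),
                            phase=str(row["phase"]), quality=str(row["quality"])))
    channels = prov.pop("channels")
    fs = prov.pop("fs")
    return EpochSet(epochs=epochs, fs=fs, channel_names=channels, provenance=prov)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Feature CSV with a sidecar ``<path>.meta.json`` holding band edges and
    entropy settings."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {k: df.attrs.get(k) for k in ("bands", "entropy", "taper")}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            df.attrs.update(json.load(fh))
    return df
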