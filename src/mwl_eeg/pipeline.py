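"""End-to-end orchestration: simulate → preprocess → features → label →
select → train, as a configured, logged, reproducible run.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so one integer reproduces a whole
run; every output file is listed in the manifest with a SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .core import PHASES
from .features import (
    calculative_columns,
    extract_feature_table,
    feature_columns,
    psd_columns,
)
from .labeling import assign_labels, test_phase_differences
from .modeling import ClassifierSpec, crossvalidate, make_estimator
from .preprocess import drop_bad_channels, lowpass_filter, reject_epochs, segment_epochs
from .selection import kw_screen, sffs, zscore
from .simulate import SimConfig, TLXConfig, generate_recording, generate_tlx

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "label", "select", "train")


@dataclass
class RunConfig:
    """All pipeline parameters; serializable to/from a single YAML file.

    Unknown keys in a config file are rejected by :meth:`from_yaml`.
    """

    seed: int = 0
    n_participants: int = 10
    phase_duration_s: float = 60.0
    lowpass_hz: float = 40.0
    window_s: float = 2.0
    overlap: float = 0.5
    ptp_uV: float = 150.0
    flat_var_uV2: float = 0.01
    clip_uV: float = 500.0
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    taper: str | None = None
    selection_method: str = "none"  # "none", "kw", or "sffs"
    selection_alpha: float = 0.01
    selection_pool: str = "psd"  # "psd", "calculative", or "all"
    sffs_max_d: int = 10
    classifier: str = "KNN"
    folds: int = 10
    paper_mode: bool = False  # global z-scoring instead of per-fold
    bnn_epochs: int = 500

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of 'error: ...' / 'warning: ...' strings; empty = ok."""
    problems: list[str] = []
    if config.n_participants < 2:
        problems.append("error: n_participants must be >= 2 (phase statistics "
                        "need at least two survey records per phase)")
    if not 0 <= config.overlap < 1:
        problems.append("error: overlap must be in [0, 1)")
    if config.window_s <= 0:
        problems.append("error: window_s must be positive")
    if config.phase_duration_s < config.window_s:
        problems.append("error: phase_duration_s shorter than window_s")
    if config.lowpass_hz >= 64.0:
        problems.append("error: lowpass_hz must be below Nyquist (64 Hz at 128 Hz)")
    if config.ptp_uV <= 0:
        problems.append("error: ptp_uV must be positive")
    if config.selection_method not in ("none", "kw", "sffs"):
        problems.append("error: selection_method must be none/kw/sffs")
    if config.selection_pool not in ("psd", "calculative", "all"):
        problems.append("error: selection_pool must be psd/calculative/all")
    if config.classifier not in ("SVM-L", "SVM-R", "SVM-P", "KNN", "RF", "BNN"):
        problems.append(f"error: unknown classifier {config.classifier!r}")
    if config.folds < 2:
        problems.append("error: folds must be >= 2")
    from .features import DEFAULT_BANDS

    top_band = max(b.high_hz for b in DEFAULT_BANDS)
    if top_band > config.lowpass_hz:
        problems.append(
            f"warning: highest band edge {top_band} Hz above low-pass cut "
            f"{config.lowpass_hz} Hz"
        )
    return problems


@dataclass
class RunManifest:
    """What a run produced: config identity, per-stage counts, seeds, files."""

    config_hash: str
    version: str
    seeds: dict[str, int]
    counts: dict[str, object] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamps: dict[str, float] = field(default_factory=dict)
    results: dict[str, object] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return path

    def comparable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("timestamps")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single seed out to one sub-seed per stage (each < 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 write_recordings: bool = False) -> RunManifest:
    """Execute all stages; write stage outputs and a manifest under
    ``out_dir``. Reruns with the same config + seed reproduce all CSV/JSON
    outputs bit-identically."""
    errors = [p for p in validate_config(config) if p.startswith("error")]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    from importlib.metadata import version as pkg_version

    try:
        version = pkg_version("mwl-eeg")
    except Exception:
        version = "unknown"
    manifest = RunManifest(config_hash=config.content_hash(), version=version,
                           seeds=seeds)
    manifest.timestamps["start"] = time.time()
    config.to_yaml(out_dir / "config.yaml")

    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------------
        durations = {p: config.phase_duration_s for p in PHASES}
        tables = []
        epochs_per_phase: dict[str, int] = {}
        n_pass_total = 0
        for pid in range(config.n_participants):
            sim_cfg = SimConfig(phase_durations=durations,
                                seed=seeds["simulate"] + pid)
            rec = generate_recording(sim_cfg)
            if write_recordings:
                rec_dir = out_dir / "recordings"
                rec_dir.mkdir(exist_ok=True)
                mio.write_recording_edf(rec, rec_dir / f"p{pid:02d}.edf")
                mio.write_annotations_csv(rec.annotations,
                                          rec_dir / f"p{pid:02d}_annotations.csv")

            # --- preprocess ------------------------------------------------
            stage = "preprocess"
            rec = drop_bad_channels(rec, config.flat_var_uV2, config.clip_uV)
            rec = lowpass_filter(rec, config.lowpass_hz)
            eps = segment_epochs(rec, config.window_s, config.overlap)
            if pid == 0:
                epochs_per_phase = {
                    ph: sum(1 for e in eps.epochs if e.phase == ph)
                    for ph in PHASES
                }
            eps = reject_epochs(eps, config.ptp_uV)
            n_pass_total += eps.n_pass

            # --- features --------------------------------------------------
            stage = "features"
            table = extract_feature_table(
                eps, m=config.entropy_m, r_factor=config.entropy_r_factor,
                taper=config.taper,
            )
            table["participant"] = pid
            tables.append(table)

        features = pd.concat(tables, ignore_index=True)
        manifest.counts["epochs_per_phase_per_participant"] = epochs_per_phase
        manifest.counts["epochs_retained"] = n_pass_total
        manifest.counts["feature_columns"] = len(
            [c for c in features.columns
             if c not in ("phase", "start_s", "participant")]
        )

        # --- label ---------------------------------------------------------
        stage = "label"
        tlx_cfg = TLXConfig(seed=seeds["label"])
        tlx = generate_tlx(tlx_cfg, config.n_participants)
        mio.write_tlx_csv(tlx, out_dir / "tlx_ratings.csv", out_dir / "tlx_weights.csv")
        labeling = test_phase_differences(tlx)
        features = assign_labels(labeling, features)
        manifest.results["phase_to_level"] = labeling.phase_to_level
        manifest.results["anova_p"] = labeling.anova_p
        manifest.results["corrected_alpha"] = labeling.corrected_alpha

        # --- select --------------------------------------------------------
        stage = "select"
        from .core import DEFAULT_CHANNELS

        chans = [ch for ch in DEFAULT_CHANNELS
                 if any(col.startswith(ch + "-") for col in features.columns)]
        pool = {
            "psd": psd_columns(chans),
            "calculative": calculative_columns(chans),
            "all": feature_columns(chans),
        }[config.selection_pool]
        selected = pool
        if config.selection_method == "kw":
            screened = kw_screen(zscore(features, columns=pool), features["mwl"],
                                 columns=pool)
            selected = screened.selected(config.selection_alpha)
            screened.table.to_csv(out_dir / "kw_screen.csv", index=False)
        elif config.selection_method == "sffs":
            est = make_estimator(ClassifierSpec(kind="KNN", k=1,
                                                seed=seeds["select"]))
            trace = sffs(zscore(features, columns=pool), features["mwl"], est,
                         columns=pool, cv_folds=config.folds,
                         max_d=min(config.sffs_max_d, len(pool)),
                         seed=seeds["select"])
            selected = list(trace.best[0])
            trace.accuracy_curve().to_csv(out_dir / "sffs_curve.csv", index=False)
        if not selected:
            raise RuntimeError("selection produced an empty feature set")
        manifest.counts["selected_columns"] = len(selected)
        mio.write_feature_table(
            features[selected + ["phase", "start_s", "participant", "mwl"]],
            out_dir / "features.csv",
        )

        # --- train ---------------------------------------------------------
        stage = "train"
        spec = ClassifierSpec(kind=config.classifier, seed=seeds["train"])
        if config.classifier == "BNN":
            spec.bnn.epochs = config.bnn_epochs
        report = crossvalidate(
            spec, features, columns=selected, folds=config.folds,
            standardize="global" if config.paper_mode else "fold",
        )
        summary = {m: {"mean": mu, "std": sd}
                   for m, (mu, sd) in report.summary().items()}
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump({"classifier": config.classifier, "folds": config.folds,
                       "metrics": summary}, fh, indent=2)
        manifest.results["metrics"] = summary
    except Exception as exc:
        manifest.results["failed_stage"] = stage
        manifest.results["error"] = str(exc)
        manifest.timestamps["end"] = time.time()
        manifest.to_json(out_dir / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for f in sorted(out_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.files[str(f.relative_to(out_dir))] = _sha256(f)
    manifest.timestamps["end"] = time.time()
    manifest.to_json(out_dir / "manifest.json")
    return manifest
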