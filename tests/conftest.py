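import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from mwl_eeg import (
    PHASES,
    Annotation,
    Recording,
    SimConfig,
    TLXConfig,
    assign_labels,
    extract_feature_table,
    generate_recording,
    generate_tlx,
    lowpass_filter,
    reject_epochs,
    segment_epochs,
    test_phase_differences,
)


@pytest.fixture(scope="session")
def short_recording() -> Recording:
    """A 3 x 12 s default-parameter synthetic recording."""
    cfg = SimConfig(phase_durations={p: 12.0 for p in PHASES}, seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def labeled_features() -> pd.DataFrame:
    """Feature table from two short synthetic participants, with workload
    labels attached from a synthetic TLX survey."""
    tables = []
    for pid in range(2):
        cfg = SimConfig(phase_durations={p: 30.0 for p in PHASES}, seed=211 + pid)
        rec = lowpass_filter(generate_recording(cfg))
        eps = reject_epochs(segment_epochs(rec))
        tables.append(extract_feature_table(eps))
    ft = pd.concat(tables, ignore_index=True)
    labeling = test_phase_differences(generate_tlx(TLXConfig(seed=5), 21))
    return assign_labels(labeling, ft)


@pytest.fixture()
def flat_recording() -> Recording:
    """All-zero 5-channel recording with one 10 s phase, for edge cases."""
    fs = 128.0
    return Recording(
        samples=np.zeros((5, int(10 * fs))),
        fs=fs,
        channel_names=["AF3", "AF4", "T7", "T8", "Pz"],
        annotations=[Annotation("cruise", 0.0, 10.0)],
    )


def single_phase_recording(samples: np.ndarray, fs: float = 128.0,
                           phase: str = "cruise") -> Recording:
    chans = [f"ch{i}" for i in range(samples.shape[0])]
    dur = samples.shape[1] / fs
    return Recording(samples=samples, fs=fs, channel_names=chans,
                     annotations=[Annotation(phase, 0.0, dur)])
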