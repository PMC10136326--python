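import numpy as np
import pytest

from wearseiz.io import (ROLE_ECG, ROLE_EEG_CROSS, ROLE_EEG_IPSI, Channel,
                         Recording)
from wearseiz.segmentation import label_windows
from wearseiz.synthetic import default_config, gen_recording, make_cohort


@pytest.fixture(scope="session")
def short_recording():
    """One 600 s synthetic recording with two seizures (cheap, shared)."""
    cfg = default_config(seed=42, duration_s=600.0)
    rec, truth = gen_recording(cfg)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def sine_recording():
    """Deterministic 60 s recording with pure sinusoid channels."""
    fs = 250.0
    t = np.arange(0, 60, 1 / fs)
    rec = Recording("sine", [
        Channel("EEG CrossHead", ROLE_EEG_CROSS,
                100.0 * np.sin(2 * np.pi * 10 * t), fs),
        Channel("EEG Ipsi", ROLE_EEG_IPSI,
                50.0 * np.sin(2 * np.pi * 6 * t), fs),
        Channel("ECG", ROLE_ECG, 0.5 * np.sin(2 * np.pi * t), fs),
    ])
    return rec


@pytest.fixture(scope="session")
def eeg_cohort_features():
    """Features + window labels of the default 10-recording cohort.

    Session-scoped: this is the expensive input shared by the end-to-end
    EEG detector tests and the acceptance suite."""
    from wearseiz.eeg import EEGSeizureDetector

    cohort = make_cohort(10, base_seed=0)
    det = EEGSeizureDetector()
    packed = []
    for m in cohort:
        grid, X = det._grid_and_features(m.recording)
        y = label_windows(grid, m.ground_truth)
        packed.append((grid, X, y))
    return cohort, packed
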