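import numpy as np
import pytest

from iscpipe import SyntheticConfig, generate_timeseries


@pytest.fixture(scope="session")
def small_dataset():
    """20 subjects, 2 ROIs, 4 short runs, moderate shared signal."""
    cfg = SyntheticConfig(
        n_subjects=20,
        run_lengths=(60, 60, 60, 60),
        run_names=("video1", "video2", "video3", "control"),
        n_rois=2,
        base_shared_fraction=0.25,
        seed=42,
    )
    ts, truth = generate_timeseries(cfg)
    return cfg, ts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
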