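import numpy as np
import pytest

from gaitnirs.cli_io import PipelineConfig
from gaitnirs.study_model import SubjectMeta, TaskDesign, build_default_montage
from gaitnirs.synthetic_fnirs import (
    GroundTruth,
    NoiseModel,
    simulate_subject_recording,
)


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture
def meta_right_impaired():
    return SubjectMeta(
        subject_id="s1", cohort="PwMS", treatment="RAGT", timepoints=("T0",),
        edss=6.5, impaired_side="right", age=55.0, sex="F",
        t25fw_speed={"T0": 0.5}, six_mwd={"T0": 120.0}, bbs={"T0": 33},
    )


@pytest.fixture(scope="session")
def random_amplitudes(montage):
    rng = np.random.default_rng(42)
    return rng.uniform(0.5, 3.0, montage.n_channels)


@pytest.fixture(scope="session")
def clean_recording(montage, design, random_amplitudes):
    """Noise-free recording with known per-channel amplitudes."""
    truth = GroundTruth.from_hbo(random_amplitudes, seed=7)
    rec = simulate_subject_recording(
        montage, design, truth, NoiseModel.silent(), seed=7
    )
    return rec, truth


@pytest.fixture
def bypass_config():
    return PipelineConfig(bypass_filter=True)
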