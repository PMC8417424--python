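import logging

import numpy as np
import pytest
from hypothesis import settings

import gaitval as gv

logging.getLogger("gaitval").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_model() -> gv.GaitModel:
    """A trial with zero tracker noise: both renderings equal the truth."""
    return gv.GaitModel(
        seed=3, noise_dlc_px=0.0, noise_ref_cm=0.0,
        ref_offset_cm=0.0, dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def default_model() -> gv.GaitModel:
    return gv.GaitModel(seed=11)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_model):
    """(track, events, truth_variables) for the noiseless trial."""
    return gv.simulate_gait(noiseless_model)


@pytest.fixture()
def fixture_dir(tmp_path, noiseless_model):
    """A complete on-disk fixture for the noiseless trial."""
    return gv.write_fixture(noiseless_model, tmp_path / "fixture")


def make_track(xy, markers=("a", "b"), frame_rate=60.0, likelihood=None,
               units="cm", orientation="kinematic"):
    return gv.PoseTrack(frame_rate, tuple(markers), np.asarray(xy, float),
                        likelihood, units=units, orientation=orientation)
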