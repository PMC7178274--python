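import numpy as np
import pytest

from rsataper.geometry import (
    CalibrationBoxModel,
    SceneGeometry,
    calibrate_view,
    project_points,
)
from rsataper.phantom import PhantomConfig, generate_study
from rsataper.pipeline import series_from_study


@pytest.fixture(scope="session")
def scene():
    return SceneGeometry.default()


@pytest.fixture(scope="session")
def box():
    return CalibrationBoxModel.default_grid()


@pytest.fixture(scope="session")
def cal_pair(scene, box):
    """Noiseless calibrations of both views of the default scene."""
    cals = []
    for view in (1, 2):
        fid = box.fiducial_markers[:, :2]
        ctl = project_points(scene, view, box.control_markers)
        cals.append(calibrate_view(box, fid, ctl))
    return cals


@pytest.fixture
def rng():
    return np.random.default_rng(20231543)


def make_series(config: PhantomConfig):
    """Generate a study and return (study, series list)."""
    study = generate_study(config)
    return study, series_from_study(study)


@pytest.fixture
def noiseless_single_patient():
    cfg = PhantomConfig(n_patients=1, schedule_months=(0.0, 6.0, 24.0), seed=4)
    return make_series(cfg)
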