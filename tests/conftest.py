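import numpy as np
import pytest

from rovnet.grid import GridGeometry
from rovnet.synthetic import BehaviorCoupling, CouplingSpec, ROVSpec, SimConfig
from rovnet.variance import SubjectContrast


@pytest.fixture
def geom() -> GridGeometry:
    return GridGeometry.isotropic((8, 8, 8), 3.0)


@pytest.fixture
def small_config() -> SimConfig:
    """A desk-scale cohort config for fast end-to-end tests."""
    return SimConfig(
        n_subjects=12,
        grid_dims=(12, 12, 12),
        rov_specs=[
            ROVSpec("A", (-9.0, 0.0, 0.0)),
            ROVSpec("B", (9.0, 0.0, 0.0)),
            ROVSpec("C", (0.0, 9.0, 0.0)),
        ],
        high_variance_regions={"A": 6.0},
        coupling=CouplingSpec(targets=np.array([[0, 0.5, 0.3], [0.5, 0, 0.3], [0.3, 0.3, 0]]), edge_sd=0.1),
        behavior_coupling=BehaviorCoupling(edges=((0, 1),)),
        n_trials_task=24,
        n_timepoints_rest=60,
        n_runs_rest=1,
        n_scans=50,
        seed=7,
    )


def make_contrast(con, resms, n_scans, geometry) -> SubjectContrast:
    return SubjectContrast(
        con=np.asarray(con, dtype=float),
        resms=np.asarray(resms, dtype=float),
        n_scans=n_scans,
        geometry=geometry,
    )


@pytest.fixture
def two_subject_cohort(geom):
    """The hand-computable fixture: con = {1, 3}, ResMS = {9, 9}, NScan = 10."""
    shape = geom.shape
    return [
        make_contrast(np.full(shape, 1.0), np.full(shape, 9.0), 10, geom),
        make_contrast(np.full(shape, 3.0), np.full(shape, 9.0), 10, geom),
    ]
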