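import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import contourclass as cc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> cc.PhantomSpec:
    return cc.PhantomSpec()


@pytest.fixture(scope="session")
def rigid_spec() -> cc.PhantomSpec:
    """Phantom spec with every jitter source disabled (pure templates)."""
    return cc.PhantomSpec(
        xy_jitter=0.0,
        z_jitter=0,
        scale_jitter=0.0,
        head_scale_jitter=0.0,
        head_xy_shift=0.0,
        head_z_shift=0,
        slice_xy_jitter=0.0,
        slice_scale_jitter=0.0,
        drift_amp=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(default_spec) -> cc.PhantomCohort:
    """Five jittered phantom patients shared across read-only tests."""
    return cc.generate_cohort(default_spec, 5, seed=11)


@pytest.fixture(scope="session")
def rigid_patient(rigid_spec):
    sset, truth = cc.generate_patient(
        rigid_spec, np.random.default_rng(0), patient_id="RIGID"
    )
    return sset, truth


@pytest.fixture()
def square_set() -> cc.StructureSet:
    """A hand-built two-structure set on a 32x32 grid."""
    sq = cc.ContourPolygon(
        np.array([[10.5, 10.5], [20.5, 10.5], [20.5, 20.5], [10.5, 20.5]])
    )
    tri = cc.ContourPolygon(np.array([[2.0, 2.0], [8.0, 2.0], [2.0, 8.0]]))
    return cc.StructureSet(
        patient_id="SQ",
        grid=(32, 32),
        slice_thickness=2.5,
        n_slices=10,
        structures=[
            cc.Structure("Brain", {3: [sq], 4: [sq], 5: [sq]}),
            cc.Structure("odd name", {4: [tri]}),
        ],
    ).validate()
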