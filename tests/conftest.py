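import numpy as np
import pytest

from cardiostrain.geometry import (
    LVGeometryConfig,
    assign_aha_segments,
    build_reference_mesh,
    compute_local_frames,
)
from cardiostrain.phantom import ClassPhenotype, simulate_subject
from cardiostrain.strain import strain_time_series


@pytest.fixture(scope="session")
def geo_config():
    return LVGeometryConfig()


@pytest.fixture(scope="session")
def ref_mesh(geo_config):
    return build_reference_mesh(geo_config)


@pytest.fixture(scope="session")
def frames(ref_mesh):
    return compute_local_frames(ref_mesh)


@pytest.fixture(scope="session")
def seg_map(ref_mesh):
    return assign_aha_segments(ref_mesh)


@pytest.fixture(scope="session")
def quiet_hcm_subject(geo_config):
    """Zero-noise subject at HCM-calibrated amplitudes (incompressible)."""
    ph = ClassPhenotype(
        label="HCM",
        amp_subendo_circ=-0.178,
        amp_subendo_long=-0.152,
        t_peak_frac=0.414,
        thickness_base=10.0,
    )
    return simulate_subject(ph, geo_config, np.random.default_rng(1))


@pytest.fixture(scope="session")
def quiet_series(quiet_hcm_subject, frames):
    return strain_time_series(quiet_hcm_subject.mesh, frames)
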