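"""Shared fixtures: full-scale reference scans (session-scoped, reused by the
estimation and acceptance tests) and a reduced phantom for fast unit tests.

The reduced phantom keeps the five-key-marker structure at a 60 mm lever on
a 160 mm field of view; its voxels are 1.25 mm isotropic, so the worst-case
marker peak sits lower than at full scale and tests pass an explicit
1200 HU threshold.
"""

import pytest

from crossjig import (
    EstimationConfig,
    JigGeometry,
    MisalignmentState,
    ScanParams,
    default_jig,
    simulate_scan,
)

MINI_THRESHOLD = 1200.0


def make_mini_jig() -> JigGeometry:
    return JigGeometry(
        arm_half_length=60.0,
        marker_diameter=1.5,
        longitudinal_marker_offsets=(-60.0, 0.0, 60.0),
        transverse_marker_offsets=(-60.0, 60.0),
    )


def make_mini_params(**overrides) -> ScanParams:
    defaults = dict(fov=160.0, matrix=128)
    defaults.update(overrides)
    return ScanParams(**defaults)


def mini_config(**overrides) -> EstimationConfig:
    defaults = dict(threshold_hu=MINI_THRESHOLD)
    defaults.update(overrides)
    return EstimationConfig(**defaults)


@pytest.fixture(scope="session")
def mini_jig():
    return make_mini_jig()


@pytest.fixture(scope="session")
def jig():
    return default_jig()


@pytest.fixture(scope="session")
def zero_scan(jig):
    """Noiseless full-scale scan with every misalignment angle zero."""
    return simulate_scan(jig, MisalignmentState("table", A=0.0, B=0.0))


@pytest.fixture(scope="session")
def scan_couch_plus2(jig):
    """Noiseless table-mode scan: couch direction +2° clockwise, tabletop true."""
    return simulate_scan(jig, MisalignmentState("table", A=2.0, B=0.0))


@pytest.fixture(scope="session")
def scan_couch_minus2(jig):
    """Sign-mirror of :func:`scan_couch_plus2`."""
    return simulate_scan(jig, MisalignmentState("table", A=-2.0, B=0.0))


@pytest.fixture(scope="session")
def scan_laser_mixed(jig):
    """Noiseless laser-mode scan: lasers −2° (counterclockwise), couch +2°."""
    return simulate_scan(jig, MisalignmentState("laser", A=2.0, C=-2.0))
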