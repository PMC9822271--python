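import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fdclass.curve_io import SEGMENT_RETRACT, CurveMetadata, FDCurve


def make_curve(force, z=None, segment=SEGMENT_RETRACT, **meta):
    """Build a retract-only curve from a force array (z defaults to -10..290)."""
    force = np.asarray(force, dtype=float)
    if z is None:
        z = np.linspace(-10.0, 290.0, force.size)
    return FDCurve(
        segment=np.full(force.shape, segment, dtype=object),
        z=np.asarray(z, dtype=float),
        force=force,
        metadata=CurveMetadata(**meta),
    )


@pytest.fixture
def flat_curve():
    return make_curve(np.zeros(1024))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
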