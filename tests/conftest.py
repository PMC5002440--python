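import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairedval.probe_io import ProbeGeometry, make_probe_32ch_poly3

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def poly3():
    return make_probe_32ch_poly3()


@pytest.fixture(scope="session")
def mini_probe():
    """Small 8-site grid (2 columns x 4 rows, 25 um pitch) for exhaustive
    oracle tests."""
    xz = np.array([(25.0 * c, 25.0 * r) for r in range(4) for c in range(2)])
    return ProbeGeometry(
        site_ids=np.arange(8),
        site_xz_um=xz,
        site_area_um2=100.0,
        adjacency_radius_um=30.0,
        name="mini-8ch",
    )
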