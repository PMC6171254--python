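import numpy as np
import pytest

from twascore import SacMask, SurfaceMesh, WallFieldSeries
from twascore.synthetic import SyntheticCaseConfig, make_case

TRIANGLE = SurfaceMesh(
    vertices=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
    faces=np.array([[0, 1, 2]]),
)


def single_face_series(vectors, times=None, period=None, pressure=None):
    """A WallFieldSeries on one triangle from a (T, 3) vector list."""
    vecs = np.asarray(vectors, dtype=float)[:, None, :]
    if times is None:
        times = np.linspace(0.0, 1.0, vecs.shape[0])
    return WallFieldSeries(
        mesh=TRIANGLE,
        times=np.asarray(times, dtype=float),
        wss_vectors=vecs,
        pressure=pressure,
        period=period,
    )


def full_reversal_series(n_times=32, magnitude=1.0):
    """Two equal half-cycles with exactly opposite direction: OSI = 1/2."""
    v = np.array([magnitude, 0.0, 0.0])
    vectors = [v if k < n_times // 2 else -v for k in range(n_times)]
    times = np.arange(n_times) / n_times
    return single_face_series(vectors, times=times, period=1.0)


@pytest.fixture(scope="session")
def default_case():
    return make_case(SyntheticCaseConfig(seed=0))


@pytest.fixture(scope="session")
def small_case():
    """Coarse, quick case for I/O and CLI round trips."""
    return make_case(
        SyntheticCaseConfig(seed=7, mesh_subdivisions=1, n_times=8, image_size=64)
    )


@pytest.fixture
def sac_all():
    return SacMask(np.ones(1, dtype=bool))
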