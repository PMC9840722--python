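import numpy as np
import pytest

from pcctherm import (
    BaseMaterialSet,
    PhantomGeometry,
    default_base_set,
    make_test_materials,
)


@pytest.fixture(scope="session")
def geometry() -> PhantomGeometry:
    """Reference distances with the phantom size that fits the detector."""
    return PhantomGeometry.self_consistent()


@pytest.fixture(scope="session")
def small_geometry() -> PhantomGeometry:
    """Few detector rows: keeps full-chain tests fast."""
    return PhantomGeometry.self_consistent(detector_shape=(12, 1280))


@pytest.fixture(scope="session")
def bases() -> BaseMaterialSet:
    return default_base_set()


@pytest.fixture(scope="session")
def test_materials(bases):
    return make_test_materials(seed=0)


def ray_march_chords(geometry, step_mm=0.01):
    """Brute-force chord lengths: midpoint sampling along each pixel's ray.

    Independent of the analytic slab intersection; used as the oracle for
    the projection simulator.
    """
    h = geometry.side_length_mm / 2.0
    dc = geometry.source_to_center_mm
    dd = geometry.source_to_detector_mm
    xs = geometry.detector_xs_mm
    ray_len = np.sqrt(xs**2 + dd**2)
    n_steps = int(np.ceil(ray_len.max() / step_mm))
    t = (np.arange(n_steps) + 0.5) / n_steps  # midpoint rule on [0, 1]
    py = dd * t
    y_ok = (py >= dc - h) & (py <= dc + h)
    out = np.empty_like(xs)
    for lo in range(0, xs.size, 128):  # chunked: the full grid is ~50M points
        sl = slice(lo, lo + 128)
        px = xs[sl, None] * t[None, :]
        inside = (np.abs(px) <= h) & y_ok[None, :]
        out[sl] = inside.sum(axis=1) * (ray_len[sl] / n_steps)
    return out
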