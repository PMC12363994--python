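import numpy as np
import pytest

from knotjones import (
    CurveCollection,
    distance_matrix,
    make_ideal_helix,
    make_parallel_strands,
    make_polygonal_knot,
    midpoint_segmentation,
    segment_at_midpoints,
)
from knotjones.jones import JonesSettings


@pytest.fixture(scope="session")
def helix19():
    return make_ideal_helix(19)


@pytest.fixture(scope="session")
def helix19_seg(helix19):
    seg = segment_at_midpoints(helix19)
    return seg, distance_matrix(seg, metric="representative")


@pytest.fixture(scope="session")
def strands8():
    return make_parallel_strands(8)


@pytest.fixture(scope="session")
def strands8_seg(strands8):
    seg = midpoint_segmentation(strands8)
    return seg, distance_matrix(seg, metric="representative")


@pytest.fixture(scope="session")
def trefoil():
    return make_polygonal_knot("trefoil")


@pytest.fixture(scope="session")
def fast_settings():
    """Modest quadrature for tests that only need determinism, not accuracy."""
    return JonesSettings(n_directions=20)


def random_collection(rng: np.random.Generator, max_components: int = 6) -> CurveCollection:
    """A random mix of small open and closed polylines (test helper)."""
    from knotjones import Polyline

    n_comp = int(rng.integers(1, max_components + 1))
    comps = []
    for _ in range(n_comp):
        n_v = int(rng.integers(2, 6))
        closed = bool(rng.random() < 0.4) and n_v >= 3
        v = rng.normal(scale=2.0, size=(n_v, 3))
        comps.append(Polyline(v, closed=closed))
    return CurveCollection(comps)
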