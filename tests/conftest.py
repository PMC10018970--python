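import numpy as np
import pytest

from angioquant.graph import VesselGraph
from angioquant.synthetic import NetworkSpec, generate_network, rasterize_network
from angioquant.volume import RasterVolume


@pytest.fixture
def straight_tube_graph():
    """A single straight cylinder (radius 3 µm, length 60 µm, z-aligned)."""
    g = VesselGraph()
    a = g.add_node((15.13, 15.21, 0.0))
    b = g.add_node((15.13, 15.21, 60.0))
    g.add_segment(a, b, np.array([[15.13, 15.21, 0.0], [15.13, 15.21, 60.0]]), 3.0)
    return g


@pytest.fixture(scope="session")
def fiber_phantom():
    """Small muscle-like phantom: graph, ground truth and rasterization."""
    spec = NetworkSpec(
        "parallel_fiber",
        (100.0, 100.0, 200.0),
        target_volume_fraction=0.039,
        mean_segment_length=68.5,
        mean_radius=4.1,
        seed=1,
    )
    graph, gt = generate_network(spec)
    raster = rasterize_network(graph, (0.5, 0.5, 1.0), domain=spec.domain_size)
    return spec, graph, gt, raster


@pytest.fixture(scope="session")
def arc_phantom():
    """Small brain-like phantom with curved segments."""
    spec = NetworkSpec(
        "random_arc",
        (120.0, 120.0, 120.0),
        n_segments=150,
        mean_segment_length=30.0,
        mean_radius=3.0,
        tortuosity=1.15,
        seed=7,
    )
    graph, gt = generate_network(spec)
    return spec, graph, gt


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return RasterVolume(np.asarray(data), spacing, check_shape=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
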