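import numpy as np
import pytest

from spinesong import (
    GeneratorParams,
    MedialAxis,
    SpineRecord,
    compute_frames,
    generate_axis,
    generate_spines,
    unroll_spines,
)


@pytest.fixture(scope="session")
def straight_axis():
    """100 μm straight axis along +z."""
    return generate_axis("straight", 100.0)


@pytest.fixture(scope="session")
def straight_frames(straight_axis):
    return compute_frames(straight_axis)


@pytest.fixture(scope="session")
def helix_axis():
    return generate_axis("helix", 100.0, n_vertices=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_unrolled(straight_axis, straight_frames):
    """141 uniformly distributed spines, unrolled."""
    spines = generate_spines(straight_axis, GeneratorParams(seed=7))
    return unroll_spines(spines, straight_axis, straight_frames)


@pytest.fixture(scope="session")
def helical_unrolled(straight_axis, straight_frames):
    """Perfect (jitter-free) helical pattern with a 10 μm period, unrolled."""
    params = GeneratorParams(seed=11, angle_model="helical", helix_period=10.0)
    spines = generate_spines(straight_axis, params)
    return unroll_spines(spines, straight_axis, straight_frames)


def make_spines_at(positions, radial=(1.0, 0.0), lengths=None, volumes=None):
    """Spines on a straight z-axis at given s values, offset in the xy-plane."""
    n = len(positions)
    lengths = lengths if lengths is not None else [1.0] * n
    volumes = volumes if volumes is not None else [0.3] * n
    return [
        SpineRecord(
            spine_id=f"s{i:03d}",
            insertion=(radial[0], radial[1], float(s)),
            length_um=float(lengths[i]),
            volume_um3=float(volumes[i]),
        )
        for i, s in enumerate(positions)
    ]
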