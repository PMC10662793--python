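import numpy as np
import pytest

from eagseg import PhantomSpec, generate_phantom, geometric_center


def disk(shape, center, radius):
    grids = np.indices(shape, dtype=float)
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius**2


@pytest.fixture(scope="session")
def default_phantom():
    """One fixed 2D phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(rng_seed=1))


@pytest.fixture(scope="session")
def tumor_center_seed(default_phantom):
    _, tumor, _ = default_phantom
    return tuple(int(round(c)) for c in geometric_center(tumor))
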