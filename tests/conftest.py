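import math

import numpy as np
import pytest

from oleomap.synthetic import SyntheticSliceSpec, generate_slice


def disk_mask(shape, center, radius):
    """Boolean disk: pixel centers within `radius` of `center` (x, y)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def circle_polygon(center, radius, n=720):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)], axis=1
    )


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced-size synthetic slice spec shared across tests."""
    return SyntheticSliceSpec(
        size=256,
        mean_radius=100.0,
        lambdas=(0.5, 1.0, 3.0, 4.0, 5.0, 7.0, 9.0, 11.0, 30.0),
        droplet_radius=(3.0, 5.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_slice(small_spec):
    return generate_slice(small_spec)
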