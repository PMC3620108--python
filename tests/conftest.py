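import math

import numpy as np
import pytest

from nucshell import Palette, classify_grid
from nucshell.synthetic import NucleusSpec, fixture_suite, make_nucleus_image

SEED = 0


@pytest.fixture(scope="session")
def palette():
    return Palette()


@pytest.fixture(scope="session")
def suite():
    """The canonical synthetic fixture cases, generated once per session."""
    return fixture_suite(seed=SEED)


@pytest.fixture(scope="session")
def ellipse_100_50():
    """Axis-aligned blue ellipse, center (200, 150), semi-axes 100 and 50."""
    spec = NucleusSpec(width=401, height=301, center=(200.0, 150.0), a=100, b=50, seed=SEED)
    grid, truth = make_nucleus_image(spec)
    return spec, grid, truth


@pytest.fixture(scope="session")
def rotated_30(suite):
    return suite["rotated_ellipse_30deg"]


def classgrid_of(grid, palette=None):
    return classify_grid(grid, palette or Palette())


def angle_diff_deg(t1: float, t2: float) -> float:
    """Absolute angular difference modulo 180 degrees, in degrees."""
    return math.degrees(abs((t1 - t2 + math.pi / 2) % math.pi - math.pi / 2))


def random_ellipse_specs(rng: np.random.Generator, n: int, a_range=(40, 150), aspect_range=(1, 3)):
    """Random nucleus specs spanning a size/eccentricity/orientation range."""
    specs = []
    for _ in range(n):
        a = rng.uniform(*a_range)
        b = a / rng.uniform(*aspect_range)
        theta = rng.uniform(0, math.pi)
        w = int(2 * a + 22)
        specs.append(
            NucleusSpec(
                width=w,
                height=w,
                center=(w / 2, w / 2),
                a=a,
                b=b,
                theta=theta,
                seed=int(rng.integers(2**31)),
            )
        )
    return specs
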