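import numpy as np
import pytest

from baropod import DEFAULT_CURVE, PercentVector, default_layout
from baropod.heatmap import SensorLayout
from baropod.firmware import N_SENSORS


@pytest.fixture
def curve():
    return DEFAULT_CURVE


@pytest.fixture
def layout():
    return default_layout()


def make_vector(values, t_ms=0, foot="left"):
    return PercentVector(timestamp_ms=t_ms, values=tuple(values), foot=foot)


def random_vector(rng, t_ms=0, foot="left"):
    return make_vector(rng.integers(0, 101, N_SENSORS), t_ms=t_ms, foot=foot)


def random_layout(rng):
    """A random row-convex footprint with 16 random vertical seed pairs.

    Row-convex masks whose per-row spans always intersect are 8-connected,
    so the fill wavefront can reach every cell.
    """
    width = int(rng.integers(8, 11))
    height = int(rng.integers(12, 23))
    mask = np.zeros((height, width), dtype=bool)
    for y in range(height):
        x0 = int(rng.integers(0, 3))
        x1 = width - 1 - int(rng.integers(0, 3))
        mask[y, x0 : x1 + 1] = True
    seeds = {}
    used = set()
    for sensor in range(N_SENSORS):
        while True:
            x = int(rng.integers(0, width))
            y = int(rng.integers(0, height - 1))
            pair = ((x, y), (x, y + 1))
            if mask[y, x] and mask[y + 1, x] and not (set(pair) & used):
                seeds[sensor] = pair
                used.update(pair)
                break
    return SensorLayout(width=width, height=height, seeds=seeds, footprint_mask=mask)
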