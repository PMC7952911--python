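import math
from collections import Counter

import numpy as np
import pytest

from symspike.fields import PointSet


def brute_force_density(points, domain, metric="euclidean", decimals=1,
                        distance_limit=None):
    """Independent scalar-loop oracle for the symmetry-density map.

    For every domain pixel, count binned distances to all input points with
    plain Python arithmetic and report the largest count.
    """
    width, height = domain
    out = [[0.0] * width for _ in range(height)]
    for y in range(height):
        for x in range(width):
            counts = Counter()
            for px, py in points:
                if metric == "euclidean":
                    d = math.hypot(px - x, py - y)
                else:
                    d = abs(px - x) + abs(py - y)
                if distance_limit is not None and d > distance_limit:
                    continue
                counts[math.floor(d * 10 ** decimals + 0.5)] += 1
            out[y][x] = float(max(counts.values())) if counts else 0.0
    return np.array(out)


def random_point_set(rng, width, height, n):
    """n distinct random grid points on a width x height domain."""
    cells = rng.choice(width * height, size=n, replace=False)
    return PointSet(np.column_stack([cells % width, cells // width]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
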