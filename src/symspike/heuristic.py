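"""GPU-tailored symmetry-density variants.

Two relaxations of the histogram algorithm that suit massively parallel
hardware (implemented here with sequential reference semantics):

* exact all-pairs *bisector rasterization*: every unordered pair of
  above-threshold points votes along the rasterized perpendicular bisector
  of the pair (Bresenham-style stepping with the slope inverted);
* a mutex-free *randomized midpoint* heuristic: points are scattered into a
  fixed-length array by random indexing, then pairs of slots are drawn at
  random and only each pair's rounded midpoint is incremented.  Randomizing
  both the array layout and the pair choice removes the critical sections a
  parallel implementation would otherwise need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import SymmetryDensityMap, extract_points
from .fields import PointSet, ScalarField2D, round_half_away

__all__ = [
    "BisectionRaster",
    "ThresholdPointArray",
    "bisector_raster",
    "bisection_density",
    "randomized_midpoint_density",
]


@dataclass
class BisectionRaster:
    """Rasterized perpendicular bisector of a point pair, clipped to bounds.

    Every raster point r satisfies |d(r,p1) - d(r,p2)| <= 1 in the
    Euclidean metric: the raster tracks the exact bisector line to within
    half a pixel, and the distance mismatch is at most twice the
    perpendicular offset from that line.
    """

    points: np.ndarray  # (n, 2) int, ordered along the line


def bisector_raster(p1, p2, bounds: tuple[int, int]) -> BisectionRaster:
    """Rasterize the perpendicular bisector of p1-p2 across the domain.

    The line passes through the exact midpoint with slope the negative
    reciprocal of the p1->p2 slope, stepping one pixel at a time along the
    dominant axis (8-connected), extended to the domain boundary both ways.
    """
    x1, y1 = p1
    x2, y2 = p2
    if (x1, y1) == (x2, y2):
        raise ValueError("degenerate pair: identical points")
    width, height = bounds
    dx = float(x2 - x1)
    dy = float(y2 - y1)
    mx = (x1 + x2) / 2.0
    my = (y1 + y2) / 2.0
    # Perpendicular direction (-dy, dx); step along its dominant axis and
    # place the other coordinate on the exact line, rounded to nearest.
    pts = []
    if abs(dx) >= abs(dy):
        # bisector is y-dominant: for each row y, x = mx - (y - my) * dy/dx
        for y in range(height):
            x = mx - (y - my) * dy / dx
            xi = int(round_half_away(x))
            if 0 <= xi < width:
                pts.append((xi, y))
    else:
        for x in range(width):
            y = my - (x - mx) * dx / dy
            yi = int(round_half_away(y))
            if 0 <= yi < height:
                pts.append((x, yi))
    return BisectionRaster(np.array(pts, dtype=int).reshape(len(pts), 2))


def bisection_density(fld: ScalarField2D, threshold: float,
                      bounds: tuple[int, int] | None = None,
                      distance_limit: float | None = None) -> SymmetryDensityMap:
    """Accumulate the bisector rasters of every above-threshold point pair.

    The value at a pixel is the number of unordered pairs whose bisector
    raster covers it.  ``distance_limit`` drops pairs farther apart than
    the given scale before rasterizing.
    """
    points = extract_points(fld, threshold)
    if len(points) < 2:
        raise ValueError(f"need >= 2 above-threshold points, got {len(points)}")
    if bounds is None:
        bounds = (fld.width, fld.height)
    width, height = bounds
    out = np.zeros((height, width))
    coords = points.coords
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if distance_limit is not None:
                d = float(np.hypot(*(coords[j] - coords[i])))
                if d > distance_limit:
                    continue
            raster = bisector_raster(coords[i], coords[j], bounds)
            out[raster.points[:, 1], raster.points[:, 0]] += 1
    return SymmetryDensityMap(out)


@dataclass
class ThresholdPointArray:
    """Fixed-length array of above-threshold points placed by random indexing.

    Each source point is written at K randomly chosen slots; any slot still
    empty afterwards is filled by a final sequential sweep through the point
    list, so every slot holds an above-threshold point and every point
    appears at least once when coverage allows.
    """

    entries: np.ndarray  # (M, 2) int
    seed: int

    @classmethod
    def build(cls, points: PointSet, capacity: int, k: int, seed: int) -> "ThresholdPointArray":
        if len(points) == 0:
            raise ValueError("no above-threshold points")
        if capacity < 1 or k < 1:
            raise ValueError("capacity and K must be >= 1")
        rng = np.random.default_rng(seed)
        entries = np.full((capacity, 2), -1, dtype=int)
        coords = points.coords
        for _ in range(k):
            slots = rng.integers(0, capacity, size=len(coords))
            entries[slots] = coords
        # Sequential sweep guarantees the capacity invariant.
        empty = np.nonzero(entries[:, 0] < 0)[0]
        if len(empty):
            entries[empty] = coords[np.arange(len(empty)) % len(coords)]
        return cls(entries, seed)

    def __len__(self) -> int:
        return len(self.entries)


def randomized_midpoint_density(fld: ScalarField2D, threshold: float,
                                capacity: int, k: int, n_draws: int,
                                seed: int,
                                distance_limit: float | None = None,
                                bounds: tuple[int, int] | None = None,
                                ) -> SymmetryDensityMap:
    """Monte-Carlo midpoint voting over a randomized threshold-point array.

    Performs ``n_draws`` iterations; each draws two slots of the array,
    skips identical points and pairs beyond ``distance_limit``, and
    increments the rounded midpoint (half-away-from-zero per coordinate).
    Deterministic given the seed.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    points = extract_points(fld, threshold)
    array = ThresholdPointArray.build(points, capacity, k, seed)
    if bounds is None:
        bounds = (fld.width, fld.height)
    width, height = bounds
    out = np.zeros((height, width))
    if n_draws == 0:
        return SymmetryDensityMap(out)
    rng = np.random.default_rng(seed + 1)
    i = rng.integers(0, capacity, size=n_draws)
    j = rng.integers(0, capacity, size=n_draws)
    a = array.entries[i]
    b = array.entries[j]
    keep = np.any(a != b, axis=1)
    if distance_limit is not None:
        d = np.hypot(*(b - a).T)
        keep &= d <= distance_limit
    mid = round_half_away((a[keep] + b[keep]) / 2.0).astype(int)
    inb = (mid[:, 0] >= 0) & (mid[:, 0] < width) & (mid[:, 1] >= 0) & (mid[:, 1] < height)
    mid = mid[inb]
    np.add.at(out, (mid[:, 1], mid[:, 0]), 1)
    return SymmetryDensityMap(out)


def exact_midpoint_distribution(array: ThresholdPointArray,
                                bounds: tuple[int, int],
                                distance_limit: float | None = None,
                                ) -> tuple[dict[tuple[int, int], float], float]:
    """Exact per-draw midpoint distribution induced by slot multiplicities.

    Enumerates all ordered slot pairs and returns (probability per rounded
    midpoint, probability of a skipped draw).  The normalized Monte-Carlo
    map converges to this distribution as the number of draws grows.
    """
    entries = array.entries
    m = len(entries)
    a = np.repeat(entries, m, axis=0)
    b = np.tile(entries, (m, 1))
    keep = np.any(a != b, axis=1)
    if distance_limit is not None:
        d = np.hypot(*(b - a).T)
        keep &= d <= distance_limit
    width, height = bounds
    mid = round_half_away((a[keep] + b[keep]) / 2.0).astype(int)
    inb = (mid[:, 0] >= 0) & (mid[:, 0] < width) & (mid[:, 1] >= 0) & (mid[:, 1] < height)
    mid = mid[inb]
    dist: dict[tuple[int, int], float] = {}
    total = float(m * m)
    for x, y in mid:
        dist[(int(x), int(y))] = dist.get((int(x), int(y)), 0.0) + 1.0 / total
    skip_prob = 1.0 - sum(dist.values())
    return dist, skip_prob
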