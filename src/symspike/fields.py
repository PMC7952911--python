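"""Grid primitives, distance metrics, distance binning, and physical bounds.

Coordinates are 0-based ``(x=column, y=row)`` with the origin at the top-left,
matching raster-image convention.  Distances are in pixel units throughout;
the only physically dimensioned quantity in the package is
:func:`min_energy_bound`, which works in SI units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy import constants

__all__ = [
    "GridPoint",
    "ScalarField2D",
    "PointSet",
    "Metric",
    "BinningSpec",
    "distance",
    "pairwise_distances",
    "bin_distance",
    "bin_index",
    "bin_label",
    "min_energy_bound",
]


class GridPoint(NamedTuple):
    """A grid position: ``x`` is the column index, ``y`` the row index."""

    x: int
    y: int


class Metric(enum.Enum):
    """Distance metric on the pixel grid.

    Both satisfy the metric axioms (non-negativity, symmetry, triangle
    inequality).  The Manhattan (L1) metric makes horizontal, vertical and
    diagonal structure equidistant, and keeps all grid distances integral,
    which is what lets the digital delay-line network bin distances with
    whole clock cycles.
    """

    EUCLIDEAN = "euclidean"
    MANHATTAN = "manhattan"


@dataclass
class ScalarField2D:
    """A non-negative scalar surface S(x, y) stored row-major.

    Used for input images, edge maps and symmetry-density outputs alike.
    """

    values: np.ndarray  # shape (height, width), float64, all >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarField2D requires a 2-D array")
        if self.values.size and self.values.min() < 0:
            raise ValueError("ScalarField2D values must be non-negative")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __getitem__(self, p: GridPoint | tuple[int, int]) -> float:
        x, y = p
        return float(self.values[y, x])

    def mirror_x(self) -> "ScalarField2D":
        """Reflect across the vertical midline (x -> width-1-x)."""
        return ScalarField2D(self.values[:, ::-1].copy())

    def to_csv(self, path) -> None:
        """Serialize as ``width,height`` header then row-major values."""
        with open(path, "w") as fh:
            fh.write(f"{self.width},{self.height}\n")
            for row in self.values:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "ScalarField2D":
        with open(path) as fh:
            w, h = (int(t) for t in fh.readline().split(","))
            rows = [[float(t) for t in line.split(",")] for line in fh if line.strip()]
        arr = np.asarray(rows, dtype=float)
        if arr.shape != (h, w):
            raise ValueError(f"CSV body {arr.shape} does not match header ({h},{w})")
        return cls(arr)

    def to_png(self, path, scale: float | None = None) -> float:
        """Write a 16-bit grayscale PNG; returns the scale factor used.

        ``scale`` maps field values to the 16-bit range; by default the
        maximum value maps to 65535.
        """
        from PIL import Image

        vmax = float(self.values.max()) if self.values.size else 0.0
        if scale is None:
            scale = 65535.0 / vmax if vmax > 0 else 1.0
        arr = np.clip(self.values * scale, 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)
        return scale


@dataclass
class PointSet:
    """Discrete grid points, optionally weighted.

    ``coords`` has shape (n, 2) in (x, y) order.  Duplicate coordinates are
    rejected unless ``allow_duplicates`` is set (heuristic sampling
    deliberately replicates points).
    """

    coords: np.ndarray
    weights: np.ndarray | None = None
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        if self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if not self.allow_duplicates and len(self.coords) > 1:
            uniq = np.unique(self.coords, axis=0)
            if len(uniq) != len(self.coords):
                raise ValueError("duplicate points in PointSet")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.coords),):
                raise ValueError("weights must match number of points")
            if self.weights.size and self.weights.min() < 0:
                raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self) -> Iterable[GridPoint]:
        return (GridPoint(int(x), int(y)) for x, y in self.coords)

    @classmethod
    def from_points(cls, points: Iterable[tuple[int, int]], weights=None,
                    allow_duplicates: bool = False) -> "PointSet":
        pts = list(points)
        arr = np.asarray(pts, dtype=int).reshape(len(pts), 2)
        return cls(arr, weights=weights, allow_duplicates=allow_duplicates)

    def union(self, other: "PointSet") -> "PointSet":
        """Set union of coordinates (weights dropped)."""
        if len(self) == 0:
            return PointSet(other.coords.copy())
        if len(other) == 0:
            return PointSet(self.coords.copy())
        merged = np.unique(np.vstack([self.coords, other.coords]), axis=0)
        return PointSet(merged)


@dataclass(frozen=True)
class BinningSpec:
    """Number of decimal places a distance is rounded to before binning.

    Two distances closer than ``0.5 * 10**(-decimals)`` fall in the same
    bin.  Rounding ties go half-away-from-zero so that binning is exactly
    reproducible across the algorithmic and spiking realizations.
    """

    decimals: int = 1


def distance(a, b, metric: Metric = Metric.EUCLIDEAN) -> float:
    """Distance between two grid points under ``metric``."""
    ax, ay = a
    bx, by = b
    dx = float(bx - ax)
    dy = float(by - ay)
    if metric is Metric.EUCLIDEAN:
        return float(np.hypot(dx, dy))
    return abs(dx) + abs(dy)


def pairwise_distances(a: np.ndarray, b: np.ndarray,
                       metric: Metric = Metric.EUCLIDEAN) -> np.ndarray:
    """All distances between rows of ``a`` (m,2) and ``b`` (n,2); shape (m, n)."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    diff = a[:, None, :] - b[None, :, :]
    if metric is Metric.EUCLIDEAN:
        return np.hypot(diff[..., 0], diff[..., 1])
    return np.abs(diff).sum(axis=-1)


def _round_half_away(x, decimals: int = 0):
    """Round half away from zero (numpy's ``round`` rounds half to even)."""
    factor = 10.0 ** decimals
    scaled = np.asarray(x, dtype=float) * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def round_half_away(x, decimals: int = 0):
    return _round_half_away(x, decimals)


def bin_index(d, spec: BinningSpec):
    """Integer bin index: the rounded distance in units of 10^-decimals."""
    scaled = np.asarray(d, dtype=float) * 10.0 ** spec.decimals
    return np.floor(np.abs(scaled) + 0.5).astype(np.int64) * np.sign(scaled).astype(np.int64)


def bin_label(index: int, spec: BinningSpec) -> str:
    """Human-readable label for an integer bin index."""
    if spec.decimals <= 0:
        return str(int(index) * 10 ** (-spec.decimals))
    return f"{index / 10.0 ** spec.decimals:.{spec.decimals}f}"


def bin_distance(d: float, spec: BinningSpec) -> str:
    """Bin a single distance, returning its label (e.g. 6.403 -> "6.4").

    Negative distances are invalid.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return bin_label(int(bin_index(d, spec)), spec)


def min_energy_bound(pitch_dp: float) -> float:
    """Lower bound on average switching energy of the threshold layer, in J.

    For a coincidence detector that must resolve pulses separated by the
    propagation time of the array pitch ``d_p`` (meters) at the speed of
    light, the time-energy uncertainty relation gives E >= pi*hbar*c/(2*d_p).
    """
    if pitch_dp <= 0:
        raise ValueError("pitch must be positive")
    return float(np.pi * constants.hbar * constants.c / (2.0 * pitch_dp))
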