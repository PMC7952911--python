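"""Mirror-symmetry density via per-point distance histograms.

At every grid point ``p`` of the output domain, the distances from ``p`` to
every input point are binned into a histogram (the discrete form of the
contour integral of the input surface over circles centered at ``p``); the
value written to the output map is the histogram's mode count — the number
of input points sharing the most frequent distance.  Loci equidistant from
many input pairs (perpendicular bisectors, centers) receive high values.

Complexity is O(m*n) for m output points and n input points; everything is
vectorized over the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import (
    BinningSpec,
    Metric,
    PointSet,
    ScalarField2D,
    bin_index,
    bin_label,
    pairwise_distances,
)

__all__ = [
    "DensityConfig",
    "DistanceHistogram",
    "SymmetryDensityMap",
    "extract_points",
    "distance_histogram",
    "symmetry_density",
    "iterate_density",
    "density_mse",
]

#: Default render range for overlays (a fixed color scale keeps density
#: images comparable across tiles).
DEFAULT_RENDER_RANGE = (0.0, 350.0)


@dataclass
class DensityConfig:
    """Parameters of the density computation.

    metric
        Euclidean or Manhattan grid distance.
    binning
        Decimal places distances are rounded to before counting.
    input_threshold
        Pixel cutoff for point extraction (strictly greater-than).
    weighting
        ``"binary"`` counts each point once; ``"pixel_value"`` accumulates
        the source pixel value instead, so the map holds the maximum
        accumulated weight per bin.
    distance_limit
        If set, contributions farther than this many pixels are skipped —
        an a-priori scale selector that suppresses cross-scale noise.
    distance_noise_sd
        If set, i.i.d. Gaussian noise of this standard deviation is added
        to every point-pair distance before binning (clamped at zero).
        Relaxes the definition of coincidence so approximate symmetry
        becomes visible.
    rng_seed
        Seed for the distance-noise generator; with ``distance_noise_sd``
        unset or zero the output is deterministic and seed-independent.
    """

    metric: Metric = Metric.EUCLIDEAN
    binning: BinningSpec = field(default_factory=BinningSpec)
    input_threshold: float = 128.0
    weighting: str = "binary"
    distance_limit: float | None = None
    distance_noise_sd: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.weighting not in ("binary", "pixel_value"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.distance_limit is not None and self.distance_limit <= 0:
            raise ValueError("distance_limit must be positive")
        if self.distance_noise_sd is not None and self.distance_noise_sd < 0:
            raise ValueError("distance_noise_sd must be non-negative")


@dataclass
class DistanceHistogram:
    """Binned distance distribution at one grid point."""

    bins: dict[str, float]

    @property
    def mode_count(self) -> float:
        """Count (or accumulated weight) of the most frequent distance."""
        return max(self.bins.values()) if self.bins else 0.0

    @property
    def total(self) -> float:
        return sum(self.bins.values())


class SymmetryDensityMap(ScalarField2D):
    """A ScalarField2D whose value at p is the histogram mode count at p."""


def extract_points(fld: ScalarField2D, input_threshold: float,
                   weighting: str = "binary") -> PointSet:
    """All grid points with value strictly above the threshold, row-major.

    With ``weighting="pixel_value"`` the pixel values ride along as weights.
    """
    ys, xs = np.nonzero(fld.values > input_threshold)
    coords = np.column_stack([xs, ys])  # nonzero is row-major, so order holds
    weights = None
    if weighting == "pixel_value":
        weights = fld.values[ys, xs].astype(float)
    return PointSet(coords, weights=weights)


def _noisy_distances(dists: np.ndarray, config: DensityConfig,
                     rng: np.random.Generator | None) -> np.ndarray:
    if config.distance_noise_sd:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        dists = dists + rng.normal(0.0, config.distance_noise_sd, size=dists.shape)
        dists = np.maximum(dists, 0.0)  # distances cannot be negative
    return dists


def distance_histogram(p, points: PointSet, config: DensityConfig | None = None,
                       rng: np.random.Generator | None = None) -> DistanceHistogram:
    """Histogram of binned distances from ``p`` to every input point."""
    config = config or DensityConfig()
    if len(points) == 0:
        raise ValueError("empty PointSet")
    px, py = p
    dists = pairwise_distances(np.array([[px, py]]), points.coords, config.metric)[0]
    dists = _noisy_distances(dists, config, rng)
    keep = np.ones(len(dists), dtype=bool)
    if config.distance_limit is not None:
        keep = dists <= config.distance_limit
    idx = bin_index(dists[keep], config.binning)
    if config.weighting == "pixel_value" and points.weights is not None:
        w = points.weights[keep]
    else:
        w = np.ones(keep.sum())
    bins: dict[str, float] = {}
    for i, wi in zip(idx, w):
        lbl = bin_label(int(i), config.binning)
        bins[lbl] = bins.get(lbl, 0.0) + float(wi)
    return DistanceHistogram(bins)


def symmetry_density(points: PointSet, domain: tuple[int, int],
                     config: DensityConfig | None = None) -> SymmetryDensityMap:
    """Mode count of the distance histogram at every point of the domain.

    ``domain`` is (width, height).  O(m*n) for m = width*height domain
    points and n input points.
    """
    config = config or DensityConfig()
    width, height = domain
    if len(points) < 1:
        raise ValueError("empty PointSet")

    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    grid = np.column_stack([xs.ravel(), ys.ravel()])  # row-major
    dists = pairwise_distances(grid, points.coords, config.metric)  # (m, n)
    rng = np.random.default_rng(config.rng_seed)
    dists = _noisy_distances(dists, config, rng)

    keep = np.ones(dists.shape, dtype=bool)
    if config.distance_limit is not None:
        keep = dists <= config.distance_limit

    idx = bin_index(dists, config.binning)  # (m, n) integer bin indices
    if config.weighting == "pixel_value" and points.weights is not None:
        w = np.broadcast_to(points.weights, idx.shape)
    else:
        w = np.ones(idx.shape)

    m = idx.shape[0]
    # Per-row weighted bincount: offset each row's bins into a disjoint range.
    max_bin = int(idx.max()) + 1 if idx.size else 1
    flat = (np.arange(m)[:, None] * max_bin + idx).ravel()
    wf = np.where(keep, w, 0.0).ravel()
    counts = np.bincount(flat, weights=wf, minlength=m * max_bin)
    out = counts.reshape(m, max_bin).max(axis=1)
    return SymmetryDensityMap(out.reshape(height, width))


def iterate_density(points: PointSet, domain: tuple[int, int],
                    config: DensityConfig | None = None, iterations: int = 1,
                    feedback_threshold: float | None = None) -> SymmetryDensityMap:
    """Apply the density algorithm iteratively with feedback.

    After each pass, domain points whose density exceeds
    ``feedback_threshold`` (default: the map mean) are unioned with the
    original input points and the density is recomputed; the k-th map is
    returned.  Repeated application generates hierarchical, fractal-like
    symmetry-of-symmetry structure.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    config = config or DensityConfig()
    current = symmetry_density(points, domain, config)
    for _ in range(iterations - 1):
        thr = feedback_threshold
        if thr is None:
            thr = float(current.values.mean())
        fed = extract_points(current, thr)
        augmented = points.union(fed)
        current = symmetry_density(augmented, domain, config)
    return current


def density_mse(a: ScalarField2D, b: ScalarField2D) -> float:
    """Mean squared per-pixel difference between two density maps."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a.values - b.values) ** 2))
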