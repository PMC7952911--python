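"""Synthetic input generators: geometric outlines, an IFS triangle fractal,
and satellite-like tiles with rectangular building footprints.

Every generator is a pure, deterministic function of its parameters.
Fixtures declared bilaterally symmetric are symmetric pixel-for-pixel about
the vertical midline by construction (one half is drawn and mirrored), so
symmetry tests never run on silently asymmetric inputs.

The synthetic tile emulates the edge-geometry statistics the method
consumes from overhead imagery — rectangular human-made structures produce
many equidistant edge-point pairs, irregular vegetation-like clutter
produces few — without modeling radiometry or ground sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from .fields import ScalarField2D

__all__ = [
    "FixtureSpec",
    "RegionAnnotation",
    "make_outline",
    "make_ifs_fractal",
    "make_synthetic_tile",
]

OUTLINE_KINDS = ("two_point", "circle", "square", "triangle", "star", "aircraft_like")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, canvas size in pixels, seed, extras."""

    kind: str
    size: int = 64
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class RegionAnnotation:
    """Closed polygon rings in pixel coordinates with labels.

    Rings are validated closed and non-self-intersecting.
    """

    polygons: list  # list of [(x, y), ...] closed rings
    labels: list

    def __post_init__(self) -> None:
        from shapely.geometry import Polygon

        for ring in self.polygons:
            if len(ring) < 4 or tuple(ring[0]) != tuple(ring[-1]):
                raise ValueError("polygon ring must be closed (first == last)")
            if not Polygon(ring[:-1]).is_valid:
                raise ValueError("polygon ring is self-intersecting")

    def __len__(self) -> int:
        return len(self.polygons)

    def to_geojson(self, path) -> None:
        import json

        features = [
            {"type": "Feature",
             "properties": {"label": lbl},
             "geometry": {"type": "Polygon",
                          "coordinates": [[list(map(float, v)) for v in ring]]}}
            for ring, lbl in zip(self.polygons, self.labels)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RegionAnnotation":
        import json

        with open(path) as fh:
            data = json.load(fh)
        polygons, labels = [], []
        for i, feat in enumerate(data["features"]):
            ring = [tuple(v) for v in feat["geometry"]["coordinates"][0]]
            polygons.append(ring)
            labels.append(feat.get("properties", {}).get("label", str(i)))
        return cls(polygons, labels)


def _mirror_or(canvas: np.ndarray) -> np.ndarray:
    """Union a canvas with its vertical-midline mirror (exact symmetry)."""
    return np.maximum(canvas, canvas[:, ::-1])


def _polygon_outline(canvas: np.ndarray, xs, ys) -> None:
    rr, cc = skdraw.polygon_perimeter(ys, xs, shape=canvas.shape, clip=True)
    canvas[rr, cc] = 255.0


def make_outline(spec: FixtureSpec) -> ScalarField2D:
    """Binary (0/255) outline of the requested kind on a size x size canvas.

    Symmetric kinds are exactly mirror-symmetric about the vertical midline.
    """
    if spec.kind not in OUTLINE_KINDS:
        raise ValueError(f"unsupported outline kind {spec.kind!r}")
    s = spec.size
    if s < 16:
        raise ValueError("size must be >= 16")
    canvas = np.zeros((s, s))
    c = (s - 1) / 2.0
    if spec.kind == "two_point":
        # Placed symmetrically by hand: exactly two pixels, mirror images.
        gap = spec.params.get("gap", s // 2)
        y = s // 2
        x0 = (s - gap) // 2
        canvas[y, x0] = 255.0
        canvas[y, s - 1 - x0] = 255.0
        return ScalarField2D(canvas)
    if spec.kind == "circle":
        r = spec.params.get("radius", s // 3)
        rr, cc = skdraw.circle_perimeter(int(round(c)), int(round(c)), int(r), shape=canvas.shape)
        canvas[rr, cc] = 255.0
    elif spec.kind == "square":
        half = spec.params.get("half", s // 3)
        lo, hi = int(round(c - half)), int(round(c + half))
        _polygon_outline(canvas, [lo, hi, hi, lo], [lo, lo, hi, hi])
    elif spec.kind == "triangle":
        half = spec.params.get("half", s // 3)
        xs = [c - half, c + half, c]
        ys = [c + half, c + half, c - half]
        _polygon_outline(canvas, [int(round(v)) for v in xs], [int(round(v)) for v in ys])
    elif spec.kind == "star":
        n = spec.params.get("points", 5)
        r_out = spec.params.get("radius", s // 2 - 2)
        r_in = r_out * 0.45
        xs, ys = [], []
        for i in range(2 * n):
            r = r_out if i % 2 == 0 else r_in
            ang = -np.pi / 2 + i * np.pi / n
            xs.append(int(round(c + r * np.cos(ang))))
            ys.append(int(round(c + r * np.sin(ang))))
        _polygon_outline(canvas, xs, ys)
    elif spec.kind == "aircraft_like":
        # Bilaterally symmetric aircraft silhouette: fuselage, swept main
        # wings, tailplane, fin.  Drawn as one closed polygon.
        u = s / 64.0  # scale factor from the 64-px design
        def P(x, y):
            return (c + x * u, 8 * u + y * u)
        right = [
            P(0, 0),     # nose tip
            P(2, 8),     # nose flank
            P(3, 18),    # fuselage fore
            P(26, 32),   # wing leading edge tip
            P(26, 37),   # wing tip chord
            P(5, 34),    # wing trailing edge root
            P(4, 42),    # aft fuselage
            P(12, 50),   # tailplane tip
            P(12, 53),   # tailplane chord
            P(2, 51),    # tail root
            P(0, 48),    # fin notch on centerline
        ]
        xs = [p[0] for p in right] + [2 * c - p[0] for p in reversed(right[1:-1])]
        ys = [p[1] for p in right] + [p[1] for p in reversed(right[1:-1])]
        _polygon_outline(canvas, [int(round(v)) for v in xs], [int(round(v)) for v in ys])
    return ScalarField2D(_mirror_or(canvas))  # exact pixel mirror symmetry


def make_ifs_fractal(depth: int, size: int, seed: int = 0) -> ScalarField2D:
    """Sierpinski-style triangle IFS rendered as a binary outline field.

    Three half-scale affine maps toward the triangle vertices are applied
    ``depth`` times; depth 1 yields three triangle outlines, and the number
    of triangles triples with each increment.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    canvas = np.zeros((size, size))
    top = ((size - 1) / 2.0, 1.0)
    left = (1.0, float(size - 2))
    right = (float(size - 2), float(size - 2))

    def recurse(a, b, c, d):
        if d == 0:
            xs = [int(round(p[0])) for p in (a, b, c)]
            ys = [int(round(p[1])) for p in (a, b, c)]
            _polygon_outline(canvas, xs, ys)
            return
        ab = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
        ac = ((a[0] + c[0]) / 2, (a[1] + c[1]) / 2)
        bc = ((b[0] + c[0]) / 2, (b[1] + c[1]) / 2)
        recurse(a, ab, ac, d - 1)
        recurse(ab, b, bc, d - 1)
        recurse(ac, bc, c, d - 1)

    recurse(top, left, right, depth)
    return ScalarField2D(canvas)


def count_ifs_triangles(depth: int) -> int:
    """Number of rendered triangle outlines at the given depth."""
    return 3 ** depth


def make_synthetic_tile(n_buildings: int, clutter: float, size: int,
                        seed: int = 0) -> tuple[ScalarField2D, RegionAnnotation]:
    """A satellite-like tile: rectangular buildings on cluttered background.

    Buildings are non-overlapping axis-aligned rectangles with bright
    edge-like boundaries; ``clutter`` is the expected number of irregular
    low-symmetry blobs per 1000 px².  Returns the image field and closed
    polygon rings (with a 1-px margin) around each building.

    Raises if a building cannot be placed without overlap in 100 attempts.
    """
    if n_buildings < 0:
        raise ValueError("n_buildings must be >= 0")
    rng = np.random.default_rng(seed)
    img = rng.uniform(0.0, 40.0, size=(size, size))  # faint background texture

    placed: list[tuple[int, int, int, int]] = []  # (x0, y0, x1, y1)
    polygons, labels = [], []
    for b in range(n_buildings):
        for attempt in range(100):
            w = int(rng.integers(size // 8, size // 3))
            h = int(rng.integers(size // 8, size // 3))
            x0 = int(rng.integers(1, size - w - 1))
            y0 = int(rng.integers(1, size - h - 1))
            x1, y1 = x0 + w, y0 + h
            clear = all(x1 + 2 < px0 or px1 + 2 < x0 or y1 + 2 < py0 or py1 + 2 < y0
                        for px0, py0, px1, py1 in placed)
            if not clear:
                continue
            placed.append((x0, y0, x1, y1))
            break
        else:
            raise RuntimeError(f"placement failure: could not place building {b}")
        # Bright rectangular boundary (edge-like intensity step).
        img[y0, x0:x1 + 1] = 255.0
        img[y1, x0:x1 + 1] = 255.0
        img[y0:y1 + 1, x0] = 255.0
        img[y0:y1 + 1, x1] = 255.0
        ring = [(x0 - 1, y0 - 1), (x1 + 1, y0 - 1), (x1 + 1, y1 + 1),
                (x0 - 1, y1 + 1), (x0 - 1, y0 - 1)]
        polygons.append(ring)
        labels.append(f"building_{b}")

    # Poisson-placed irregular clutter blobs (vegetation-like).
    n_clutter = rng.poisson(clutter * size * size / 1000.0)
    for _ in range(n_clutter):
        cx = rng.uniform(2, size - 3)
        cy = rng.uniform(2, size - 3)
        n_vert = int(rng.integers(5, 9))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        radii = rng.uniform(1.5, size / 16.0, size=n_vert)
        xs = np.clip(np.round(cx + radii * np.cos(angles)), 0, size - 1).astype(int)
        ys = np.clip(np.round(cy + radii * np.sin(angles)), 0, size - 1).astype(int)
        try:
            rr, cc = skdraw.polygon_perimeter(ys, xs, shape=img.shape, clip=True)
            img[rr, cc] = np.maximum(img[rr, cc], rng.uniform(150, 255))
        except (ValueError, IndexError):
            continue  # degenerate blob, skip
    return ScalarField2D(img), RegionAnnotation(polygons, labels)
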