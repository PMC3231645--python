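"""Polygonal fitting of the leaf contour and the three shape features.

The smooth closed contour is replaced by a polygon whose vertices are a
subset of the contour points (recursive farthest-point splitting, i.e. a
closed-curve Ramer-Douglas-Peucker).  The polygon is triangulated and the
three shape features are measured on it:

* surface area -- the pixel area of the fitted polygon (sum of signed fan
  triangle areas, which equals the shoelace area of the whole polygon);
* surface perimeter -- the number of pixels obtained by rasterising every
  polygon side with an 8-connected line, counting each shared vertex once;
* disfigurement -- the percentage of the polygon's strictly interior pixels
  whose colour matches the known background (holes and damage that show the
  board through the leaf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .edges import Contour, EdgeConfig, LeafImage, extract_contour
from .errors import GeometryError

#: per-channel tolerance when matching a pixel against the background colour
#: (tolerates anti-aliasing at hole rims).
BACKGROUND_MATCH_TOLERANCE = 10

#: default maximum point-to-segment deviation of the polygonal fit, pixels.
DEFAULT_FIT_TOLERANCE = 2.0


@dataclass
class PolygonFit:
    """A simplified closed polygon fitted to a contour.

    ``vertices`` are (row, col) contour points in traversal order;
    ``triangles`` is a fan triangulation as index triples whose signed
    areas sum to the polygon area.
    """

    vertices: np.ndarray
    tolerance_px: float
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.vertices)

    def euclidean_length(self) -> float:
        """Sum of Euclidean side lengths of the closed polygon."""
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def bounding_box(self) -> tuple[int, int]:
        """(height, width) of the polygon's bounding box, inclusive."""
        mins = self.vertices.min(axis=0)
        maxs = self.vertices.max(axis=0)
        return (int(round(maxs[0] - mins[0])) + 1,
                int(round(maxs[1] - mins[1])) + 1)


@dataclass
class ShapeFeatures:
    """The three shape features plus the bounding box of the leaf."""

    area_px: int
    perimeter_px: int
    disfigurement_pct: float
    height_px: int
    width_px: int

    def as_array(self) -> np.ndarray:
        return np.array([self.area_px, self.perimeter_px,
                         self.disfigurement_pct], dtype=np.float64)


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Distances from an (N, 2) point set to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.hypot(*(points - a).T)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(points - proj).T)


def _rdp_open(points: np.ndarray, tolerance: float) -> np.ndarray:
    """Indices kept by Ramer-Douglas-Peucker on an open chain."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = points[i + 1:j]
        d = _point_segment_distance(seg, points[i].astype(float),
                                    points[j].astype(float))
        k = int(np.argmax(d))
        if d[k] > tolerance:
            split = i + 1 + k
            keep[split] = True
            stack.append((i, split))
            stack.append((split, j))
    return np.flatnonzero(keep)


def fit_polygon(contour: Contour,
                tolerance_px: float = DEFAULT_FIT_TOLERANCE) -> PolygonFit:
    """Simplify a closed contour to a polygon within a deviation tolerance.

    The closed curve is split at its two mutually farthest points and each
    half is simplified recursively; every discarded contour point stays
    within ``tolerance_px`` of the polygon boundary (point-to-segment
    distance).  ``tolerance_px = 0`` keeps every contour point.
    """
    pts = np.asarray(contour.points, dtype=np.float64)
    if not contour.closed or len(pts) < 3:
        raise GeometryError("a closed contour with >= 3 points is required")
    if tolerance_px < 0:
        raise GeometryError("tolerance_px must be >= 0")
    if tolerance_px == 0:
        idx = np.arange(len(pts))
    else:
        # two mutually farthest points (chunked to bound memory)
        n = len(pts)
        best = (0, 0, -1.0)
        step = 2048
        for s in range(0, n, step):
            block = pts[s:s + step]
            d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            k = int(np.argmax(d2))
            bi, bj = divmod(k, n)
            if d2[bi, bj] > best[2]:
                best = (s + bi, bj, d2[bi, bj])
        i, j = sorted(best[:2])
        if best[2] == 0:
            raise GeometryError("degenerate contour: all points coincide")
        rolled = np.roll(pts, -i, axis=0)
        jj = (j - i) % n
        first = _rdp_open(rolled[:jj + 1], tolerance_px)
        second = _rdp_open(np.vstack([rolled[jj:], rolled[:1]]), tolerance_px)
        idx = np.concatenate([first, jj + second[1:-1]])
        idx = (idx + i) % n
        idx.sort()
    verts = pts[idx]
    # drop exactly collinear runs produced by zero-tolerance duplicates
    if len(verts) < 3 or _polygon_area_shoelace(verts) == 0:
        raise GeometryError("contour is collinear; cannot fit a polygon")
    tri = np.column_stack([
        np.zeros(len(verts) - 2, dtype=np.intp),
        np.arange(1, len(verts) - 1, dtype=np.intp),
        np.arange(2, len(verts), dtype=np.intp),
    ])
    return PolygonFit(vertices=verts, tolerance_px=float(tolerance_px),
                      triangles=tri)


def _polygon_area_shoelace(verts: np.ndarray) -> float:
    y = verts[:, 0]
    x = verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])
        return int(v > 0) - int(v < 0)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and o1 != 0 and o3 != 0


def _is_simple(verts: np.ndarray) -> bool:
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            c, d = verts[j], verts[(j + 1) % n]
            if _segments_intersect(a, b, c, d):
                return False
    return True


def polygon_area(poly: PolygonFit) -> int:
    """Pixel area of the fitted polygon via its fan triangulation.

    Signed triangle areas are summed, so the result equals the shoelace
    area of the whole polygon (within rounding) for any simple polygon,
    convex or not.
    """
    v = poly.vertices
    # the quadratic simplicity check is only affordable for genuinely
    # simplified polygons; dense zero-tolerance fits inherit simplicity
    # from the traced contour
    if len(v) <= 400 and not _is_simple(v):
        raise GeometryError("polygon is self-intersecting")
    total = 0.0
    for i0, i1, i2 in poly.triangles:
        a, b, c = v[i0], v[i1], v[i2]
        total += 0.5 * ((b[1] - a[1]) * (c[0] - a[0])
                        - (b[0] - a[0]) * (c[1] - a[1]))
    return int(round(abs(total)))


def _side_pixel_sets(poly: PolygonFit) -> tuple[np.ndarray, int]:
    """Rasterise all sides; returns (boundary pixel array, perimeter count).

    Each side is drawn with an 8-connected Bresenham line including both
    endpoints; shared vertices are counted once by dropping the final pixel
    of every side (the next side re-contributes it as its first pixel).
    """
    v = np.rint(poly.vertices).astype(np.intp)
    count = 0
    chunks = []
    n = len(v)
    for i in range(n):
        r0, c0 = v[i]
        r1, c1 = v[(i + 1) % n]
        rr, cc = draw_line(r0, c0, r1, c1)
        count += len(rr) - 1
        chunks.append(np.column_stack([rr, cc]))
    boundary = np.unique(np.vstack(chunks), axis=0)
    return boundary, count


def polygon_perimeter(poly: PolygonFit) -> int:
    """Perimeter as the pixel count of the rasterised polygon sides."""
    _, count = _side_pixel_sets(poly)
    return count


def disfigurement(image: LeafImage, poly: PolygonFit) -> float:
    """Percentage of strictly interior polygon pixels coloured as background.

    Interior pixels are found by scan-line (even-odd) filling of the
    polygon on pixel centres, minus the rasterised boundary pixels.  A
    pixel matches the background when every channel is within
    :data:`BACKGROUND_MATCH_TOLERANCE` of ``image.background_rgb``.
    """
    v = poly.vertices
    if (v.min() < 0 or v[:, 0].max() >= image.height
            or v[:, 1].max() >= image.width):
        raise GeometryError("polygon exceeds image bounds")
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=image.pixels.shape[:2])
    fill = np.zeros(image.pixels.shape[:2], dtype=bool)
    fill[rr, cc] = True
    boundary, _ = _side_pixel_sets(poly)
    fill[boundary[:, 0], boundary[:, 1]] = False
    n_interior = int(fill.sum())
    if n_interior == 0:
        raise GeometryError("polygon has no interior pixels")
    bg = np.asarray(image.background_rgb, dtype=np.int16)
    diff = np.abs(image.pixels.astype(np.int16) - bg)
    bg_like = np.all(diff <= BACKGROUND_MATCH_TOLERANCE, axis=-1)
    n_bg = int(np.count_nonzero(bg_like & fill))
    return 100.0 * n_bg / n_interior


def shape_features(image: LeafImage, config: EdgeConfig | None = None,
                   tolerance_px: float = DEFAULT_FIT_TOLERANCE
                   ) -> ShapeFeatures:
    """Extract the contour and measure all three shape features."""
    contour = extract_contour(image, config)
    poly = fit_polygon(contour, tolerance_px)
    return shape_features_from_polygon(image, poly)


def shape_features_from_polygon(image: LeafImage,
                                poly: PolygonFit) -> ShapeFeatures:
    h, w = poly.bounding_box()
    return ShapeFeatures(
        area_px=polygon_area(poly),
        perimeter_px=polygon_perimeter(poly),
        disfigurement_pct=disfigurement(image, poly),
        height_px=h,
        width_px=w,
    )
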