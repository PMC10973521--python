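"""Coordinate-geometry primitives for landmark detection on bone masks.

Conventions used throughout the package:

* Continuous pixel centres sit at integer coordinates; ``x`` is the image
  column and ``y`` the image row, with the origin at the top-left corner and
  ``y`` increasing downward (toward the ankle in a correctly oriented
  standing AP radiograph).  "Above" therefore always means *smaller* ``y``.
* Outlines are closed pixel-boundary loops traced clockwise in image
  coordinates (Moore neighbour tracing on the 8-connected foreground).
* Ties are broken by smallest outline index, then smallest ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError


class GeometryError(ValueError):
    """Raised when a geometric operation receives degenerate input."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


@dataclass(frozen=True)
class Point:
    """A continuous image location (x = column, y = row, y grows downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GeometryError("non-finite-point", f"({self.x}, {self.y})")

    def __iter__(self):
        yield self.x
        yield self.y

    def distance_to(self, other: "Point") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


@dataclass(frozen=True)
class Line:
    """A directed line through two distinct anchor points, direction p -> q."""

    p: Point
    q: Point

    def __post_init__(self):
        if self.p.x == self.q.x and self.p.y == self.q.y:
            raise GeometryError("degenerate-line", "anchor points coincide")

    @property
    def direction(self) -> np.ndarray:
        d = np.array([self.q.x - self.p.x, self.q.y - self.p.y], dtype=float)
        return d / np.hypot(d[0], d[1])

    @property
    def normal(self) -> np.ndarray:
        dx, dy = self.direction
        return np.array([-dy, dx])

    def midpoint(self) -> Point:
        return Point((self.p.x + self.q.x) / 2.0, (self.p.y + self.q.y) / 2.0)

    def signed_distance(self, pt: Point) -> float:
        """Perpendicular distance of ``pt`` from the infinite line (signed
        by the left/right side relative to the p -> q direction)."""
        nx, ny = self.normal
        return float(nx * (pt.x - self.p.x) + ny * (pt.y - self.p.y))


@dataclass(frozen=True)
class Circle:
    center: Point
    radius: float

    def __post_init__(self):
        if not (self.radius > 0):
            raise GeometryError("degenerate-circle", f"radius {self.radius}")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box.  The "bottom line" is the row ``y = ymax``; the
    "upper corners" are ``(xmin, ymin)`` and ``(xmax, ymin)``."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise GeometryError("degenerate-box", repr(self))

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def upper_left(self) -> Point:
        return Point(self.xmin, self.ymin)

    @property
    def upper_right(self) -> Point:
        return Point(self.xmax, self.ymin)


class Outline:
    """An ordered, closed, clockwise boundary loop of a mask component.

    Stored as an (n, 2) float array of (x, y) pixel coordinates with n >= 8,
    first point adjacent to the last, no consecutive duplicates.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("bad-outline", "expected (n, 2) array")
        if len(pts) < 8:
            raise GeometryError("bad-outline", f"only {len(pts)} points")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("bad-outline", "non-finite coordinates")
        dup = np.all(pts == np.roll(pts, -1, axis=0), axis=1)
        if dup.any():
            raise GeometryError("bad-outline", "consecutive duplicate points")
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if abs(area) < 0.5:
            # e.g. a single-row component traced back and forth
            raise GeometryError("bad-outline", "outline encloses no area")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def point(self, i: int) -> Point:
        x, y = self.points[int(i) % len(self.points)]
        return Point(float(x), float(y))

    def centroid(self) -> Point:
        cx, cy = self.points.mean(axis=0)
        return Point(float(cx), float(cy))

    def arc_indices(self, i: int, j: int) -> np.ndarray:
        """Indices of the forward arc i -> j (inclusive), wrapping at n."""
        n = len(self.points)
        i, j = int(i) % n, int(j) % n
        if j >= i:
            return np.arange(i, j + 1)
        return np.concatenate([np.arange(i, n), np.arange(0, j + 1)])


# ---------------------------------------------------------------------------
# Outline extraction (Moore neighbour tracing, 8-connected foreground)
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order for image coords (y down):
# E, SE, S, SW, W, NW, N, NE as (dy, dx)
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of the largest 8-connected foreground component."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise GeometryError("empty-mask", "no foreground pixels")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def extract_outline(mask: np.ndarray) -> Outline:
    """Trace the boundary of the largest 8-connected component of ``mask``.

    Returns a clockwise (in image coordinates) closed loop of boundary pixel
    centres.  Interior holes are ignored.
    """
    comp = largest_component(mask)
    # Pad so tracing never walks off the raster.
    padded = np.pad(comp, 1)
    rows, cols = np.nonzero(padded)
    # Start at the top-most, then left-most foreground pixel.
    start_idx = np.lexsort((cols, rows))[0]
    start = (int(rows[start_idx]), int(cols[start_idx]))

    boundary = [start]
    # Backtrack: the pixel we "came from".  For the top-left start, the pixel
    # above it is background; entering direction W keeps the trace clockwise.
    prev_dir = 6  # N neighbour is background, so begin scanning from N
    cur = start
    while True:
        found = False
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            dy, dx = _MOORE[d]
            ny, nx = cur[0] + dy, cur[1] + dx
            if padded[ny, nx]:
                boundary.append((ny, nx))
                # Next scan starts just past the reverse of the move taken.
                prev_dir = (d + 4) % 8
                cur = (ny, nx)
                found = True
                break
        if not found:  # isolated pixel
            break
        if cur == start:
            boundary.pop()  # drop the repeated start
            break
        if len(boundary) > 4 * padded.size:  # pragma: no cover - safety stop
            raise GeometryError("bad-outline", "tracing failed to close")

    pts = np.array([(c - 1, r - 1) for r, c in boundary], dtype=float)
    if len(pts) < 8:
        # Tiny components (single pixels, short bars) cannot form a valid
        # closed outline; treat as degenerate.
        raise GeometryError("bad-outline", f"component boundary of {len(pts)} px")
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    return Outline(pts[keep])


# ---------------------------------------------------------------------------
# Circle fitting (algebraic least squares, Kasa formulation)
# ---------------------------------------------------------------------------


def fit_circle(points: Sequence | np.ndarray) -> Circle:
    """Least-squares circle through >= 3 non-collinear points.

    Solves the linear (Kasa) system 2ax + 2by + c = x^2 + y^2 for the centre
    (a, b) and radius sqrt(c + a^2 + b^2).  Exact on noiseless circular data.
    """
    pts = _as_xy(points)
    if len(pts) < 3:
        raise GeometryError("degenerate-circle", "need >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    # Centre coordinates to condition the normal equations.
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    A = np.column_stack([2 * u, 2 * v, np.ones(len(u))])
    b = u * u + v * v
    sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise GeometryError("degenerate-circle", "collinear points")
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if not (r2 > 0) or not np.isfinite(r2):
        raise GeometryError("degenerate-circle", "non-positive radius")
    return Circle(Point(float(a + mx), float(bb + my)), float(np.sqrt(r2)))


# ---------------------------------------------------------------------------
# Convex hull / bounding box
# ---------------------------------------------------------------------------


def convex_hull(points: Sequence | np.ndarray) -> np.ndarray:
    """Hull vertices as an (m, 2) array in consistent (clockwise on screen)
    order; raises ``degenerate-hull`` when all points are collinear."""
    pts = _as_xy(points)
    if len(pts) < 3:
        raise GeometryError("degenerate-hull", "need >= 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError("degenerate-hull", "collinear points") from exc
    return pts[hull.vertices]


def bounding_box(outline: Outline | np.ndarray) -> Box:
    """Tight axis-aligned bounding box of an outline (or point array)."""
    pts = outline.points if isinstance(outline, Outline) else _as_xy(outline)
    return Box(
        float(pts[:, 0].min()),
        float(pts[:, 1].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].max()),
    )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def find_two_peaks(
    outline: Outline, orientation: str = "upward", min_prominence_frac: float = 0.05
) -> Tuple[int, int]:
    """Outline indices of the two most prominent upward prominences.

    A peak is a local minimum in ``y`` along the closed outline whose
    prominence is at least ``min_prominence_frac`` of the outline's bounding
    box height.  Returns the left peak (smaller x) first.
    """
    if orientation != "upward":
        raise GeometryError("bad-orientation", orientation)
    y = outline.y
    n = len(y)
    box = bounding_box(outline)
    prominence = min_prominence_frac * box.height
    # Unroll the closed curve starting at its lowest point so peaks are not
    # split across the wrap point.
    start = int(np.argmax(y))
    rolled = np.roll(y, -start)
    signal = np.concatenate([rolled, rolled[:1]])
    idx, props = find_peaks(-signal, prominence=prominence)
    if len(idx) < 2:
        raise GeometryError("peaks-not-found", f"{len(idx)} peak(s) detected")
    order = np.argsort(props["prominences"])[::-1][:2]
    picked = [(int(idx[k]) + start) % n for k in order]
    picked.sort(key=lambda i: (outline.x[i], i))
    return picked[0], picked[1]


# ---------------------------------------------------------------------------
# Angles and closest points
# ---------------------------------------------------------------------------


def directed_angle(a: Line, b: Line) -> float:
    """Signed angle (degrees, in (-180, 180]) rotating a's direction onto
    b's, positive counter-clockwise in image coordinates (x right, y down).

    Antisymmetric and additive modulo 360.
    """
    ax, ay = a.q.x - a.p.x, a.q.y - a.p.y
    bx, by = b.q.x - b.p.x, b.q.y - b.p.y
    ang = np.degrees(np.arctan2(ax * by - ay * bx, ax * bx + ay * by))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else float(a)


def closest_point_on_outline(
    outline: Outline, line: Line, region: Optional[np.ndarray] = None
) -> Point:
    """Outline point with minimum perpendicular distance to the infinite
    line; the search may be restricted to ``region`` (outline indices).
    Ties break toward the smaller outline index."""
    if region is None:
        region = np.arange(len(outline))
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise GeometryError("empty-region", "no outline indices to search")
    pts = outline.points[region]
    nx, ny = line.normal
    d = np.abs(nx * (pts[:, 0] - line.p.x) + ny * (pts[:, 1] - line.p.y))
    best = int(np.argmin(d))  # argmin returns the first (smallest index) tie
    return Point(float(pts[best, 0]), float(pts[best, 1]))


def _as_xy(points) -> np.ndarray:
    if isinstance(points, Outline):
        return points.points
    if len(points) and isinstance(points[0], Point):
        return np.array([(p.x, p.y) for p in points], dtype=float)
    return np.asarray(points, dtype=float).reshape(-1, 2)
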