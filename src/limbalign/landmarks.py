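"""Rule-based anatomic feature-point extraction from per-bone masks.

Five procedures turn the per-bone binary segmentation masks of one leg into
the eight feature points used for coronal alignment measurement:

1.  femoral head centre — centre of a least-squares circle fit to the
    femoral-head outline;
2.  distal femur — the two most distal condyle points (one per lateral half
    of the lower outline arc, each closest to the bounding-box bottom line)
    and the intercondylar notch (highest outline point strictly between the
    condyles and below the centroid);
3.  tibial spine centre — midpoint of the two tibial-spine peaks, projected
    onto the outline along the line orthogonal to the inter-peak segment;
4.  tibial plateau edge points — convex-hull points above the centroid
    closest to the two upper bounding-box corners;
5.  ankle centre — the talus' plateau-style corner points define an
    orthogonal mid-line, and the distal-tibia outline point closest to that
    line on its lower arc is the mid-malleolar (ankle centre) point.

Medial/lateral labels are resolved from the patient ``side``: on a standard
AP image the medial side of a right leg is the larger-x side, of a left leg
the smaller-x side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Optional, Tuple

import numpy as np

from . import geometry as geo
from .geometry import GeometryError, Line, Outline, Point

Side = Literal["left", "right"]


class LandmarkError(ValueError):
    """A landmark procedure failed; ``regions`` names the failing parts."""

    def __init__(self, regions, message: str = ""):
        if isinstance(regions, str):
            regions = [regions]
        self.regions = list(regions)
        label = ", ".join(self.regions)
        super().__init__(f"landmark-failure({label})" + (f": {message}" if message else ""))


BONE_NAMES = ("femoral_head", "distal_femur", "proximal_tibia", "distal_tibia", "talus")


@dataclass
class LimbMasks:
    """The five per-bone binary rasters of one leg on a shared image grid."""

    femoral_head: np.ndarray
    distal_femur: np.ndarray
    proximal_tibia: np.ndarray
    distal_tibia: np.ndarray
    talus: np.ndarray
    side: Side = "right"
    pixel_spacing: Optional[float] = None  # mm per pixel, isotropic

    def __post_init__(self):
        shapes = {self[name].shape for name in BONE_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"masks must share one image grid, got {shapes}")
        for name in BONE_NAMES:
            setattr(self, name, np.asarray(self[name]).astype(bool))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in BONE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.femoral_head.shape

    def check_ordering(self) -> bool:
        """Proximal-to-distal ordering of component centroids (femoral head
        above distal femur above proximal tibia above distal tibia above
        talus)."""
        cy = []
        for name in BONE_NAMES:
            m = self[name]
            if not m.any():
                return False
            cy.append(np.nonzero(m)[0].mean())
        return bool(np.all(np.diff(cy) > 0))


@dataclass(frozen=True)
class LandmarkSet:
    """The eight anatomic feature points of one leg (pixel coordinates)."""

    femoral_head_center: Point
    intercondylar_notch: Point
    tibial_spine_center: Point
    medial_condyle: Point
    lateral_condyle: Point
    medial_plateau: Point
    lateral_plateau: Point
    ankle_center: Point

    def as_dict(self) -> Dict[str, Tuple[float, float]]:
        return {k: (p.x, p.y) for k, p in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d) -> "LandmarkSet":
        return cls(**{k: Point(float(v[0]), float(v[1])) for k, v in d.items()})

    def check_invariants(self) -> None:
        if not (
            self.femoral_head_center.y
            < self.intercondylar_notch.y
            < self.ankle_center.y
        ):
            raise LandmarkError("ordering", "proximal-to-distal ordering violated")


def _medial_lateral(a: Point, b: Point, side: Side) -> Tuple[Point, Point]:
    """Order a pair as (medial, lateral) for the given patient side."""
    left, right = (a, b) if a.x <= b.x else (b, a)
    # Right leg in a standard AP image: medial = larger x.
    return (right, left) if side == "right" else (left, right)


# ---------------------------------------------------------------------------
# 1. Femoral head
# ---------------------------------------------------------------------------


def femoral_head_center(mask: np.ndarray) -> Point:
    """Centre of the least-squares circle fit to the femoral-head outline."""
    try:
        outline = geo.extract_outline(mask)
        circle = geo.fit_circle(outline.points)
    except GeometryError as exc:
        raise LandmarkError("femoral_head", str(exc)) from exc
    return circle.center


# ---------------------------------------------------------------------------
# 2. Distal femur: condyle points and intercondylar notch
# ---------------------------------------------------------------------------


def distal_femur_landmarks(
    mask: np.ndarray, side: Side = "right"
) -> Tuple[Point, Point, Point]:
    """(intercondylar_notch, medial_condyle, lateral_condyle).

    The two condyle points are, on each lateral half of the outline's lower
    arc (split at the centroid column), the point closest to the bounding
    box's bottom line.  The notch is the highest point of the outline arc
    strictly between the condyles and below the centroid.
    """
    try:
        outline = geo.extract_outline(mask)
    except GeometryError as exc:
        raise LandmarkError("distal_femur", str(exc)) from exc
    box = geo.bounding_box(outline)
    centroid = outline.centroid()

    lower = outline.y > centroid.y
    left = lower & (outline.x < centroid.x)
    right = lower & (outline.x >= centroid.x)
    if not left.any() or not right.any():
        raise LandmarkError("distal_femur", "no lower arc on one side")

    def _closest_to_bottom(sel: np.ndarray) -> int:
        idx = np.nonzero(sel)[0]
        d = box.ymax - outline.y[idx]  # distance to the bottom line
        tied = idx[d == d.min()]
        # Flat raster runs tie; the middle of the run is the stable,
        # mirror-consistent representative of the most distal point.
        tied = tied[np.argsort(outline.x[tied], kind="stable")]
        return int(tied[(len(tied) - 1) // 2])

    i_left = _closest_to_bottom(left)
    i_right = _closest_to_bottom(right)
    p_left, p_right = outline.point(i_left), outline.point(i_right)

    # The notch lies on the outline arc joining the condyles through the
    # inter-condylar region: of the two arcs, the one staying lower (larger
    # mean y) is the inter-condylar one.
    arc_a = outline.arc_indices(i_left, i_right)
    arc_b = outline.arc_indices(i_right, i_left)
    arc = arc_a if outline.y[arc_a].mean() >= outline.y[arc_b].mean() else arc_b
    interior = arc[1:-1]
    interior = interior[outline.y[interior] > centroid.y]
    if interior.size == 0:
        raise LandmarkError("distal_femur", "no inter-condylar arc below centroid")
    notch_i = int(interior[np.argmin(outline.y[interior])])
    notch = outline.point(notch_i)
    # A true notch rises above both condyle tips; a convex lower border
    # yields no such prominence.
    if notch.y >= min(p_left.y, p_right.y):
        raise LandmarkError("distal_femur", "no intercondylar prominence")

    medial, lateral = _medial_lateral(p_left, p_right, side)
    return notch, medial, lateral


# ---------------------------------------------------------------------------
# 3. Proximal tibia: tibial spine centre
# ---------------------------------------------------------------------------


def tibial_spine_center(mask: np.ndarray) -> Point:
    """Midpoint of the two tibial-spine peaks projected onto the outline.

    The two upward peaks are detected on the outline; the line through their
    midpoint orthogonal to the inter-peak segment is intersected with the
    outline arc between the peaks (the outline point of minimum distance to
    that line).
    """
    try:
        outline = geo.extract_outline(mask)
        i1, i2 = geo.find_two_peaks(outline)
    except GeometryError as exc:
        raise LandmarkError("proximal_tibia", str(exc)) from exc
    p1, p2 = outline.point(i1), outline.point(i2)
    mid = Point((p1.x + p2.x) / 2.0, (p1.y + p2.y) / 2.0)
    ortho = _orthogonal_line(p1, p2, mid)
    # Search only the arc between the peaks (the shorter one runs through
    # the inter-spine sulcus; the longer one loops around the whole bone).
    arc_a = outline.arc_indices(i1, i2)
    arc_b = outline.arc_indices(i2, i1)
    arc = arc_a if len(arc_a) <= len(arc_b) else arc_b
    arc = arc[1:-1]
    if arc.size == 0:
        raise LandmarkError("proximal_tibia", "no inter-peak arc")
    return geo.closest_point_on_outline(outline, ortho, region=arc)


def _orthogonal_line(p1: Point, p2: Point, through: Point) -> Line:
    nx, ny = -(p2.y - p1.y), (p2.x - p1.x)
    norm = np.hypot(nx, ny)
    # Perpendicular direction to p1 -> p2, anchored at `through`.
    return Line(through, Point(through.x + nx / norm, through.y + ny / norm))


# ---------------------------------------------------------------------------
# 4. Proximal tibia surface line (plateau edge points)
# ---------------------------------------------------------------------------


def plateau_surface_points(
    mask: np.ndarray, side: Side = "right", region: str = "proximal_tibia_surface"
) -> Tuple[Point, Point]:
    """(medial_plateau, lateral_plateau): the convex-hull points above the
    centroid closest to the two upper bounding-box corners."""
    try:
        outline = geo.extract_outline(mask)
        hull = geo.convex_hull(outline.points)
    except GeometryError as exc:
        raise LandmarkError(region, str(exc)) from exc
    centroid = outline.centroid()
    box = geo.bounding_box(outline)
    cand = hull[hull[:, 1] < centroid.y]
    if len(cand) == 0:
        raise LandmarkError(region, "no hull candidates above centroid")

    def _nearest(corner: Point) -> Point:
        d = np.hypot(cand[:, 0] - corner.x, cand[:, 1] - corner.y)
        # ties break toward the more superior (smaller y) candidate, which
        # is mirror-consistent, then toward smaller x
        order = np.lexsort((cand[:, 0], cand[:, 1], d))
        return Point(float(cand[order[0], 0]), float(cand[order[0], 1]))

    p_ul = _nearest(box.upper_left)
    p_ur = _nearest(box.upper_right)
    if p_ul == p_ur:
        raise LandmarkError(region, "corner candidates coincide")
    return _medial_lateral(p_ul, p_ur, side)


# ---------------------------------------------------------------------------
# 5. Ankle centre (distal tibia + talus)
# ---------------------------------------------------------------------------


def ankle_center(distal_tibia_mask: np.ndarray, talus_mask: np.ndarray) -> Point:
    """Mid-malleolar point: the distal-tibia outline point on its lower arc
    closest to the orthogonal mid-line of the two talus corner points."""
    try:
        t1, t2 = plateau_surface_points(talus_mask, side="right", region="ankle")
    except LandmarkError as exc:
        raise LandmarkError("ankle", str(exc)) from exc
    mid = Point((t1.x + t2.x) / 2.0, (t1.y + t2.y) / 2.0)
    ortho = _orthogonal_line(t1, t2, mid)
    try:
        outline = geo.extract_outline(distal_tibia_mask)
    except GeometryError as exc:
        raise LandmarkError("ankle", str(exc)) from exc
    centroid = outline.centroid()
    region = np.nonzero(outline.y > centroid.y)[0]
    if region.size == 0:
        raise LandmarkError("ankle", "no lower arc on distal tibia")
    return geo.closest_point_on_outline(outline, ortho, region=region)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def extract_landmarks(masks: LimbMasks) -> LandmarkSet:
    """All eight feature points from one leg's masks.

    Sub-procedure failures are aggregated into one ``LandmarkError`` naming
    every failing region.
    """
    failures: list = []
    results: dict = {}

    def _run(key, fn, *args):
        try:
            results[key] = fn(*args)
        except LandmarkError as exc:
            failures.extend(exc.regions)

    _run("head", femoral_head_center, masks.femoral_head)
    _run("femur", distal_femur_landmarks, masks.distal_femur, masks.side)
    _run("spine", tibial_spine_center, masks.proximal_tibia)
    _run("plateau", plateau_surface_points, masks.proximal_tibia, masks.side)
    _run("ankle", ankle_center, masks.distal_tibia, masks.talus)
    if failures:
        raise LandmarkError(failures)

    notch, med_condyle, lat_condyle = results["femur"]
    med_plateau, lat_plateau = results["plateau"]
    lm = LandmarkSet(
        femoral_head_center=results["head"],
        intercondylar_notch=notch,
        tibial_spine_center=results["spine"],
        medial_condyle=med_condyle,
        lateral_condyle=lat_condyle,
        medial_plateau=med_plateau,
        lateral_plateau=lat_plateau,
        ankle_center=results["ankle"],
    )
    lm.check_invariants()
    return lm


def split_both_legs(image: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split a both-leg AP image at the vertical midline into (right, left)
    halves: in a standard AP view the patient's right leg is on the image
    left."""
    w = image.shape[1]
    return image[:, : w // 2], image[:, w // 2 :]
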