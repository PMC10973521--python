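"""Parametric limb phantoms: stylised standing AP long-leg radiographs.

The generator first places the eight ground-truth feature points
analytically from the three generative angles (mLDFA, MPTA, signed JLCA):
the tibial mechanical axis is laid out vertically, the plateau line is
rotated to the MPTA target about the tibial spine centre, the condylar line
is rotated from it by the JLCA target, and the femoral mechanical axis is
rotated to the mLDFA target about the intercondylar notch.  mTFA then
follows from the angle-composition identity.  Stylised bone silhouettes are
rasterised around those points:

* femoral head — a disk (optionally with a flattened inferior arc, as when
  the acetabulum overlaps the head on a radiograph);
* distal femur — shaft + two condylar lobes tangent to the condylar line,
  with a carved intercondylar wedge whose apex is the notch truth point;
* proximal tibia — a plateau slab with two triangular spine prominences
  flanking the spine centre, tapering into the shaft;
* distal tibia — a shaft ending in a flat plafond through the ankle centre;
* talus — a dome (semicircular top) centred under the plafond.

The landmark rules depend only on these topological features (two condyles,
two spines, a dome), so simple parametric shapes keep the ground truth
exact.  The rendered image is an 8-bit gray raster (bone 200, soft-tissue
halo 120, background 30, a vertical illumination gradient, and optional
Gaussian intensity noise); values are conventions, not physics.

Default angle distributions for populations are the automated-measurement
marginals reported for a varus-risk clinical cohort: mLDFA 87.73 +- 1.86,
MPTA 86.99 +- 3.29, JLCA 1.67 +- 1.41 (degrees).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import alignment
from .geometry import Point
from .landmarks import BONE_NAMES, LandmarkSet, LimbMasks

DEFAULT_ANGLE_DISTRIBUTIONS = {
    "mLDFA": (87.73, 1.86),
    "MPTA": (86.99, 3.29),
    "JLCA_signed": (1.67, 1.41),
}

PHYSIOLOGIC_MLDFA = 85.8
PHYSIOLOGIC_MPTA = 85.6


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and noise parameters of one synthetic limb (pixels)."""

    image_size: Tuple[int, int] = (448, 1376)  # (width, height)
    side: str = "right"
    femur_length: float = 600.0
    tibia_length: float = 540.0
    femoral_head_radius: float = 60.0
    condyle_radius: float = 26.0
    condyle_separation: float = 100.0
    spine_height: float = 22.0
    spine_separation: float = 44.0
    plateau_halfwidth: float = 80.0
    joint_gap: float = 18.0
    head_flatten: float = 0.0  # fraction of the head radius cut inferiorly
    mLDFA_target: float = PHYSIOLOGIC_MLDFA
    MPTA_target: float = PHYSIOLOGIC_MPTA
    JLCA_target_signed: float = 0.0
    boundary_jitter_p: float = 0.0
    intensity_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "femur_length",
            "tibia_length",
            "femoral_head_radius",
            "condyle_radius",
            "condyle_separation",
            "spine_height",
            "spine_separation",
            "plateau_halfwidth",
            "joint_gap",
        ):
            if not getattr(self, name) > 0:
                raise PhantomError(f"{name} must be positive")
        if self.side not in ("left", "right"):
            raise PhantomError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (0 <= self.head_flatten < 0.8):
            raise PhantomError("head_flatten must be in [0, 0.8)")
        if not (0 <= self.boundary_jitter_p < 0.5):
            raise PhantomError("boundary_jitter_p must be in [0, 0.5)")
        if not (60 <= self.mLDFA_target <= 120 and 60 <= self.MPTA_target <= 120):
            raise PhantomError("angle targets outside sanity bounds")
        if not abs(self.JLCA_target_signed) <= 30:
            raise PhantomError("JLCA target outside sanity bounds")

    def with_angles(self, mLDFA=None, MPTA=None, JLCA_signed=None, **kw) -> "PhantomSpec":
        upd = dict(kw)
        if mLDFA is not None:
            upd["mLDFA_target"] = mLDFA
        if MPTA is not None:
            upd["MPTA_target"] = MPTA
        if JLCA_signed is not None:
            upd["JLCA_target_signed"] = JLCA_signed
        return dataclasses.replace(self, **upd)


@dataclass
class PhantomCase:
    image: np.ndarray  # uint8 grayscale
    masks: LimbMasks
    truth_landmarks: LandmarkSet
    truth_angles: alignment.AlignmentAngles
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Vector helpers (all in image coordinates: x right, y down)
# ---------------------------------------------------------------------------


def _rot(deg: float) -> np.ndarray:
    """Rotation by ``deg`` such that directed_angle(u, R u) == deg."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s], [s, c]])


def _truth_landmarks_normalised(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Truth points in the side-normalised frame (lateral = +x)."""
    w, h = spec.image_size
    ankle = np.array([w / 2.0, h - 80.0])
    spine = ankle - np.array([0.0, spec.tibia_length])  # tibial mech vertical

    t_dist = np.array([0.0, 1.0])
    p_med = _rot(spec.MPTA_target) @ t_dist  # plateau, medial-pointing
    p_lat = -p_med
    c_lat = _rot(-spec.JLCA_target_signed) @ p_lat  # condylar, lateral
    n_c = _rot(90.0) @ c_lat  # condylar down-normal (y > 0 near neutral)

    med_plateau = spine + spec.plateau_halfwidth * p_med
    lat_plateau = spine + spec.plateau_halfwidth * p_lat

    c0 = spine - np.array([0.0, spec.joint_gap])  # condylar line midpoint
    med_condyle = c0 - (spec.condyle_separation / 2.0) * c_lat
    lat_condyle = c0 + (spec.condyle_separation / 2.0) * c_lat
    notch = c0 - 1.2 * spec.condyle_radius * n_c

    u_prox = _rot(-spec.mLDFA_target) @ c_lat  # femoral mech, proximal
    head = notch + spec.femur_length * u_prox

    return {
        "femoral_head_center": head,
        "intercondylar_notch": notch,
        "tibial_spine_center": spine,
        "medial_condyle": med_condyle,
        "lateral_condyle": lat_condyle,
        "medial_plateau": med_plateau,
        "lateral_plateau": lat_plateau,
        "ankle_center": ankle,
    }


# ---------------------------------------------------------------------------
# Rasterisation primitives (evaluated on the full canvas grid)
# ---------------------------------------------------------------------------


def _grid(shape) -> Tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return xx.astype(float), yy.astype(float)


def _disk(xx, yy, center, radius) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def _capsule(xx, yy, p1, p2, radius) -> np.ndarray:
    """Pixels within ``radius`` of the segment p1 -> p2."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    d = p2 - p1
    L2 = d @ d
    t = ((xx - p1[0]) * d[0] + (yy - p1[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    cx, cy = p1[0] + t * d[0], p1[1] + t * d[1]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _superellipse(xx, yy, touch, u_dir, n_dir, radius, power=1.3) -> np.ndarray:
    """Superellipse of semi-axes ``radius`` in the (u_dir, n_dir) frame,
    tangent to the u_dir line at ``touch`` from the -n_dir side."""
    dx, dy = xx - touch[0], yy - touch[1]
    xi = dx * u_dir[0] + dy * u_dir[1]
    eta = dx * n_dir[0] + dy * n_dir[1] + radius  # centre sits at eta = -radius
    return (np.abs(xi) / radius) ** power + (np.abs(eta) / radius) ** power <= 1.0


def _convex_poly(xx, yy, vertices) -> np.ndarray:
    """Fill of a convex polygon given vertices in consistent order."""
    v = np.asarray(vertices, float)
    inside = np.ones(xx.shape, dtype=bool)
    n = len(v)
    # Determine winding once from the signed area.
    area = 0.0
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    sign = 1.0 if area >= 0 else -1.0
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        cross = (x2 - x1) * (yy - y1) - (y2 - y1) * (xx - x1)
        inside &= sign * cross >= 0
    return inside


# ---------------------------------------------------------------------------
# Bone silhouettes
# ---------------------------------------------------------------------------


def _rasterise_bones(
    spec: PhantomSpec, lm: Dict[str, np.ndarray]
) -> Dict[str, np.ndarray]:
    w, h = spec.image_size
    xx, yy = _grid((h, w))
    r_c = spec.condyle_radius

    head = lm["femoral_head_center"]
    notch = lm["intercondylar_notch"]
    spine = lm["tibial_spine_center"]
    ankle = lm["ankle_center"]
    med_c, lat_c = lm["medial_condyle"], lm["lateral_condyle"]
    med_p, lat_p = lm["medial_plateau"], lm["lateral_plateau"]

    c0 = (med_c + lat_c) / 2.0
    c_dir = lat_c - med_c
    c_dir = c_dir / np.linalg.norm(c_dir)
    n_c = _rot(90.0) @ c_dir
    if n_c[1] < 0:
        n_c, c_dir = -n_c, c_dir  # keep the normal pointing distally
    u_fem = head - notch
    u_fem = u_fem / np.linalg.norm(u_fem)

    # --- femoral head: disk, optionally with a flattened inferior arc ------
    fh = _disk(xx, yy, head, spec.femoral_head_radius)
    if spec.head_flatten > 0:
        cut_y = head[1] + spec.femoral_head_radius * (1.0 - spec.head_flatten)
        fh &= yy <= cut_y

    # --- distal femur: condylar lobes + bridge + shaft, minus notch wedge --
    # Lobes are superellipses tangent to the condylar line at the condyle
    # points: the mild exponent gives a sharper most-distal point than a
    # circle, so the extreme survives raster quantisation and joint-line
    # tilt with sub-pixel stability.
    lobe_m = _superellipse(xx, yy, med_c, c_dir, n_c, r_c, power=1.3)
    lobe_l = _superellipse(xx, yy, lat_c, c_dir, n_c, r_c, power=1.3)
    half_sep = spec.condyle_separation / 2.0
    bridge = _convex_poly(
        xx,
        yy,
        [
            c0 - half_sep * c_dir - 0.8 * r_c * n_c,
            c0 + half_sep * c_dir - 0.8 * r_c * n_c,
            c0 + half_sep * c_dir - 2.1 * r_c * n_c,
            c0 - half_sep * c_dir - 2.1 * r_c * n_c,
        ],
    )
    shaft_f = _capsule(
        xx,
        yy,
        notch + 0.08 * spec.femur_length * u_fem,
        notch + 0.40 * spec.femur_length * u_fem,
        0.32 * spec.condyle_separation,
    )
    wedge = _convex_poly(
        xx,
        yy,
        [
            notch,
            c0 - 0.15 * r_c * n_c + 0.55 * r_c * c_dir,
            c0 - 0.15 * r_c * n_c - 0.55 * r_c * c_dir,
        ],
    )
    df = (lobe_m | lobe_l | bridge | shaft_f) & ~wedge

    # --- proximal tibia: plateau slab + spine triangles + shaft ------------
    p_dir = lat_p - med_p
    p_dir = p_dir / np.linalg.norm(p_dir)
    n_p = _rot(90.0) @ p_dir
    if n_p[1] < 0:
        n_p = -n_p
    taper = 70.0
    shaft_hw = 24.0
    sx = 1.0 if lat_p[0] >= med_p[0] else -1.0  # keep perimeter order
    drop = 25.0  # vertical sides below the plateau corners keep the
    # rasterised corners near right angles (no acute-corner pixel loss)
    slab = _convex_poly(
        xx,
        yy,
        [
            med_p,
            lat_p,
            lat_p + np.array([0.0, drop]),
            spine + np.array([sx * shaft_hw, taper]),
            spine + np.array([-sx * shaft_hw, taper]),
            med_p + np.array([0.0, drop]),
        ],
    )
    shaft_t = _capsule(
        xx,
        yy,
        spine + np.array([0.0, taper * 0.8]),
        spine + np.array([0.0, 0.35 * spec.tibia_length]),
        shaft_hw,
    )
    half_ss = spec.spine_separation / 2.0
    base_hw = 0.35 * spec.spine_separation
    spines = np.zeros(xx.shape, dtype=bool)
    for s in (-1.0, 1.0):
        base = spine + s * half_ss * p_dir
        tip = base - spec.spine_height * n_p
        spines |= _convex_poly(
            xx,
            yy,
            [tip, base + base_hw * p_dir + 2.0 * n_p, base - base_hw * p_dir + 2.0 * n_p],
        )
    pt = slab | shaft_t | spines

    # --- distal tibia: shaft with a flat plafond through the ankle ---------
    dt_hw = 22.0
    dt = (
        (np.abs(xx - ankle[0]) <= dt_hw)
        & (yy >= ankle[1] - 90.0)
        & (yy <= ankle[1])
    )

    # --- talus: dome (semicircular top) under the plafond ------------------
    r_t = 34.0
    gap = 8.0
    dome_c = ankle + np.array([0.0, gap + r_t])
    talus = (_disk(xx, yy, dome_c, r_t) & (yy <= dome_c[1])) | (
        (np.abs(xx - ankle[0]) <= r_t)
        & (yy > dome_c[1])
        & (yy <= dome_c[1] + 22.0)
    )

    masks = {
        "femoral_head": fh,
        "distal_femur": df,
        "proximal_tibia": pt,
        "distal_tibia": dt,
        "talus": talus,
    }
    for name, m in masks.items():
        if not m.any():
            raise PhantomError(f"canvas-overflow: {name} rasterised empty")
    # Overflow check: every silhouette must stay clear of the canvas border.
    border = np.zeros((h, w), dtype=bool)
    border[[0, -1], :] = True
    border[:, [0, -1]] = True
    for name, m in masks.items():
        if (m & border).any():
            raise PhantomError(f"canvas-overflow: {name} touches the border")
    return masks


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_image(spec: PhantomSpec, masks: Dict[str, np.ndarray], rng) -> np.ndarray:
    w, h = spec.image_size
    bone = np.zeros((h, w), dtype=bool)
    for m in masks.values():
        bone |= m
    halo = ndimage.binary_dilation(bone, iterations=8)
    img = np.full((h, w), 30.0)
    img[halo] = 120.0
    img[bone] = 200.0
    # Vertical illumination gradient (brighter at the hip, as with a tube
    # centred high on a long-leg stitch).
    img += np.linspace(12.0, -12.0, h)[:, None]
    if spec.intensity_sigma > 0:
        img += rng.normal(0.0, spec.intensity_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Deterministically build one phantom case from its spec."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    lm_norm = _truth_landmarks_normalised(spec)

    if spec.side == "right":
        # Right leg: lateral is the smaller-x side of a standard AP image,
        # so mirror the normalised (lateral = +x) construction.
        lm_img = {k: np.array([(w - 1) - v[0], v[1]]) for k, v in lm_norm.items()}
    else:
        lm_img = lm_norm

    masks_arr = _rasterise_bones(spec, lm_img)
    if spec.boundary_jitter_p > 0:
        masks_arr = {
            k: _jitter_mask(m, spec.boundary_jitter_p, rng)
            for k, m in masks_arr.items()
        }
    masks = LimbMasks(side=spec.side, **masks_arr)
    image = _render_image(spec, masks_arr, rng)

    truth = LandmarkSet(**{k: Point(float(v[0]), float(v[1])) for k, v in lm_img.items()})
    axes = alignment.build_axes(truth)
    truth_angles = alignment.compute_angles(axes, spec.side)
    _check_targets(spec, truth_angles)
    return PhantomCase(
        image=image, masks=masks, truth_landmarks=truth, truth_angles=truth_angles, spec=spec
    )


def _check_targets(spec: PhantomSpec, angles: alignment.AlignmentAngles) -> None:
    ok = (
        abs(angles.mLDFA - spec.mLDFA_target) < 1e-6
        and abs(angles.MPTA - spec.MPTA_target) < 1e-6
        and abs(angles.JLCA_signed - spec.JLCA_target_signed) < 1e-6
    )
    if not ok:  # pragma: no cover - construction is analytic
        raise PhantomError("truth angles inconsistent with targets")


def sample_specs(
    n: int,
    angle_distributions: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
) -> List[PhantomSpec]:
    """n i.i.d. phantom specs with Gaussian (mLDFA, MPTA, JLCA_signed)
    draws, truncated to the angle sanity bounds (and to an implied
    mechanical-axis deviation the canvas can contain).  Reproducible given
    ``seed``; generating the specs is cheap, so large populations can be
    streamed one rasterised case at a time."""
    if n < 1:
        raise PhantomError("n must be >= 1")
    dists = dict(DEFAULT_ANGLE_DISTRIBUTIONS)
    if angle_distributions:
        dists.update(angle_distributions)
    for key, (mean, sd) in dists.items():
        if sd < 0:
            raise PhantomError(f"negative SD for {key}")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = []
    while len(specs) < n:
        draw = {}
        for key, (mean, sd) in dists.items():
            lo, hi = (-10.0, 10.0) if key == "JLCA_signed" else (78.0, 102.0)
            val = rng.normal(mean, sd)
            while not (lo <= val <= hi):  # marginal truncation by resampling
                val = rng.normal(mean, sd)
            draw[key] = float(val)
        child_seed = int(rng.integers(0, 2**31 - 1))
        # Joint truncation: the implied mechanical-axis deviation
        # |mTFA - 180| must stay within what the canvas holds (a > 3.4 SD
        # event under the default marginals).
        implied_dev = abs(
            draw["mLDFA"] + draw["JLCA_signed"] + 180.0 - draw["MPTA"] - 180.0
        )
        if implied_dev > 12.0:
            continue
        specs.append(
            base.with_angles(
                mLDFA=draw["mLDFA"],
                MPTA=draw["MPTA"],
                JLCA_signed=draw["JLCA_signed"],
                seed=child_seed,
            )
        )
    return specs


def sample_population(
    n: int,
    angle_distributions: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
) -> List[PhantomCase]:
    """n i.i.d. generated phantoms (see ``sample_specs``)."""
    return [
        generate_phantom(s)
        for s in sample_specs(n, angle_distributions, seed, base_spec)
    ]


def _jitter_mask(mask: np.ndarray, p: float, rng) -> np.ndarray:
    """One Bernoulli erosion/dilation pass on the boundary pixels."""
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    out = mask.copy()
    out[inner & (rng.random(mask.shape) < p)] = False
    out[outer & (rng.random(mask.shape) < p)] = True
    return out


def corrupt_masks(masks: LimbMasks, boundary_jitter_p: float, seed: int = 0) -> LimbMasks:
    """Random boundary erosion/dilation noise on each bone mask.

    Each bone must stay a single 8-connected component; on violation the
    corruption is resampled (up to 10 tries) before failing.
    """
    if not (0 <= boundary_jitter_p < 0.5):
        raise PhantomError("boundary_jitter_p must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out = {}
    struct = np.ones((3, 3), dtype=int)
    for name in BONE_NAMES:
        src = masks[name]
        for attempt in range(10):
            cand = _jitter_mask(src, boundary_jitter_p, rng)
            if cand.any() and ndimage.label(cand, structure=struct)[1] == 1:
                out[name] = cand
                break
        else:
            raise PhantomError(f"corruption-failure({name})")
    return LimbMasks(side=masks.side, pixel_spacing=masks.pixel_spacing, **out)
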