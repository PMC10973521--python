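"""Coronal alignment angles from the eight knee/ankle feature points.

Builds the four measurement lines —

* femoral mechanical axis: femoral head centre -> intercondylar notch,
* tibial mechanical axis: tibial spine centre -> ankle centre,
* distal femoral articular line: medial -> lateral condyle,
* proximal tibial articular line: medial -> lateral plateau,

— and computes mTFA, mLDFA, MPTA and JLCA.  All angles are evaluated as
directed angles in a side-normalised frame (lateral = +x, proximal = -y),
which makes the composition identity

    mTFA = mLDFA + JLCA_signed + (180 - MPTA)

hold exactly and makes every value invariant under left/right mirroring.

Sign conventions (selectable for mTFA):

* ``varus_gt_180`` (default): mTFA = 180 + varus deviation, so varus knees
  read > 180 (matching population means around 181.8 in varus-risk cohorts);
* ``varus_lt_180``: the complementary convention in which the hip-knee-ankle
  angle of a varus knee reads < 180 (the "HKA < 177 means varus" reading).

JLCA is reported as a magnitude; its signed value (positive = lateral
joint-line opening) is retained for the identity above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal

from .geometry import GeometryError, Line, Point, directed_angle, wrap_angle
from .landmarks import LandmarkSet

Side = Literal["left", "right"]

MTFA_CONVENTIONS = ("varus_gt_180", "varus_lt_180")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AxisSet:
    """The four measurement lines of one leg."""

    femoral_mech: Line
    tibial_mech: Line
    femoral_articular: Line
    tibial_articular: Line


@dataclass(frozen=True)
class AlignmentAngles:
    """The four coronal alignment angles, in degrees.

    ``mTFA`` uses the ``varus_gt_180`` convention unless stated otherwise;
    ``JLCA`` is the magnitude of ``JLCA_signed`` (positive = lateral
    joint-line opening).
    """

    mTFA: float
    mLDFA: float
    MPTA: float
    JLCA_signed: float

    @property
    def JLCA(self) -> float:
        return abs(self.JLCA_signed)

    def quality_flags(self) -> List[str]:
        """Sanity-bound violations (do not invalidate the numbers)."""
        flags = []
        if not 150 <= self.mTFA <= 210:
            flags.append("mTFA-out-of-range")
        if not 60 <= self.mLDFA <= 120:
            flags.append("mLDFA-out-of-range")
        if not 60 <= self.MPTA <= 120:
            flags.append("MPTA-out-of-range")
        if not 0 <= self.JLCA <= 30:
            flags.append("JLCA-out-of-range")
        return flags

    def as_dict(self) -> dict:
        return {
            "mTFA": self.mTFA,
            "mLDFA": self.mLDFA,
            "MPTA": self.MPTA,
            "JLCA": self.JLCA,
            "JLCA_signed": self.JLCA_signed,
        }


def build_axes(landmarks: LandmarkSet) -> AxisSet:
    """Assemble the four lines from the named feature points."""

    def _line(name: str, p: Point, q: Point) -> Line:
        try:
            return Line(p, q)
        except GeometryError as exc:
            raise AlignmentError(f"degenerate-axis({name})") from exc

    return AxisSet(
        femoral_mech=_line(
            "femoral_mech", landmarks.femoral_head_center, landmarks.intercondylar_notch
        ),
        tibial_mech=_line(
            "tibial_mech", landmarks.tibial_spine_center, landmarks.ankle_center
        ),
        femoral_articular=_line(
            "femoral_articular", landmarks.medial_condyle, landmarks.lateral_condyle
        ),
        tibial_articular=_line(
            "tibial_articular", landmarks.medial_plateau, landmarks.lateral_plateau
        ),
    )


def _mirror_line(line: Line) -> Line:
    return Line(Point(-line.p.x, line.p.y), Point(-line.q.x, line.q.y))


def compute_angles(
    axes: AxisSet, side: Side, mtfa_convention: str = "varus_gt_180"
) -> AlignmentAngles:
    """The four alignment angles from an AxisSet.

    Angles are computed in a frame where the lateral side is +x: for a right
    leg in a standard AP image (medial = larger x) the x axis is mirrored
    first.  In that frame, with distal mechanical directions f (femur,
    head -> notch) and t (tibia, spine -> ankle) and lateral articular
    directions c (condylar) and p (plateau):

        mLDFA        = angle(-f -> c)   (lateral side of the knee)
        MPTA         = angle(t  -> -p)  (medial side of the knee)
        JLCA_signed  = angle(c  -> p)   (positive = lateral opening)
        mTFA         = mLDFA + JLCA_signed + (180 - MPTA)
                     = 180 + angle(f -> t)  (mod 360)

    so the composition identity is exact by construction.
    """
    if mtfa_convention not in MTFA_CONVENTIONS:
        raise AlignmentError(f"unknown mTFA convention {mtfa_convention!r}")
    if side not in ("left", "right"):
        raise AlignmentError(f"side must be 'left' or 'right', got {side!r}")

    fm, tm = axes.femoral_mech, axes.tibial_mech
    fa, ta = axes.femoral_articular, axes.tibial_articular
    if side == "right":
        # Right leg: medial is the larger-x side, so mirror to put lateral
        # at +x.  Mirroring also flips the articular (medial -> lateral)
        # directions consistently.
        fm, tm, fa, ta = map(_mirror_line, (fm, tm, fa, ta))

    f_prox = Line(fm.q, fm.p)  # notch -> head (proximal)
    c_lat = fa  # medial -> lateral condyle
    p_lat = ta  # medial -> lateral plateau
    p_med = Line(ta.q, ta.p)

    mldfa = directed_angle(f_prox, c_lat)
    mpta = directed_angle(tm, p_med)
    jlca_signed = directed_angle(c_lat, p_lat)
    mtfa = mldfa + jlca_signed + (180.0 - mpta)

    if mtfa_convention == "varus_lt_180":
        mtfa = 360.0 - mtfa

    return AlignmentAngles(
        mTFA=float(mtfa),
        mLDFA=float(mldfa),
        MPTA=float(mpta),
        JLCA_signed=float(jlca_signed),
    )


def classify_alignment(
    angles: AlignmentAngles, varus_threshold: float = 3.0
) -> Literal["varus", "neutral", "valgus"]:
    """Varus / neutral / valgus from mTFA with a deviation threshold
    (default 3 degrees, the conventional deformity cut-off)."""
    if not varus_threshold > 0:
        raise AlignmentError("varus_threshold must be > 0")
    dev = angles.mTFA - 180.0
    if dev > varus_threshold:
        return "varus"
    if -dev > varus_threshold:
        return "valgus"
    return "neutral"
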