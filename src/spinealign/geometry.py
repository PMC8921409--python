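"""Sagittal spinal-alignment geometry.

Twelve standard parameters are computed from eleven anatomical key points on a
lateral (sagittal) whole-spine radiograph: the anterior/posterior corner pairs
of five endplates — C2 inferior (AA'), C7 inferior (BB'), T1 superior (CC'),
L1 superior (DD') and S1/sacral superior (EE') — plus the femoral-head
center F.

Image coordinate convention: x = column (increases rightward), y = row
(increases downward).  "Horizontal" is the image row axis and "vertical" the
column axis; radiographs are assumed upright, so no gravity-vector correction
is applied.

Sign conventions (internal, signed representation):

* endplate slope: positive when the posterior corner is inferior (larger y)
  than the anterior corner; magnitude is the acute angle with the horizontal.
* pelvic tilt: positive when the sacral-plate midpoint lies posterior to the
  femoral-head center.
* incidence-type angles are defined through the identity
  ``incidence = signed_pelvic_tilt + signed_slope(target endplate)``,
  i.e. the signed angle between the femoral-center-to-sacral-midpoint line
  and the anterior-leaning perpendicular of the target endplate.
* Cobb-type angles (LL, TK, C27L) are ``slope(lower) - slope(upper)``.

The public report (:func:`compute_all_parameters` with ``signed=False``,
the default) contains unsigned magnitudes in degrees, matching clinical
reporting practice; the signed representation used by the identity suite
(PI = PT + SS, LL = SS - L1S, ...) is available with ``signed=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "Point2D",
    "EndplateLine",
    "KeyPointSet",
    "SpinalParameters",
    "GeometryError",
    "signed_slope_angle",
    "signed_pelvic_tilt",
    "pelvic_tilt",
    "signed_incidence",
    "incidence_angle",
    "signed_cobb",
    "cobb_angle",
    "compute_all_parameters",
    "PARAMETER_NAMES",
]

PARAMETER_NAMES = (
    "pi", "pt", "ss", "l1i", "t1i", "c2i",
    "ll", "tk", "c27l", "l1s", "t1s", "c2s",
)


class GeometryError(ValueError):
    """Raised for degenerate landmark configurations."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class EndplateLine:
    """An endplate represented by its anterior and posterior corner points."""

    anterior: Point2D
    posterior: Point2D

    def __post_init__(self) -> None:
        if self.anterior.x == self.posterior.x and self.anterior.y == self.posterior.y:
            raise GeometryError("zero-length endplate")

    @property
    def midpoint(self) -> Point2D:
        return Point2D(
            0.5 * (self.anterior.x + self.posterior.x),
            0.5 * (self.anterior.y + self.posterior.y),
        )


#: canonical landmark-name order of the shared CSV schema
LANDMARK_NAMES = (
    "c2_inf_ant", "c2_inf_post",
    "c7_inf_ant", "c7_inf_post",
    "t1_sup_ant", "t1_sup_post",
    "l1_sup_ant", "l1_sup_post",
    "s1_sup_ant", "s1_sup_post",
    "femoral_center",
)


@dataclass(frozen=True)
class KeyPointSet:
    """The eleven measurement key points of one radiograph."""

    c2_inf: EndplateLine
    c7_inf: EndplateLine
    t1_sup: EndplateLine
    l1_sup: EndplateLine
    s1_sup: EndplateLine
    femoral_center: Point2D

    def as_dict(self) -> dict[str, Point2D]:
        """Flatten to the shared ``landmark -> point`` naming."""
        out: dict[str, Point2D] = {}
        for name in ("c2_inf", "c7_inf", "t1_sup", "l1_sup", "s1_sup"):
            line: EndplateLine = getattr(self, name)
            out[f"{name}_ant"] = line.anterior
            out[f"{name}_post"] = line.posterior
        out["femoral_center"] = self.femoral_center
        return out

    @staticmethod
    def from_dict(points: dict[str, Point2D]) -> "KeyPointSet":
        missing = [n for n in LANDMARK_NAMES if n not in points]
        if missing:
            raise GeometryError(f"missing landmarks: {', '.join(missing)}")
        lines = {
            name: EndplateLine(points[f"{name}_ant"], points[f"{name}_post"])
            for name in ("c2_inf", "c7_inf", "t1_sup", "l1_sup", "s1_sup")
        }
        return KeyPointSet(femoral_center=points["femoral_center"], **lines)


@dataclass(frozen=True)
class SpinalParameters:
    """The twelve sagittal alignment parameters, in degrees.

    pi/pt/ss: pelvic incidence, tilt, sacral slope; l1i/t1i/c2i: incidence
    angles of L1/T1/C2; ll/tk/c27l: lumbar lordosis, thoracic kyphosis and
    C2-C7 lordosis (Cobb-type); l1s/t1s/c2s: slope angles of L1/T1/C2.
    """

    pi: float
    pt: float
    ss: float
    l1i: float
    t1i: float
    c2i: float
    ll: float
    tk: float
    c27l: float
    l1s: float
    t1s: float
    c2s: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def signed_slope_angle(line: EndplateLine) -> float:
    """Signed angle in degrees between an endplate line and the horizontal.

    Positive when the posterior corner is lower (larger y) than the anterior
    one; the magnitude is the acute angle with the image row axis.  Range
    (-90, 90]; a vertical endplate maps to +90.
    """
    run = abs(line.posterior.x - line.anterior.x)
    rise = line.posterior.y - line.anterior.y
    ang = math.degrees(math.atan2(rise, run))
    if ang == -90.0:  # fold the excluded branch point onto +90
        ang = 90.0
    return ang


def _posterior_sign(sacral: EndplateLine) -> float:
    """x-direction of 'posterior' as implied by the sacral corner labels."""
    dx = sacral.posterior.x - sacral.anterior.x
    return 1.0 if dx >= 0 else -1.0


def signed_pelvic_tilt(f: Point2D, sacral: EndplateLine) -> float:
    """Signed angle between the F-to-sacral-midpoint line and the vertical.

    Positive when the sacral midpoint lies posterior to the femoral-head
    center F (posterior direction taken from the sacral corner labels).
    """
    m = sacral.midpoint
    vx = m.x - f.x
    vy = m.y - f.y
    if vx == 0.0 and vy == 0.0:
        raise GeometryError("femoral center coincides with sacral midpoint")
    return math.degrees(math.atan2(_posterior_sign(sacral) * vx, -vy))


def pelvic_tilt(f: Point2D, sacral: EndplateLine) -> float:
    """Unsigned pelvic tilt in degrees (magnitude of the signed angle)."""
    return abs(signed_pelvic_tilt(f, sacral))


def signed_incidence(f: Point2D, sacral: EndplateLine, target: EndplateLine) -> float:
    """Signed incidence angle of ``target``: signed PT + signed slope(target).

    Geometrically, the signed angle between the line from F to the sacral
    midpoint and the perpendicular to ``target``.  With ``target`` equal to
    the sacral endplate itself this is the pelvic incidence.
    """
    return signed_pelvic_tilt(f, sacral) + signed_slope_angle(target)


def incidence_angle(f: Point2D, sacral: EndplateLine, target: EndplateLine) -> float:
    """Unsigned incidence angle in degrees."""
    return abs(signed_incidence(f, sacral, target))


def signed_cobb(upper: EndplateLine, lower: EndplateLine) -> float:
    """Signed Cobb-type angle: slope(lower) - slope(upper), degrees."""
    return signed_slope_angle(lower) - signed_slope_angle(upper)


def cobb_angle(upper: EndplateLine, lower: EndplateLine) -> float:
    """Unsigned angle in [0, 90] between two endplate lines."""
    d = abs(signed_cobb(upper, lower)) % 180.0
    return min(d, 180.0 - d) if d > 90.0 else d


def compute_all_parameters(kps: KeyPointSet, *, signed: bool = False) -> SpinalParameters:
    """Compute the twelve alignment parameters from one key-point set.

    With ``signed=False`` (default) every parameter is an unsigned magnitude
    in degrees (Cobb-type angles folded to [0, 90]); with ``signed=True`` the
    internal signed representation is returned, on which the identities
    PI = PT + SS, L1I = PT + L1S, T1I = PT + T1S, C2I = PT + C2S,
    LL = SS - L1S and TK = L1S - T1S hold exactly.
    """
    slopes = {}
    for name in ("c2_inf", "c7_inf", "t1_sup", "l1_sup", "s1_sup"):
        try:
            slopes[name] = signed_slope_angle(getattr(kps, name))
        except GeometryError as exc:
            raise GeometryError(f"{name}: {exc}") from exc
    try:
        pt = signed_pelvic_tilt(kps.femoral_center, kps.s1_sup)
    except GeometryError as exc:
        raise GeometryError(f"femoral_center/s1_sup: {exc}") from exc

    ss = slopes["s1_sup"]
    l1s = slopes["l1_sup"]
    t1s = slopes["t1_sup"]
    c2s = slopes["c2_inf"]
    c7s = slopes["c7_inf"]

    values = dict(
        pi=pt + ss,
        pt=pt,
        ss=ss,
        l1i=pt + l1s,
        t1i=pt + t1s,
        c2i=pt + c2s,
        ll=ss - l1s,
        tk=l1s - t1s,
        c27l=c7s - c2s,
        l1s=l1s,
        t1s=t1s,
        c2s=c2s,
    )
    if signed:
        return SpinalParameters(**values)

    unsigned = {}
    for key, val in values.items():
        if key in ("ll", "tk", "c27l"):
            d = abs(val) % 180.0
            unsigned[key] = min(d, 180.0 - d) if d > 90.0 else d
        else:
            unsigned[key] = abs(val)
    return SpinalParameters(**unsigned)
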