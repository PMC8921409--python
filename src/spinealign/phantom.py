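"""Synthetic lateral spine radiograph phantoms with exact landmark truth.

The generator emulates the statistical structure of a whole-spine lateral
radiograph study population — a mix of good-posture, increased-lumbar-
lordosis and thoracic-kyphosis morphologies acquired in flexion, neutral and
extension postures — while keeping every landmark analytically known.
Realism is intentionally minimal: vertebral bodies are bright rotated
quadrilaterals whose corners *are* the endplate landmarks, femoral heads are
bright discs centred about the key point F, and acquisition is modelled as
Gaussian blur plus additive Gaussian noise.  The cascade therefore has to
learn localization, not radiograph physics.

Pose synthesis is exact rather than approximate: the twelve alignment
parameters are linear functions of six underlying signed angles
(PT, SS, L1S, T1S, C2S and the C7 slope), so pinned target angles are
satisfied by a least-squares projection onto the consistent subspace and
infeasible pins (e.g. PI, PT, SS fixed with PI != PT + SS) are detected from
the projection residual, not by heuristics.

The default image size is the desk-scale 810 x 270 (one quarter of the
3240 x 1080 average native resolution); all region-of-interest crop sizes in
:mod:`spinealign.pipeline` scale with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk, line, polygon

from . import io as sio
from .geometry import (EndplateLine, KeyPointSet, Point2D, SpinalParameters,
                       compute_all_parameters)

__all__ = [
    "PhantomSpec", "SpinePose", "AnnotatedImage", "InfeasibleTargets",
    "sample_spine_pose", "sample_pose", "render_phantom", "generate_phantom",
    "generate_dataset", "MORPHOLOGY_MIX", "POSTURE_MIX",
]

#: empirical class mixes of the emulated study dataset (fractions of 500)
MORPHOLOGY_MIX = {"good_posture": 283 / 500, "lumbar_lordosis": 101 / 500,
                  "thoracic_kyphosis": 116 / 500}
POSTURE_MIX = {"flexion": 150 / 500, "neutral": 200 / 500,
               "extension": 150 / 500}

AUX_NAMES = ("c1_ant", "c1_post", "c3_sup_ant", "c3_sup_post",
             "t12_inf_ant", "t12_inf_post", "l5_inf_ant", "l5_inf_post")

ROI_NAMES = ("cervical", "lumbar", "femoral",
             "c1", "c23", "c7t1", "t12l1", "l5s1")


class InfeasibleTargets(ValueError):
    """Pinned target angles violate the alignment identities."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom radiograph."""

    image_size: tuple[int, int] = (810, 270)  # (height, width) pixels
    posture: str = "neutral"                  # flexion | neutral | extension
    morphology: str = "good_posture"          # good_posture | lumbar_lordosis | thoracic_kyphosis
    target_angles: dict[str, float] | None = None  # signed degrees, partial
    noise_sigma: float = 5.0                  # grey levels
    blur_sigma: float = 1.0                   # pixels
    side: str = "left_facing"                 # left_facing | right_facing
    occlusion: bool = False                   # shoulder-girdle band over C7/T1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 64 or self.image_size[1] < 32:
            raise ValueError("image_size too small")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be >= 0")
        if self.posture not in POSTURE_MIX:
            raise ValueError(f"unknown posture {self.posture!r}")
        if self.morphology not in MORPHOLOGY_MIX:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.side not in ("left_facing", "right_facing"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass(frozen=True)
class SpinePose:
    """Sampled landmark geometry: measurement points, auxiliary points used
    only for training crops/rendering, ROI centres, and the signed angles."""

    keypoints: KeyPointSet
    aux: dict[str, Point2D]
    roi_centers: dict[str, Point2D]
    signed_angles: dict[str, float]


@dataclass
class AnnotatedImage:
    pixels: np.ndarray  # uint8 (H, W)
    landmarks: KeyPointSet
    spec: PhantomSpec
    true_parameters: SpinalParameters
    pose: SpinePose

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        for name, pt in self.landmarks.as_dict().items():
            if not (0 <= pt.x < w and 0 <= pt.y < h):
                raise ValueError(f"landmark {name} outside image bounds")


# --- target-angle solving ----------------------------------------------------

_X_NAMES = ("pt", "ss", "l1s", "t1s", "c2s", "c7s")

_PARAM_ROWS = {
    "pi":   (1, 1, 0, 0, 0, 0),
    "pt":   (1, 0, 0, 0, 0, 0),
    "ss":   (0, 1, 0, 0, 0, 0),
    "l1i":  (1, 0, 1, 0, 0, 0),
    "t1i":  (1, 0, 0, 1, 0, 0),
    "c2i":  (1, 0, 0, 0, 1, 0),
    "ll":   (0, 1, -1, 0, 0, 0),
    "tk":   (0, 0, 1, -1, 0, 0),
    "c27l": (0, 0, 0, 0, -1, 1),
    "l1s":  (0, 0, 1, 0, 0, 0),
    "t1s":  (0, 0, 0, 1, 0, 0),
    "c2s":  (0, 0, 0, 0, 1, 0),
}

#: signed sampling ranges (degrees) of the generative slope angles per
#: morphology; LL/TK/C27L follow through the alignment identities (increased
#: lumbar lordosis = steeper negative L1 slope on a steeper sacral slope;
#: thoracic kyphosis = steeper negative T1 slope).  docs/methods.md discusses
#: the choices.
_MORPH_RANGES = {
    "good_posture":      dict(pt=(8, 22), ss=(28, 45), l1s=(-12, 10),
                              t1s=(-38, -15)),
    "lumbar_lordosis":   dict(pt=(12, 28), ss=(42, 55), l1s=(-25, -8),
                              t1s=(-38, -15)),
    "thoracic_kyphosis": dict(pt=(10, 25), ss=(28, 45), l1s=(-5, 12),
                              t1s=(-55, -30)),
}


def _sample_free_angles(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    r = _MORPH_RANGES[spec.morphology]
    pt = rng.uniform(*r["pt"])
    ss = rng.uniform(*r["ss"])
    l1s = rng.uniform(*r["l1s"])
    t1s = rng.uniform(*r["t1s"])
    c7s = t1s + rng.uniform(-6, 6)
    c2s = c7s + rng.uniform(5, 20)   # cervical lordosis: C2 plate less steep
    x = np.array([pt, ss, l1s, t1s, c2s, c7s], dtype=float)
    if spec.posture != "neutral":
        sign = 1.0 if spec.posture == "flexion" else -1.0
        x[0] += sign * rng.uniform(4, 12)          # pelvic retro/anteversion
        lean = sign * rng.uniform(4, 12)           # upper spine leans forward
        x[3] -= lean
        x[4] -= lean
        x[5] -= lean
        x[2] -= sign * rng.uniform(0, 6)           # lordosis flattens in flexion
    return x


def _apply_targets(x0: np.ndarray, targets: dict[str, float]) -> np.ndarray:
    unknown = set(targets) - set(_PARAM_ROWS)
    if unknown:
        raise InfeasibleTargets(f"unknown target angles {sorted(unknown)}")
    if not targets:
        return x0
    a = np.array([_PARAM_ROWS[k] for k in targets], dtype=float)
    b = np.array([targets[k] for k in targets], dtype=float)
    x = x0 + np.linalg.pinv(a) @ (b - a @ x0)
    resid = float(np.max(np.abs(a @ x - b))) if len(b) else 0.0
    if resid > 1e-6:
        raise InfeasibleTargets(
            "pinned target angles are mutually inconsistent "
            f"(identity residual {resid:.3g} deg); e.g. PI must equal PT + SS")
    return x


# --- pose construction -------------------------------------------------------

#: vertical positions as fractions of image height
_Y_FRAC = dict(c1=0.115, c2_inf=0.135, c7_inf=0.215, t1_sup=0.235,
               l1_sup=0.615, s1_sup=0.735)
_GAP_FRAC = dict(c23=0.010, t12=0.012, l5=0.014)
#: endplate half-widths as fractions of image height
_HALF_W = dict(c1=0.010, c2_inf=0.014, c3_sup=0.014, c7_inf=0.016,
               t1_sup=0.016, t12_inf=0.018, l1_sup=0.019, l5_inf=0.018,
               s1_sup=0.021)
_FEMORAL_DROP = 0.10   # |F - sacral midpoint| as a fraction of image height


def _plate(mid: Point2D, slope_deg: float, half_w: float) -> EndplateLine:
    # canonical frame: posterior toward +x
    s = math.radians(slope_deg)
    ux, uy = math.cos(s), math.sin(s)
    return EndplateLine(
        anterior=Point2D(mid.x - half_w * ux, mid.y - half_w * uy),
        posterior=Point2D(mid.x + half_w * ux, mid.y + half_w * uy),
    )


def sample_pose(spec: PhantomSpec) -> SpinePose:
    """Sample a full spine pose (deterministic for a fixed spec/seed)."""
    rng = np.random.default_rng(spec.seed)
    x = _apply_targets(_sample_free_angles(spec, rng),
                       dict(spec.target_angles or {}))
    ang = dict(zip(_X_NAMES, x))

    h, w = spec.image_size
    cx = 0.5 * w
    jitter = rng.uniform(-0.006, 0.006, size=6) * h
    ys = {k: (f * h + j) for (k, f), j in zip(_Y_FRAC.items(), jitter)}
    # gentle sagittal-curve x offsets (cosmetic; angles do not depend on them)
    off = rng.uniform(-0.03, 0.03, size=4) * w
    xs = dict(c1=cx + off[0], c2_inf=cx + off[0], c7_inf=cx + off[1],
              t1_sup=cx + off[1], l1_sup=cx + off[2], s1_sup=cx + off[3])

    slopes = dict(c2_inf=ang["c2s"], c7_inf=ang["c7s"], t1_sup=ang["t1s"],
                  l1_sup=ang["l1s"], s1_sup=ang["ss"])
    plates = {k: _plate(Point2D(xs[k], ys[k]), slopes[k], _HALF_W[k] * h)
              for k in slopes}

    m = plates["s1_sup"].midpoint
    pt_r = math.radians(ang["pt"])
    f = Point2D(m.x - _FEMORAL_DROP * h * math.sin(pt_r),
                m.y + _FEMORAL_DROP * h * math.cos(pt_r))
    kps = KeyPointSet(femoral_center=f, **plates)

    aux_plates = {
        "c1": _plate(Point2D(xs["c1"], ys["c1"]), ang["c2s"], _HALF_W["c1"] * h),
        "c3_sup": _plate(Point2D(xs["c2_inf"], ys["c2_inf"] + _GAP_FRAC["c23"] * h),
                         ang["c2s"], _HALF_W["c3_sup"] * h),
        "t12_inf": _plate(Point2D(xs["l1_sup"], ys["l1_sup"] - _GAP_FRAC["t12"] * h),
                          ang["l1s"], _HALF_W["t12_inf"] * h),
        "l5_inf": _plate(Point2D(xs["s1_sup"], ys["s1_sup"] - _GAP_FRAC["l5"] * h),
                         ang["ss"], _HALF_W["l5_inf"] * h),
    }
    aux: dict[str, Point2D] = {}
    for name, plate in aux_plates.items():
        aux[f"{name}_ant"] = plate.anterior
        aux[f"{name}_post"] = plate.posterior

    def _mid(a: Point2D, b: Point2D) -> Point2D:
        return Point2D(0.5 * (a.x + b.x), 0.5 * (a.y + b.y))

    roi = {
        "c1": aux_plates["c1"].midpoint,
        "c23": _mid(plates["c2_inf"].midpoint, aux_plates["c3_sup"].midpoint),
        "c7t1": _mid(plates["c7_inf"].midpoint, plates["t1_sup"].midpoint),
        "t12l1": _mid(aux_plates["t12_inf"].midpoint, plates["l1_sup"].midpoint),
        "l5s1": _mid(aux_plates["l5_inf"].midpoint, plates["s1_sup"].midpoint),
        "femoral": f,
    }
    cerv_pts = [aux_plates["c1"].midpoint, plates["c2_inf"].midpoint,
                plates["c7_inf"].midpoint, plates["t1_sup"].midpoint]
    roi["cervical"] = Point2D(float(np.mean([p.x for p in cerv_pts])),
                              float(np.mean([p.y for p in cerv_pts])))
    roi["lumbar"] = _mid(roi["t12l1"], roi["l5s1"])

    pose = SpinePose(keypoints=kps, aux=aux, roi_centers=roi,
                     signed_angles=ang)
    if spec.side == "right_facing":
        pose = _mirror_pose(pose, w)
    return pose


def _mirror_point(p: Point2D, w: int) -> Point2D:
    return Point2D(w - 1 - p.x, p.y)


def _mirror_pose(pose: SpinePose, w: int) -> SpinePose:
    def mline(line: EndplateLine) -> EndplateLine:
        return EndplateLine(_mirror_point(line.anterior, w),
                            _mirror_point(line.posterior, w))
    kps = KeyPointSet(
        c2_inf=mline(pose.keypoints.c2_inf), c7_inf=mline(pose.keypoints.c7_inf),
        t1_sup=mline(pose.keypoints.t1_sup), l1_sup=mline(pose.keypoints.l1_sup),
        s1_sup=mline(pose.keypoints.s1_sup),
        femoral_center=_mirror_point(pose.keypoints.femoral_center, w),
    )
    aux = {k: _mirror_point(p, w) for k, p in pose.aux.items()}
    roi = {k: _mirror_point(p, w) for k, p in pose.roi_centers.items()}
    return SpinePose(kps, aux, roi, dict(pose.signed_angles))


def sample_spine_pose(spec: PhantomSpec) -> KeyPointSet:
    """Sample the eleven measurement key points for one phantom."""
    return sample_pose(spec).keypoints


# --- rendering ---------------------------------------------------------------

def _quad_from_plate(plate: EndplateLine, height: float, upward: bool) -> np.ndarray:
    """Body quadrilateral grown from an endplate, normal to it."""
    ux = plate.posterior.x - plate.anterior.x
    uy = plate.posterior.y - plate.anterior.y
    norm = math.hypot(ux, uy)
    nx, ny = -uy / norm, ux / norm
    if (ny > 0) == upward:  # pick the normal pointing the requested way (y down)
        nx, ny = -nx, -ny
    a, p = plate.anterior, plate.posterior
    return np.array([[a.x, a.y], [p.x, p.y],
                     [p.x + height * nx, p.y + height * ny],
                     [a.x + height * nx, a.y + height * ny]])


def _draw_quad(img: np.ndarray, quad: np.ndarray, value: float) -> None:
    rr, cc = polygon(quad[:, 1], quad[:, 0], shape=img.shape)
    img[rr, cc] = value


def _draw_spinous_process(img: np.ndarray, plate: EndplateLine,
                          height: float, upward: bool, value: float) -> None:
    """Posterior element behind a vertebral body: real vertebrae are
    posteriorly asymmetric, which is what makes the anterior/posterior corner
    identity locally recognizable on a radiograph crop."""
    a, p = plate.anterior, plate.posterior
    ux, uy = p.x - a.x, p.y - a.y
    norm = math.hypot(ux, uy)
    ux, uy = ux / norm, uy / norm          # anterior -> posterior
    nx, ny = -uy, ux
    if (ny > 0) == upward:                 # into the body (y down frame)
        nx, ny = -nx, -ny
    length = 0.9 * norm                    # protrusion beyond posterior wall
    t0, t1 = 0.30 * height, 0.75 * height  # tab spans mid-body
    quad = np.array([
        [p.x + t0 * nx, p.y + t0 * ny],
        [p.x + t0 * nx + length * ux, p.y + t0 * ny + length * uy],
        [p.x + t1 * nx + length * ux, p.y + t1 * ny + length * uy],
        [p.x + t1 * nx, p.y + t1 * ny],
    ])
    _draw_quad(img, quad, value)


def _draw_plate_line(img: np.ndarray, plate: EndplateLine, value: float) -> None:
    h, w = img.shape
    r0 = int(np.clip(round(plate.anterior.y), 0, h - 1))
    c0 = int(np.clip(round(plate.anterior.x), 0, w - 1))
    r1 = int(np.clip(round(plate.posterior.y), 0, h - 1))
    c1 = int(np.clip(round(plate.posterior.x), 0, w - 1))
    rr, cc = line(r0, c0, r1, c1)
    img[rr, cc] = value


def render_phantom(pose: SpinePose | KeyPointSet, spec: PhantomSpec) -> AnnotatedImage:
    """Render one phantom radiograph; landmark labels are exact by
    construction and independent of noise/blur."""
    if isinstance(pose, KeyPointSet):
        pose = SpinePose(pose, {}, {}, {})
    h, w = spec.image_size
    img = np.full((h, w), 25.0, dtype=np.float32)
    kps = pose.keypoints

    body = 190.0
    hgt = dict(cerv=0.016 * h, thor=0.020 * h, lumb=0.022 * h)

    def plate_of(names: str) -> EndplateLine | None:
        if hasattr(kps, names):
            return getattr(kps, names)
        a, p = pose.aux.get(f"{names}_ant"), pose.aux.get(f"{names}_post")
        return EndplateLine(a, p) if a and p else None

    # measured + auxiliary vertebral bodies
    for name, height, upward in (
        ("c2_inf", hgt["cerv"], True), ("c3_sup", hgt["cerv"], False),
        ("c7_inf", hgt["cerv"], True), ("t1_sup", hgt["thor"], False),
        ("t12_inf", hgt["thor"], True), ("l1_sup", hgt["lumb"], False),
        ("l5_inf", hgt["lumb"], True), ("s1_sup", 0.045 * h, False),
    ):
        plate = plate_of(name)
        if plate is not None:
            _draw_quad(img, _quad_from_plate(plate, height, upward),
                       body if name != "s1_sup" else 170.0)
            _draw_spinous_process(img, plate, height, upward,
                                  150.0 if name != "s1_sup" else 140.0)
    c1 = plate_of("c1")
    if c1 is not None:
        _draw_quad(img, _quad_from_plate(c1, 0.008 * h, True), body)

    # filler vertebral bodies along the interpolated curve (cosmetic)
    def _fill_between(pa: EndplateLine, pb: EndplateLine, count: int,
                      fracs: tuple[float, float], bulge: float) -> None:
        ma, mb = pa.midpoint, pb.midpoint
        sa = math.degrees(math.atan2(pa.posterior.y - pa.anterior.y,
                                     abs(pa.posterior.x - pa.anterior.x)))
        sb = math.degrees(math.atan2(pb.posterior.y - pb.anterior.y,
                                     abs(pb.posterior.x - pb.anterior.x)))
        px = 1.0 if (pa.posterior.x - pa.anterior.x) >= 0 else -1.0
        for t in np.linspace(*fracs, count):
            mid = Point2D(ma.x + t * (mb.x - ma.x)
                          + bulge * w * math.sin(math.pi * t) * px,
                          ma.y + t * (mb.y - ma.y))
            plate = _plate(mid, sa + t * (sb - sa), (0.016 + 0.003 * t) * h)
            if px < 0:
                plate = EndplateLine(
                    Point2D(2 * mid.x - plate.anterior.x, plate.anterior.y),
                    Point2D(2 * mid.x - plate.posterior.x, plate.posterior.y))
            _draw_quad(img, _quad_from_plate(plate, hgt["thor"], False), body - 15.0)
            _draw_spinous_process(img, plate, hgt["thor"], False, 150.0)

    t12 = plate_of("t12_inf")
    l5 = plate_of("l5_inf")
    if t12 is not None:
        _fill_between(kps.t1_sup, t12, 8, (0.12, 0.88), 0.015)
    if l5 is not None:
        _fill_between(kps.l1_sup, l5, 3, (0.28, 0.75), 0.004)

    # femoral heads: two near-superimposed discs, centroid at F
    f = kps.femoral_center
    r = max(3, int(round(0.020 * h)))
    for dx in (-0.006 * h, 0.006 * h):
        rr, cc = disk((f.y, f.x + dx), r, shape=img.shape)
        img[rr, cc] = 210.0

    # endplate emphasis so corners are sharp, landmark pixels exactly on them
    for name in ("c2_inf", "c7_inf", "t1_sup", "l1_sup", "s1_sup"):
        _draw_plate_line(img, getattr(kps, name), 235.0)
    for name in ("c1", "c3_sup", "t12_inf", "l5_inf"):
        plate = plate_of(name)
        if plate is not None:
            _draw_plate_line(img, plate, 215.0)

    if spec.occlusion:
        y0 = int(max(0, kps.t1_sup.midpoint.y - 0.05 * h))
        y1 = int(min(h, kps.t1_sup.midpoint.y + 0.03 * h))
        img[y0:y1] *= 0.55

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed + 0x9E3779B9) % (2 ** 31))
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    return AnnotatedImage(pixels=pixels, landmarks=kps, spec=spec,
                          true_parameters=compute_all_parameters(kps),
                          pose=pose)


def generate_phantom(spec: PhantomSpec) -> AnnotatedImage:
    return render_phantom(sample_pose(spec), spec)


# --- dataset generation ------------------------------------------------------

def _apportion(n: int, props: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among classes."""
    total = sum(props.values())
    quotas = {k: n * v / total for k, v in props.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(props, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    posture_mix: dict[str, float] | None = None,
    *,
    seed: int = 0,
    image_size: tuple[int, int] = (810, 270),
    noise_sigma: float = 5.0,
    blur_sigma: float = 1.0,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> tuple[list[AnnotatedImage], list[dict]]:
    """Generate a stratified phantom dataset plus its manifest.

    Class mixes default to the emulated study proportions (morphology
    283/101/116 and posture 150/200/150 out of 500); counts are assigned by
    largest-remainder apportionment, so at n = 500 the default strata counts
    are met exactly.  Returns (images, manifest); with ``out_dir`` also
    writes PNGs, the landmark CSV and a YAML manifest.
    """
    class_mix = dict(class_mix or MORPHOLOGY_MIX)
    posture_mix = dict(posture_mix or POSTURE_MIX)
    if n < 1:
        raise ValueError("n must be >= 1")
    n_strata = (sum(1 for v in class_mix.values() if v > 0)
                * sum(1 for v in posture_mix.values() if v > 0))
    if n < n_strata:
        raise ValueError(f"n = {n} is smaller than the {n_strata} requested strata")

    rng = np.random.default_rng(seed)
    morph_list = [k for k, c in _apportion(n, class_mix).items() for _ in range(c)]
    post_list = [k for k, c in _apportion(n, posture_mix).items() for _ in range(c)]
    rng.shuffle(post_list)  # cross the two stratifications
    sides = rng.choice(["left_facing", "right_facing"], size=n)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    images: list[AnnotatedImage] = []
    manifest: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    landmark_cases: dict[str, KeyPointSet] = {}

    for i in range(n):
        spec = PhantomSpec(image_size=image_size, posture=post_list[i],
                           morphology=morph_list[i], side=str(sides[i]),
                           noise_sigma=noise_sigma, blur_sigma=blur_sigma,
                           seed=int(seeds[i]))
        case_id = f"phantom_{i:04d}"
        if render:
            ann = generate_phantom(spec)
        else:
            pose = sample_pose(spec)
            ann = AnnotatedImage(
                pixels=np.zeros(image_size, dtype=np.uint8),
                landmarks=pose.keypoints, spec=spec,
                true_parameters=compute_all_parameters(pose.keypoints),
                pose=pose)
        images.append(ann)
        entry = {"case_id": case_id, "morphology": spec.morphology,
                 "posture": spec.posture, "side": spec.side,
                 "seed": spec.seed,
                 "image_size": list(image_size),
                 **{k: round(v, 3)
                    for k, v in ann.true_parameters.as_dict().items()}}
        if out_path is not None and render:
            fname = f"{case_id}.png"
            sio.write_image(out_path / fname, ann.pixels)
            entry["image"] = fname
        manifest.append(entry)
        landmark_cases[case_id] = ann.landmarks

    if out_path is not None:
        sio.write_landmark_csv(out_path / "landmarks.csv", landmark_cases)
        sio.write_manifest(out_path / "manifest.yaml", manifest)
    return images, manifest
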