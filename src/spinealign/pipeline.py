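"""End-to-end cascade inference: radiograph in, 12 parameters out.

The cascade works coarse-to-fine in three detecting orders.  The first-order
models read the (downsampled) whole radiograph and regress the centres of
three regions of interest — cervical spine, lumbar spine, femoral heads.
The second-order models read fixed-size crops of the cervical and lumbar
regions and regress minor-ROI centres (C1, C2-C3 disc, C7-T1 disc; T12-L1
disc, L5-S1 disc); the femoral branch passes straight from first to third
order since the published second-order heads cover only the cervical (6
outputs) and lumbar (4 outputs) sections.  The third-order models read small
crops centred on each minor ROI and regress the key-point coordinates, which
are mapped back to native pixels through the composed ROI transforms and
converted to the twelve alignment parameters by the geometry module.

Every stage regresses ROI *centres* with fixed crop sizes (no box
regression).  Predictions falling outside their crop are clipped to it and
flagged in the result provenance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import resize as sk_resize

from . import io as sio
from .geometry import KeyPointSet, Point2D, SpinalParameters, compute_all_parameters
from .models import (NetworkModel, OUTPUT_UNITS, RoiTransform, build_model,
                     crop_with_transform, map_to_global, map_to_local,
                     resize_transform, scaled_arch)
from .phantom import AnnotatedImage, SpinePose
from .training import TrainingConfig, TrainingSample, standardize, train_model

__all__ = [
    "ScaleProfile", "CascadeBundle", "MeasurementResult", "CascadeError",
    "NetworkPredictor", "OraclePredictor", "oracle_bundle",
    "run_cascade", "measure_image", "measure_batch",
    "build_training_sets", "train_cascade", "MODEL_POINTS", "PAIR_SLOTS",
]


class CascadeError(RuntimeError):
    """Raised when a cascade stage cannot run on an image."""


#: ordered point names each model regresses (in its input frame)
MODEL_POINTS: dict[str, tuple[str, ...]] = {
    "first_cervical": ("cervical",),
    "first_lumbar": ("lumbar",),
    "first_femoral": ("femoral",),
    "second_cervical": ("c1", "c23", "c7t1"),
    "second_lumbar": ("t12l1", "l5s1"),
    "third_c1": ("c1_ant", "c1_post"),
    "third_c2": ("c2_inf_ant", "c2_inf_post", "c3_sup_ant", "c3_sup_post"),
    "third_t1": ("c7_inf_ant", "c7_inf_post", "t1_sup_ant", "t1_sup_post"),
    "third_l1": ("l1_sup_ant", "l1_sup_post"),
    "third_s1": ("l5_inf_ant", "l5_inf_post", "s1_sup_ant", "s1_sup_post"),
    "third_femoral": ("femoral_center",),
}

#: anterior/posterior point-index pairs to swap under horizontal flips
PAIR_SLOTS: dict[str, tuple[tuple[int, int], ...]] = {
    "third_c1": ((0, 1),), "third_c2": ((0, 1), (2, 3)),
    "third_t1": ((0, 1), (2, 3)), "third_l1": ((0, 1),),
    "third_s1": ((0, 1), (2, 3)),
}

_ORDER_OF = {name: name.split("_")[0] + "_order" for name in MODEL_POINTS}


@dataclass(frozen=True)
class ScaleProfile:
    """Geometry of one cascade configuration: image size, first-order input
    size and the fixed crop sizes of the later orders."""

    image_size: tuple[int, int] = (810, 270)
    first_input: tuple[int, int] = (162, 54)
    second_crop: tuple[int, int] = (155, 79)
    third_crop: tuple[int, int] = (42, 42)
    # the femoral branch skips the second order, so its minor-ROI window is
    # larger and its training jitter matches first-order error directly
    femoral_crop: tuple[int, int] = (63, 63)
    second_jitter: float = 12.0  # training crop-centre jitter, px
    third_jitter: float = 6.0
    femoral_jitter: float = 10.0
    # kernel shrink factors of the desk-scale architectures, per order
    kernel_scales: tuple[float, float, float] = (0.5, 0.5, 1.0)
    # desk-scale architectures add a ReLU after every convolution
    relu_convs: bool = True

    @staticmethod
    def for_image(image_size: tuple[int, int],
                  first_downsample: int = 5) -> "ScaleProfile":
        """Derive crop sizes from an image size, scaling the native
        500x250 / 150x150 crops by image_height/3240."""
        s = image_size[0] / 3240.0
        r = lambda v: max(8, int(v * s + 0.5))
        ks = 1.0 if s >= 0.5 else 0.5
        # at reduced scale the ROI windows get a margin: the third-order
        # window so the steepest sacral endplates stay fully inside, the
        # second-order and femoral windows so upstream centre error cannot
        # push a section outside its crop
        third = r(150) if s >= 0.5 else r(150) + 4
        second = (r(500), r(250)) if s >= 0.5 else (r(500) + 30, r(250) + 16)
        femoral = (r(150), r(150)) if s >= 0.5 else (r(250), r(250))
        return ScaleProfile(
            image_size=tuple(image_size),
            first_input=(image_size[0] // first_downsample,
                         max(16, int(round(image_size[1] / first_downsample)))),
            second_crop=second,
            third_crop=(third, third),
            femoral_crop=femoral,
            second_jitter=max(1.0, 48.0 * s),
            third_jitter=max(1.0, 24.0 * s),
            femoral_jitter=max(1.0, 40.0 * s),
            kernel_scales=(ks, ks, 1.0),
            relu_convs=s < 0.5,
        )


def desk_profile() -> ScaleProfile:
    """Default desk-scale profile (quarter-native 810 x 270 phantoms)."""
    return ScaleProfile.for_image((810, 270))


class NetworkPredictor:
    """Wraps a trained model: standardize crop, forward, denormalize."""

    def __init__(self, model: NetworkModel) -> None:
        self.model = model

    def predict(self, crop: np.ndarray, transform: RoiTransform) -> list[Point2D]:
        h, w = crop.shape
        out = self.model.predict(standardize(crop)[None, ..., None])[0]
        pts = out.reshape(-1, 2)
        return [Point2D(float(x) * w, float(y) * h) for x, y in pts]


class OraclePredictor:
    """Ground-truth lookup predictor: returns known global points mapped into
    the crop frame.  Used to isolate coordinate-transform correctness from
    model error."""

    def __init__(self, points: list[Point2D]) -> None:
        self.points = points

    def predict(self, crop: np.ndarray, transform: RoiTransform) -> list[Point2D]:
        return [map_to_local(p, transform) for p in self.points]


@dataclass
class CascadeBundle:
    """All predictors of one cascade plus its scale profile."""

    first: dict[str, object]
    second: dict[str, object]
    third: dict[str, object]
    profile: ScaleProfile
    meta: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for group, preds in (("first", self.first), ("second", self.second),
                             ("third", self.third)):
            for key, pred in preds.items():
                if not isinstance(pred, NetworkPredictor):
                    raise TypeError("only network predictors are serializable")
                pred.model.save(directory / f"{group}_{key}.npz")
                names.append(f"{group}_{key}")
        with open(directory / "bundle.yaml", "w") as fh:
            yaml.safe_dump({"models": names, "meta": self.meta,
                            "profile": {k: list(v) if isinstance(v, tuple) else v
                                        for k, v in vars(self.profile).items()}},
                           fh, sort_keys=False)

    @staticmethod
    def load(directory: str | Path) -> "CascadeBundle":
        directory = Path(directory)
        with open(directory / "bundle.yaml") as fh:
            info = yaml.safe_load(fh)
        prof = {k: tuple(v) if isinstance(v, list) else v
                for k, v in info["profile"].items()}
        groups: dict[str, dict[str, object]] = {"first": {}, "second": {}, "third": {}}
        for name in info["models"]:
            group, key = name.split("_", 1)
            model = NetworkModel.load(directory / f"{name}.npz")
            groups[group][key] = NetworkPredictor(model)
        return CascadeBundle(first=groups["first"], second=groups["second"],
                             third=groups["third"],
                             profile=ScaleProfile(**prof), meta=info.get("meta", {}))


def oracle_bundle(pose: SpinePose, profile: ScaleProfile) -> CascadeBundle:
    """Bundle whose predictors look up the phantom's ground truth."""
    def points_of(name: str) -> list[Point2D]:
        lm = pose.keypoints.as_dict()
        out = []
        for pname in MODEL_POINTS[name]:
            if pname in lm:
                out.append(lm[pname])
            elif pname in pose.aux:
                out.append(pose.aux[pname])
            else:
                out.append(pose.roi_centers[pname])
        return out

    return CascadeBundle(
        first={k: OraclePredictor(points_of(f"first_{k}"))
               for k in ("cervical", "lumbar", "femoral")},
        second={k: OraclePredictor(points_of(f"second_{k}"))
                for k in ("cervical", "lumbar")},
        third={k: OraclePredictor(points_of(f"third_{k}"))
               for k in ("c2", "t1", "l1", "s1", "femoral")},
        profile=profile, meta={"oracle": True},
    )


def _clip_local(p: Point2D, size: tuple[int, int],
                warnings: list[str], tag: str) -> Point2D:
    h, w = size
    x = min(max(p.x, 0.0), w - 1.0)
    y = min(max(p.y, 0.0), h - 1.0)
    if x != p.x or y != p.y:
        warnings.append(f"{tag}: prediction clipped to crop")
    return Point2D(x, y)


def run_cascade(image: np.ndarray, bundle: CascadeBundle,
                return_provenance: bool = False):
    """Run the three-order cascade on one grayscale image.

    Returns the recovered :class:`KeyPointSet` in native pixel coordinates
    (optionally with a provenance dict recording the ROI chain and any
    clipped predictions).
    """
    if image.ndim != 2:
        raise CascadeError("expected a 2-D grayscale image")
    prof = bundle.profile
    warnings: list[str] = []
    prov: dict[str, object] = {"warnings": warnings, "roi": {}}

    resized = sk_resize(image.astype(np.float32), prof.first_input,
                        preserve_range=True, anti_aliasing=True)
    t0 = resize_transform(image.shape, prof.first_input)

    centers: dict[str, Point2D] = {}
    for region in ("cervical", "lumbar", "femoral"):
        try:
            pred = bundle.first[region]
        except KeyError:
            raise CascadeError(f"bundle missing first-order model {region!r}")
        p_local = bundle.first[region].predict(resized, t0)[0]
        p_local = _clip_local(p_local, prof.first_input, warnings,
                              f"first/{region}")
        centers[region] = map_to_global(p_local, t0)
        prov["roi"][f"first/{region}"] = (centers[region].x, centers[region].y)

    minors: dict[str, Point2D] = {"femoral": centers["femoral"]}
    second_routes = {"cervical": ("c1", "c23", "c7t1"),
                     "lumbar": ("t12l1", "l5s1")}
    for section, names in second_routes.items():
        if section not in bundle.second:
            raise CascadeError(f"bundle missing second-order model {section!r}")
        try:
            crop, t = crop_with_transform(image, centers[section],
                                          prof.second_crop)
        except ValueError as exc:
            raise CascadeError(f"second-order crop failed for {section}: {exc}")
        preds = bundle.second[section].predict(crop, t)
        for name, p_local in zip(names, preds):
            p_local = _clip_local(p_local, prof.second_crop, warnings,
                                  f"second/{name}")
            minors[name] = map_to_global(p_local, t)
            prov["roi"][f"second/{name}"] = (minors[name].x, minors[name].y)

    third_routes = {"c2": "c23", "t1": "c7t1", "l1": "t12l1",
                    "s1": "l5s1", "femoral": "femoral"}
    if "c1" in bundle.third:
        third_routes["c1"] = "c1"
    points: dict[str, Point2D] = {}
    for model_key, minor in third_routes.items():
        if model_key not in bundle.third:
            raise CascadeError(f"bundle missing third-order model {model_key!r}")
        if minor not in minors:
            # the C1 minor ROI is only predicted by the cervical second-order
            # model; when absent, skip the optional branch
            continue
        size = prof.femoral_crop if model_key == "femoral" else prof.third_crop
        predictor = bundle.third[model_key]
        try:
            crop, t = crop_with_transform(image, minors[minor], size)
        except ValueError as exc:
            raise CascadeError(f"third-order crop failed for {model_key}: {exc}")
        preds = predictor.predict(crop, t)
        offset = getattr(getattr(predictor, "model", None), "training_meta",
                         {}).get("label_centroid_offset")
        if offset is not None:
            # refinement pass: re-centre the window on the first prediction
            # (minus the mean label offset seen in training) and re-predict
            cx = float(np.mean([p.x for p in preds])) - offset[0]
            cy = float(np.mean([p.y for p in preds])) - offset[1]
            center2 = map_to_global(Point2D(cx, cy), t)
            center2 = Point2D(min(max(center2.x, 0.0), image.shape[1] - 1.0),
                              min(max(center2.y, 0.0), image.shape[0] - 1.0))
            crop, t = crop_with_transform(image, center2, size)
            preds = predictor.predict(crop, t)
            prov["roi"][f"third/{model_key}_refined"] = (center2.x, center2.y)
        for name, p_local in zip(MODEL_POINTS[f"third_{model_key}"], preds):
            p_local = _clip_local(p_local, size, warnings,
                                  f"third/{name}")
            points[name] = map_to_global(p_local, t)

    lm_names = ("c2_inf_ant", "c2_inf_post", "c7_inf_ant", "c7_inf_post",
                "t1_sup_ant", "t1_sup_post", "l1_sup_ant", "l1_sup_post",
                "s1_sup_ant", "s1_sup_post", "femoral_center")
    kps = KeyPointSet.from_dict({k: points[k] for k in lm_names})
    if return_provenance:
        prov["aux_points"] = {k: (p.x, p.y) for k, p in points.items()
                              if k not in lm_names}
        return kps, prov
    return kps


@dataclass
class MeasurementResult:
    case_id: str
    landmarks: KeyPointSet
    parameters: SpinalParameters
    provenance: dict
    elapsed: float  # seconds, informational


def measure_image(path: str | Path, bundle: CascadeBundle,
                  case_id: str | None = None) -> MeasurementResult:
    """Measure one radiograph file end to end."""
    path = Path(path)
    case_id = case_id or path.stem
    try:
        image = sio.read_image(path)
    except Exception as exc:
        raise CascadeError(f"{case_id}: unreadable image {path}: {exc}") from exc
    start = time.perf_counter()
    kps, prov = run_cascade(image, bundle, return_provenance=True)
    params = compute_all_parameters(kps)
    elapsed = time.perf_counter() - start
    prov["models"] = bundle.meta
    return MeasurementResult(case_id=case_id, landmarks=kps, parameters=params,
                             provenance=prov, elapsed=elapsed)


def measure_batch(paths: list[str | Path], bundle: CascadeBundle,
                  out_csv: str | Path | None = None,
                  landmarks_out: str | Path | None = None):
    """Measure a batch; failures are collected, never silently dropped.

    Returns (results, failures) where failures is a list of (path, message).
    """
    results: list[MeasurementResult] = []
    failures: list[tuple[str, str]] = []
    for p in paths:
        try:
            results.append(measure_image(p, bundle))
        except (CascadeError, Exception) as exc:  # noqa: BLE001 - batch contract
            failures.append((str(p), str(exc)))
    if out_csv is not None:
        sio.write_parameters_csv(out_csv, {r.case_id: r.parameters for r in results})
    if landmarks_out is not None:
        sio.write_landmark_csv(landmarks_out, {r.case_id: r.landmarks for r in results})
    return results, failures


# --- cascade training --------------------------------------------------------

def _pose_point(pose: SpinePose, name: str) -> Point2D:
    lm = pose.keypoints.as_dict()
    if name in lm:
        return lm[name]
    if name in pose.aux:
        return pose.aux[name]
    return pose.roi_centers[name]


def build_training_sets(
    phantoms: list[AnnotatedImage],
    profile: ScaleProfile,
    seed: int = 0,
    include_c1: bool = False,
    first_mult: int = 6,
    second_mult: int = 6,
    third_mult: int = 8,
) -> dict[str, list[TrainingSample]]:
    """Build per-model training crops from annotated phantoms.

    Second/third-order crops are taken at the ground-truth ROI centres with
    Gaussian centre jitter, mimicking upstream prediction error;
    ``second_mult``/``third_mult`` independent jittered crops are drawn per
    phantom, mirroring the crop multiplication the later orders rely on.
    First-order samples are multiplied by random translations plus
    horizontal flips of the downsampled whole image (``first_mult``).
    """
    rng = np.random.default_rng(seed)
    model_names = [n for n in MODEL_POINTS
                   if include_c1 or n != "third_c1"]
    sets: dict[str, list[TrainingSample]] = {n: [] for n in model_names}

    for ann in phantoms:
        image = ann.pixels.astype(np.float32)
        pose = ann.pose
        resized = sk_resize(image, profile.first_input, preserve_range=True,
                            anti_aliasing=True)
        t0 = resize_transform(image.shape, profile.first_input)
        fh, fw = profile.first_input
        shift_max = max(2, fh // 16)
        variants: list[tuple[np.ndarray, int, int, bool]] = [(resized, 0, 0, False)]
        for _ in range(max(0, first_mult - 1)):
            dy, dx = (int(rng.integers(-shift_max, shift_max + 1)),
                      int(rng.integers(-shift_max, shift_max + 1)))
            img2 = np.zeros_like(resized)
            ys0, ys1 = max(dy, 0), min(fh + dy, fh)
            xs0, xs1 = max(dx, 0), min(fw + dx, fw)
            img2[ys0:ys1, xs0:xs1] = resized[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
            variants.append((img2, dy, dx, bool(rng.integers(0, 2))))
        for region in ("cervical", "lumbar", "femoral"):
            p = map_to_local(pose.roi_centers[region], t0)
            for img2, dy, dx, flip in variants:
                x_px, y_px = p.x + dx, p.y + dy
                if flip:
                    img2 = img2[:, ::-1]
                    x_px = fw - 1 - x_px
                sets[f"first_{region}"].append(TrainingSample(
                    image=np.ascontiguousarray(img2),
                    label=np.array([x_px / fw, y_px / fh], dtype=np.float32)))

        def crop_sample(center: Point2D, size: tuple[int, int],
                        jitter: float, names: tuple[str, ...]) -> TrainingSample:
            h, w = size
            jc = Point2D(center.x + float(rng.normal(0, jitter)),
                         center.y + float(rng.normal(0, jitter)))
            jc = Point2D(min(max(jc.x, 0), image.shape[1] - 1),
                         min(max(jc.y, 0), image.shape[0] - 1))
            crop, t = crop_with_transform(image, jc, size)
            label = []
            for nm in names:
                q = map_to_local(_pose_point(pose, nm), t)
                label.extend([q.x / w, q.y / h])
            return TrainingSample(image=crop,
                                  label=np.asarray(label, dtype=np.float32))

        for section in ("cervical", "lumbar"):
            for _ in range(second_mult):
                sets[f"second_{section}"].append(crop_sample(
                    pose.roi_centers[section], profile.second_crop,
                    profile.second_jitter, MODEL_POINTS[f"second_{section}"]))

        third_minor = {"c1": "c1", "c2": "c23", "t1": "c7t1",
                       "l1": "t12l1", "s1": "l5s1", "femoral": "femoral"}
        for key, minor in third_minor.items():
            name = f"third_{key}"
            if name not in sets:
                continue
            size = profile.femoral_crop if key == "femoral" else profile.third_crop
            jit = profile.femoral_jitter if key == "femoral" else profile.third_jitter
            for m in range(third_mult):
                # alternate full and small jitter: robust to upstream error
                # yet precise on the re-centred crops of the refinement pass
                sets[name].append(crop_sample(
                    pose.roi_centers[minor], size,
                    jit if m % 2 == 0 else 0.3 * jit, MODEL_POINTS[name]))
    return sets


def train_cascade(
    phantoms: list[AnnotatedImage],
    cfg: TrainingConfig,
    profile: ScaleProfile | None = None,
    seed: int = 0,
    include_c1: bool = False,
    first_mult: int = 6,
    second_mult: int = 6,
    third_mult: int = 8,
) -> tuple[CascadeBundle, dict[str, dict[str, list[float]]]]:
    """Train every cascade model on annotated phantoms; per-order training is
    independent (inference chains the predictions)."""
    profile = profile or desk_profile()
    sets = build_training_sets(phantoms, profile, seed=seed,
                               include_c1=include_c1, first_mult=first_mult,
                               second_mult=second_mult, third_mult=third_mult)
    input_shape = {"first_order": profile.first_input,
                   "second_order": profile.second_crop,
                   "third_order": profile.third_crop}
    kscale = dict(zip(("first_order", "second_order", "third_order"),
                      profile.kernel_scales))
    groups: dict[str, dict[str, object]] = {"first": {}, "second": {}, "third": {}}
    histories: dict[str, dict[str, list[float]]] = {}
    for i, (name, samples) in enumerate(sets.items()):
        order = _ORDER_OF[name]
        shape = (profile.femoral_crop if name == "third_femoral"
                 else input_shape[order])
        arch = scaled_arch(order, shape,
                           output_units=OUTPUT_UNITS[name],
                           kernel_scale=kscale[order],
                           relu_convs=profile.relu_convs)
        model = build_model(arch, seed=seed + 101 * (i + 1))
        model, hist = train_model(model, samples, cfg)
        model.training_meta.update({"role": name, "n_samples": len(samples)})
        if name.startswith("third_"):
            h_c, w_c = samples[0].image.shape
            pts = np.stack([smp.label.reshape(-1, 2) for smp in samples])
            centroid = pts.mean(axis=(0, 1)) * [w_c, h_c]
            model.training_meta["label_centroid_offset"] = [
                float(centroid[0] - (w_c - 1) / 2.0),
                float(centroid[1] - (h_c - 1) / 2.0)]
        histories[name] = hist
        group, key = name.split("_", 1)
        groups[group][key] = NetworkPredictor(model)
    bundle = CascadeBundle(first=groups["first"], second=groups["second"],
                           third=groups["third"], profile=profile,
                           meta={"seed": seed, "epochs": cfg.epochs,
                                 "n_phantoms": len(phantoms)})
    return bundle, histories
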