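"""Cascade network architectures and ROI coordinate transforms.

The three detection orders are declared as ordered layer lists (``ArchSpec``)
whose propagated shapes reproduce, cell for cell, the published layer tables
of the first-, second- and third-order models:

* first order  — whole-image input 1620x540, regresses one ROI center,
  hidden FC widths 256/128;
* second order — 500x250 ROI input, regresses the minor-ROI centers
  (cervical: 3 centers / 6 outputs, lumbar: 2 centers / 4 outputs),
  hidden FC widths 256/90;
* third order  — 150x150 minor-ROI input, regresses the key-point
  coordinates themselves (C1 and L1 regions: 4 outputs, C2/T1/S1 regions: 8,
  femoral heads: 2), hidden FC widths 256/90.

Convolutions are valid (no padding), pooling is non-overlapping with floor
division — with one exception: the published second-order table rounds its
first pooling width up (242/3 -> 81) while every other pooling cell in all
three tables rounds down, so that single layer carries ``ceil=True``.

The same layer patterns can be re-fitted to smaller inputs for desk-scale
phantoms (``scaled_arch``): kernels are clipped and pooling skipped where a
feature-map axis would otherwise collapse, so every order keeps its five
convolution stages at any sensible input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .geometry import Point2D

__all__ = [
    "LayerSpec", "ArchSpec", "ArchError", "NetworkModel", "RoiTransform",
    "first_order_arch", "second_order_arch", "third_order_arch",
    "scaled_arch", "propagate_shapes", "shape_table", "build_model",
    "crop_with_transform", "map_to_global", "map_to_local", "compose",
    "resize_transform", "OUTPUT_UNITS",
]

#: printed output dimensionality of every model role in the cascade
OUTPUT_UNITS = {
    "first_cervical": 2, "first_lumbar": 2, "first_femoral": 2,
    "second_cervical": 6, "second_lumbar": 4,
    "third_c1": 4, "third_c2": 8, "third_t1": 8,
    "third_l1": 4, "third_s1": 8, "third_femoral": 2,
}

NATIVE_INPUTS = {"first_order": (1620, 540), "second_order": (500, 250),
                 "third_order": (150, 150)}


class ArchError(ValueError):
    """Raised when an architecture cannot propagate a valid shape."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | maxpool | dropout | relu | fully_connected
    filters: int = 0
    kernel: tuple[int, int] = (1, 1)
    pool: tuple[int, int] = (1, 1)
    units: int = 0
    rate: float = 0.5
    ceil: bool = False


def _conv(filters: int, k: int | tuple[int, int]) -> LayerSpec:
    kk = (k, k) if isinstance(k, int) else k
    return LayerSpec("conv", filters=filters, kernel=kk)


def _pool(p: int | tuple[int, int], ceil: bool = False) -> LayerSpec:
    pp = (p, p) if isinstance(p, int) else p
    return LayerSpec("maxpool", pool=pp, ceil=ceil)


def _fc(units: int) -> LayerSpec:
    return LayerSpec("fully_connected", units=units)


@dataclass(frozen=True)
class ArchSpec:
    name: str
    input_shape: tuple[int, int, int]  # (h, w, channels)
    layers: tuple[LayerSpec, ...]
    output_units: int

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "input_shape": list(self.input_shape),
            "output_units": self.output_units,
            "layers": [vars(l) | {"kernel": list(l.kernel), "pool": list(l.pool)}
                       for l in self.layers],
        })

    @staticmethod
    def from_json(text: str) -> "ArchSpec":
        d = json.loads(text)
        layers = tuple(
            LayerSpec(kind=l["kind"], filters=l["filters"],
                      kernel=tuple(l["kernel"]), pool=tuple(l["pool"]),
                      units=l["units"], rate=l["rate"], ceil=l["ceil"])
            for l in d["layers"]
        )
        return ArchSpec(d["name"], tuple(d["input_shape"]), layers,
                        d["output_units"])


# --- published architectures -------------------------------------------------

def first_order_arch(input_shape: tuple[int, int] | None = None) -> ArchSpec:
    """Whole-image ROI-center detector (one instance per region)."""
    h, w = input_shape or NATIVE_INPUTS["first_order"]
    layers = (
        _conv(8, 9), _pool(4), _conv(16, 7), _pool(3), _conv(16, 7), _pool(2),
        _conv(32, 5), _pool(2), _conv(32, 3),
        LayerSpec("dropout", rate=0.5), LayerSpec("relu"),
        _fc(256), _fc(128),
    )
    return ArchSpec("first_order", (h, w, 1), layers, 2)


def second_order_arch(output_units: int = 6,
                      input_shape: tuple[int, int] | None = None) -> ArchSpec:
    """Minor-ROI-center detector for the cervical (6) / lumbar (4) sections.

    The first pooling layer uses ceiling division, as its published output
    width (81 from 242/3) requires; all other pools round down.
    """
    h, w = input_shape or NATIVE_INPUTS["second_order"]
    layers = (
        _conv(8, 9), _pool(3, ceil=True), _conv(16, 7), _pool(2),
        _conv(16, 7), _pool(2), _conv(32, 5), _pool(2), _conv(32, 3),
        LayerSpec("dropout", rate=0.5), LayerSpec("relu"),
        _fc(256), _fc(90),
    )
    return ArchSpec("second_order", (h, w, 1), layers, output_units)


def third_order_arch(output_units: int = 8,
                     input_shape: tuple[int, int] | None = None) -> ArchSpec:
    """Key-point detector for one minor ROI (C1/L1: 4, C2/T1/S1: 8, femur: 2)."""
    h, w = input_shape or NATIVE_INPUTS["third_order"]
    layers = (
        _conv(8, 9), _pool(2), _conv(8, 7), _pool(2), _conv(16, 5), _pool(2),
        _conv(16, 3), _pool(2), _conv(32, 1),
        LayerSpec("dropout", rate=0.5), LayerSpec("relu"),
        _fc(256), _fc(90),
    )
    return ArchSpec("third_order", (h, w, 1), layers, output_units)


def scaled_arch(order: str, input_shape: tuple[int, int],
                output_units: int | None = None,
                kernel_scale: float = 1.0,
                relu_convs: bool = False) -> ArchSpec:
    """Refit an order's layer pattern to a (smaller) input shape.

    ``kernel_scale`` shrinks kernels proportionally (rounded to odd sizes),
    kernels are clipped so each convolution keeps at least a few output
    cells, and a pooling axis is skipped once the running feature map is too
    small to divide further.  ``relu_convs`` inserts a ReLU after every
    convolution (the desk-scale profile uses this; at reduced resolution the
    purely linear feature stack underfits the localization task).  At the
    native input size with kernel_scale 1 and relu_convs False this
    reproduces the published architecture unchanged.
    """
    if order == "first_order":
        base = first_order_arch()
    elif order == "second_order":
        base = second_order_arch(output_units or 6)
    elif order == "third_order":
        base = third_order_arch(output_units or 8)
    else:
        raise ArchError(f"unknown order {order!r}")
    if output_units is not None:
        base = replace(base, output_units=output_units)

    def _odd(k: int) -> int:
        k2 = max(1, int(round(k * kernel_scale)))
        return k2 + 1 if k2 % 2 == 0 else k2

    h, w = input_shape
    layers: list[LayerSpec] = []
    for spec in base.layers:
        if spec.kind == "conv":
            k0, k1 = _odd(spec.kernel[0]), _odd(spec.kernel[1])
            kh = k0 if h >= k0 + 4 else max(1, min(k0, h - 2))
            kw = k1 if w >= k1 + 4 else max(1, min(k1, w - 2))
            spec = replace(spec, kernel=(kh, kw))
            h, w = h - kh + 1, w - kw + 1
            if h < 1 or w < 1:
                raise ArchError(f"input {input_shape} too small for {order}")
            layers.append(spec)
            if relu_convs:
                layers.append(LayerSpec("relu"))
            continue
        elif spec.kind == "maxpool":
            ph = spec.pool[0] if h // spec.pool[0] >= 6 else 1
            pw = spec.pool[1] if w // spec.pool[1] >= 6 else 1
            if (ph, pw) == (1, 1):
                continue
            spec = replace(spec, pool=(ph, pw))
            if spec.ceil:
                h, w = -(-h // ph), -(-w // pw)
            else:
                h, w = h // ph, w // pw
        layers.append(spec)
    return ArchSpec(base.name, (input_shape[0], input_shape[1], 1),
                    tuple(layers), base.output_units)


# --- shape propagation -------------------------------------------------------

def propagate_shapes(arch: ArchSpec) -> list[tuple[int, ...]]:
    """Shapes after each layer; convs use the valid rule h' = h - k + 1,
    pooling divides (floor, or ceiling where flagged), FC layers flatten."""
    h, w, c = arch.input_shape
    shapes: list[tuple[int, ...]] = []
    flat: int | None = None
    for i, spec in enumerate(arch.layers):
        if spec.kind == "conv":
            h, w = h - spec.kernel[0] + 1, w - spec.kernel[1] + 1
            c = spec.filters
            if h < 1 or w < 1:
                raise ArchError(f"layer {i} ({spec.kind}) yields non-positive "
                                f"dimension ({h}, {w})")
            shapes.append((h, w, c))
        elif spec.kind == "maxpool":
            ph, pw = spec.pool
            if spec.ceil:
                h, w = -(-h // ph), -(-w // pw)
            else:
                h, w = h // ph, w // pw
            if h < 1 or w < 1:
                raise ArchError(f"layer {i} ({spec.kind}) yields non-positive "
                                f"dimension ({h}, {w})")
            shapes.append((h, w, c))
        elif spec.kind in ("dropout", "relu"):
            shapes.append((h, w, c) if flat is None else (flat,))
        elif spec.kind == "fully_connected":
            flat = spec.units
            shapes.append((flat,))
        else:
            raise ArchError(f"unknown layer kind {spec.kind!r}")
    shapes.append((arch.output_units,))
    return shapes


def shape_table(arch: ArchSpec) -> str:
    """Human-readable propagated-shape table (for diffing against print)."""
    rows = [f"{arch.name}  input {arch.input_shape}"]
    names = []
    counts = {"conv": 0, "maxpool": 0, "fully_connected": 0}
    for spec in arch.layers:
        if spec.kind in counts:
            counts[spec.kind] += 1
            label = {"conv": "Conv", "maxpool": "Max-pooling",
                     "fully_connected": "Fully connected"}[spec.kind]
            names.append(f"{label} {counts[spec.kind]}")
        else:
            names.append(spec.kind.capitalize())
    for name, shp in zip(names + ["Output"], propagate_shapes(arch)):
        rows.append(f"  {name:<18} {shp}")
    return "\n".join(rows)


# --- model construction ------------------------------------------------------

@dataclass
class NetworkModel:
    """A built network plus its architecture and training metadata."""

    arch: ArchSpec
    net: nn.Network
    training_meta: dict = field(default_factory=dict)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.net.forward(batch, train=False)

    def save(self, path: str | Path) -> None:
        np.savez(path, __arch__=np.frombuffer(self.arch.to_json().encode(), dtype=np.uint8),
                 __meta__=np.frombuffer(json.dumps(self.training_meta).encode(), dtype=np.uint8),
                 **self.net.state_arrays())

    @staticmethod
    def load(path: str | Path) -> "NetworkModel":
        with np.load(path) as data:
            arch = ArchSpec.from_json(bytes(data["__arch__"]).decode())
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = build_model(arch, arch.output_units, seed=0)
            model.net.load_state_arrays({k: data[k] for k in data.files
                                         if not k.startswith("__")})
        model.training_meta = meta
        return model


def build_model(arch: ArchSpec, output_units: int | None = None,
                seed: int = 0) -> NetworkModel:
    """Instantiate the network for an ArchSpec with seeded initialization."""
    output_units = arch.output_units if output_units is None else output_units
    if output_units <= 0:
        raise ArchError("output_units must be positive")
    if output_units != arch.output_units:
        arch = replace(arch, output_units=output_units)
    rng = np.random.default_rng(seed)
    h, w, c = arch.input_shape
    layers: list[nn.Layer] = []
    flat: int | None = None
    for i, spec in enumerate(arch.layers):
        if spec.kind == "conv":
            nxt = arch.layers[i + 1] if i + 1 < len(arch.layers) else None
            gain = np.sqrt(2.0) if (nxt is not None and nxt.kind == "relu") else 1.0
            layers.append(nn.Conv2D(c, spec.filters, spec.kernel, rng, gain=gain))
            h, w, c = h - spec.kernel[0] + 1, w - spec.kernel[1] + 1, spec.filters
        elif spec.kind == "maxpool":
            layer = nn.MaxPool2D(spec.pool, ceil=spec.ceil)
            h, w = layer.out_hw(h, w)
            layers.append(layer)
        elif spec.kind == "dropout":
            layers.append(nn.Dropout(spec.rate, rng))
        elif spec.kind == "relu":
            layers.append(nn.ReLU())
        elif spec.kind == "fully_connected":
            if flat is None:
                layers.append(nn.Flatten())
                flat = h * w * c
            layers.append(nn.Dense(flat, spec.units, rng))
            flat = spec.units
    if layers and isinstance(layers[0], nn.Conv2D):
        layers[0].input_layer = True  # its input gradient is never consumed
    if flat is None:
        layers.append(nn.Flatten())
        flat = h * w * c
    head = nn.Dense(flat, output_units, rng)
    head.params["w"][:] = 0.0  # start at the bias (label-mean regime)
    layers.append(head)
    return NetworkModel(arch=arch, net=nn.Network(layers),
                        training_meta={"seed": seed, "epochs_completed": 0})


# --- ROI crops and coordinate transforms ------------------------------------

@dataclass(frozen=True)
class RoiTransform:
    """Affine map between a crop's local frame and global pixel coordinates.

    ``local = (global - origin) * scale``; ``scale`` is (sx, sy) applied
    before the crop (1, 1 for a plain crop, h_resized/h_native for resizing).
    """

    origin: Point2D
    scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError("scale must be positive")


def map_to_global(p_local: Point2D, t: RoiTransform) -> Point2D:
    return Point2D(t.origin.x + p_local.x / t.scale[0],
                   t.origin.y + p_local.y / t.scale[1])


def map_to_local(p_global: Point2D, t: RoiTransform) -> Point2D:
    return Point2D((p_global.x - t.origin.x) * t.scale[0],
                   (p_global.y - t.origin.y) * t.scale[1])


def compose(outer: RoiTransform, inner: RoiTransform) -> RoiTransform:
    """Transform equivalent to applying ``inner`` within ``outer``'s frame."""
    ox = outer.origin.x + inner.origin.x / outer.scale[0]
    oy = outer.origin.y + inner.origin.y / outer.scale[1]
    return RoiTransform(Point2D(ox, oy),
                        (outer.scale[0] * inner.scale[0],
                         outer.scale[1] * inner.scale[1]))


def resize_transform(native_hw: tuple[int, int],
                     resized_hw: tuple[int, int]) -> RoiTransform:
    return RoiTransform(Point2D(0.0, 0.0),
                        (resized_hw[1] / native_hw[1], resized_hw[0] / native_hw[0]))


def crop_with_transform(image: np.ndarray, center: Point2D,
                        size: tuple[int, int]) -> tuple[np.ndarray, RoiTransform]:
    """Fixed-size crop centered on ``center`` with zero padding at borders.

    Returns the crop and the transform mapping crop-local coordinates back to
    the global pixel frame.  ``size`` is (height, width).
    """
    h, w = size
    if h < 1 or w < 1:
        raise ValueError("crop size must be positive")
    ih, iw = image.shape[:2]
    cx, cy = int(round(center.x)), int(round(center.y))
    if not (0 <= cx < iw and 0 <= cy < ih):
        raise ValueError(f"crop center ({center.x}, {center.y}) outside "
                         f"image of shape ({ih}, {iw})")
    ox, oy = cx - w // 2, cy - h // 2
    crop = np.zeros((h, w), dtype=image.dtype)
    y0, y1 = max(oy, 0), min(oy + h, ih)
    x0, x1 = max(ox, 0), min(ox + w, iw)
    crop[y0 - oy: y1 - oy, x0 - ox: x1 - ox] = image[y0:y1, x0:x1]
    return crop, RoiTransform(Point2D(float(ox), float(oy)))
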