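"""CSV / YAML / image I/O for the shared file schemas.

Landmark CSV: columns ``case_id, landmark, x, y`` with eleven landmark names
per case (the five endplate corner pairs plus ``femoral_center``),
coordinates in native image pixels, 0-based.

Parameters CSV: columns ``case_id, pi, pt, ss, l1i, t1i, c2i, ll, tk, c27l,
l1s, t1s, c2s`` in degrees, written with 3 decimals.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import (LANDMARK_NAMES, PARAMETER_NAMES, KeyPointSet, Point2D,
                       SpinalParameters)

__all__ = [
    "write_landmark_csv", "read_landmark_csv",
    "write_parameters_csv", "read_parameters_csv",
    "write_manifest", "read_manifest", "read_image", "write_image",
]


def write_landmark_csv(path: str | Path,
                       cases: dict[str, KeyPointSet]) -> None:
    rows = []
    for case_id, kps in cases.items():
        for name, pt in kps.as_dict().items():
            rows.append({"case_id": case_id, "landmark": name,
                         "x": pt.x, "y": pt.y})
    pd.DataFrame(rows, columns=["case_id", "landmark", "x", "y"]).to_csv(
        path, index=False, float_format="%.17g")  # bit-exact round trip


def read_landmark_csv(path: str | Path) -> dict[str, KeyPointSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, KeyPointSet] = {}
    for case_id, grp in df.groupby("case_id", sort=False):
        points = {r.landmark: Point2D(float(r.x), float(r.y))
                  for r in grp.itertuples()}
        unknown = set(points) - set(LANDMARK_NAMES)
        if unknown:
            raise ValueError(f"{case_id}: unknown landmarks {sorted(unknown)}")
        out[str(case_id)] = KeyPointSet.from_dict(points)
    return out


def write_parameters_csv(path: str | Path,
                         cases: dict[str, SpinalParameters]) -> None:
    rows = [{"case_id": cid, **{k: round(v, 3) for k, v in p.as_dict().items()}}
            for cid, p in cases.items()]
    pd.DataFrame(rows, columns=["case_id", *PARAMETER_NAMES]).to_csv(
        path, index=False)


def read_parameters_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PARAMETER_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"parameters CSV missing columns {sorted(missing)}")
    return df


def write_manifest(path: str | Path, manifest: list[dict]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF); RGB inputs are averaged."""
    img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(np.float32)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    iio.imwrite(path, pixels)
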