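"""Reading and writing images, masks and contours."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .segmentation import Contour

__all__ = [
    "read_image",
    "write_mask",
    "write_contour_csv",
    "read_contour_csv",
    "write_contour_json",
    "write_overlay",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float64; RGB input is averaged."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float64)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * np.uint8(255))


def write_contour_csv(contour: Contour | np.ndarray, path: str | Path) -> None:
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour)
    df = pd.DataFrame(
        {"index": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1]}
    )
    df.to_csv(path, index=False)


def read_contour_csv(path: str | Path) -> Contour:
    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(dtype=np.int64)
    return Contour(points=pts, closed=True)


def write_contour_json(contour: Contour, path: str | Path) -> None:
    """GeoJSON-style LineString of the closed contour."""
    pts = np.asarray(contour.points)
    ring = pts.tolist() + [pts[0].tolist()]
    obj = {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": ring},
        "properties": {"closed": bool(contour.closed), "n_pixels": int(len(pts))},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_overlay(
    image: np.ndarray,
    contour: Contour | None,
    path: str | Path,
    half_arc: np.ndarray | None = None,
) -> None:
    """Write the image as RGB PNG with the contour in red and, optionally,
    the upper half arc in green."""
    img8 = np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.uint8)
    rgb = np.stack([img8] * 3, axis=-1)
    if contour is not None:
        pts = np.asarray(contour.points)
        rgb[pts[:, 1], pts[:, 0]] = (255, 0, 0)
    if half_arc is not None:
        arc = np.asarray(half_arc)
        rgb[arc[:, 1], arc[:, 0]] = (0, 255, 0)
    iio.imwrite(Path(path), rgb)
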