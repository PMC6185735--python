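"""Image and ROI readers/writers.

Images are the package's universal currency: 2-D float arrays with
intensities nominally in [0, 255].  Files are 8-bit grayscale PNG/TIFF;
RGB inputs are collapsed by luminance and 16-bit inputs rescaled to the
8-bit range, both with a logged warning.  ROI lists travel as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .metrics import ROI

__all__ = ["read_image", "write_image", "read_rois", "write_rois"]

logger = logging.getLogger("pcanlm")

_LUMA = np.array([0.2125, 0.7154, 0.0721])


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as a float array in [0, 255]."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        if arr.shape[-1] != 3:
            raise IOError(f"unsupported channel count {arr.shape[-1]} in {path}")
        logger.warning("%s: RGB input converted to grayscale by luminance", path)
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input rescaled to [0, 255]", path)
        return arr.astype(np.float64) * (255.0 / 65535.0)
    if arr.dtype.kind not in "fiu":
        raise IOError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return arr.astype(np.float64)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit grayscale (rounded, clipped to [0, 255])."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def read_rois(path: str | Path) -> list[ROI]:
    """Load a JSON list of {top, left, height, width, role, label} ROIs."""
    path = Path(path)
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise IOError(f"{path}: expected a JSON list of ROIs")
    rois = []
    for e in entries:
        rois.append(
            ROI(
                top=int(e["top"]),
                left=int(e["left"]),
                height=int(e["height"]),
                width=int(e["width"]),
                role=e.get("role", "background"),
                label=e.get("label", ""),
            )
        )
    return rois


def write_rois(rois: list[ROI], path: str | Path) -> None:
    entries = [
        {
            "top": r.top,
            "left": r.left,
            "height": r.height,
            "width": r.width,
            "role": r.role,
            "label": r.label,
        }
        for r in rois
    ]
    with open(Path(path), "w") as fh:
        json.dump(entries, fh, indent=2)
        fh.write("\n")
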