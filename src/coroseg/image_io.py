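"""Image and result I/O.

All images are handled in-memory as 2D float64 arrays on a nominal
[0, 255] scale, coordinates are x = column, y = row, 0-based, with pixel
centers at integer coordinates.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_skeleton",
    "read_skeleton",
    "write_skeleton_csv",
    "validate_image",
]

#: RGB -> luminance weights (ITU-R BT.601)
_LUMA = np.array([0.2989, 0.5870, 0.1140])


def validate_image(img: np.ndarray, min_size: int = 16) -> np.ndarray:
    """Check a 2D intensity image: finite values, minimum size."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(f"image must be at least {min_size}x{min_size}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale (or RGB, collapsed by luminance) PNG/TIFF.

    Values are returned as float64 on [0, 255]: images already within that
    range are passed through unchanged; wider dynamic range is min-max
    rescaled to [0, 255]; a constant out-of-range image maps to 127.5.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-size image: {path}")
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout {raw.shape} in {path}")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 255.0:
        if hi == lo:
            arr = np.full_like(arr, 127.5)
        else:
            arr = (arr - lo) * (255.0 / (hi - lo))
    return validate_image(arr, min_size=1)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an intensity image as 8-bit PNG (values clipped to [0, 255])."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0, 1} binary mask as an 8-bit {0, 255} PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG back to a {0, 1} uint8 array."""
    arr = read_image(path)
    return (arr > 127.5).astype(np.uint8)


def _skeleton_payload(skel) -> dict:
    if not skel.branches or all(len(b) == 0 for b in skel.branches):
        raise ValueError("cannot serialise an empty skeleton")
    return {
        "branches": [
            [
                {"x": float(pt.x), "y": float(pt.y), "adjusted": bool(pt.adjusted)}
                for pt in branch
            ]
            for branch in skel.branches
        ],
        "bifurcations": [
            {"x": float(b[0]), "y": float(b[1])} for b in skel.bifurcations
        ],
        "seed": {"x": float(skel.seed[0]), "y": float(skel.seed[1])},
    }


def write_skeleton(skel, path: str | Path) -> None:
    """Write a tracked skeleton as JSON (sub-pixel x/y, 0-based)."""
    payload = _skeleton_payload(skel)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_skeleton(path: str | Path) -> dict:
    """Parse a skeleton JSON document back to its dict form."""
    with open(path) as fh:
        return json.load(fh)


def write_skeleton_csv(skel, path: str | Path) -> None:
    """CSV alternative: columns branch_id, order, x, y, is_bifurcation."""
    payload = _skeleton_payload(skel)
    bifs = [(b["x"], b["y"]) for b in payload["bifurcations"]]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["branch_id", "order", "x", "y", "is_bifurcation"])
        for bid, branch in enumerate(payload["branches"]):
            for order, pt in enumerate(branch):
                is_bif = any(
                    abs(pt["x"] - bx) < 1e-9 and abs(pt["y"] - by) < 1e-9
                    for bx, by in bifs
                )
                writer.writerow(
                    [bid, order, f"{pt['x']:.6f}", f"{pt['y']:.6f}", int(is_bif)]
                )
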