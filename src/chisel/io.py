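"""Readers and writers for images, label masks and point-marker tables.

Conventions
-----------
* Images are ``uint8`` arrays of shape ``(H, W, 3)`` in R,G,B order.
* Label masks are non-negative integer arrays; 0 is background.  They are
  written as 16-bit grayscale PNG where the pixel value is the label id.
* Marker tables are CSV files with header ``x,y[,class]``; ``x`` is the
  0-based column and ``y`` the 0-based row, matching common annotation
  tools.  The in-memory form is a :class:`pandas.DataFrame` with columns
  ``x`` (int), ``y`` (int) and ``class`` (one of ``positive``, ``negative``,
  ``unspecified``).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("chisel")

MARKER_CLASSES = ("positive", "negative", "unspecified")


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit RGB array.

    Grayscale inputs are replicated to three channels (with a warning);
    an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various decoder errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) > 255:
            arr = (arr.astype(np.float64) / arr.max() * 255).round()
        arr = arr.astype(np.uint8)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale input replicated to 3 channels")
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise FormatError(f"{path}: unsupported image shape {arr.shape}")
    return np.ascontiguousarray(arr)


def write_rgb_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit PNG (pixel value = label id)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("label ids must fit in uint16")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-channel")
    return arr.astype(np.int32)


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read a point-marker CSV with header ``x,y[,class]``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected header x,y[,class]") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: expected columns x,y[,class], got {cols}")
    if "class" not in cols:
        df["class"] = "unspecified"
    df = df[["x", "y", "class"]].copy()
    if len(df):
        for c in ("x", "y"):
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"{path}: non-numeric {c} coordinate")
            if (vals < 0).any():
                raise ValidationError(f"{path}: negative {c} coordinate")
            df[c] = vals.astype(int)
        df["class"] = df["class"].astype(str).str.strip().str.lower()
        bad = ~df["class"].isin(MARKER_CLASSES)
        if bad.any():
            raise ValidationError(
                f"{path}: unknown marker class {df.loc[bad, 'class'].iloc[0]!r}"
            )
    else:
        df = df.astype({"x": int, "y": int, "class": str})
    return df.reset_index(drop=True)


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers = markers[["x", "y", "class"]]
    markers.to_csv(path, index=False)


def validate_markers(markers: pd.DataFrame, shape: tuple[int, int]) -> None:
    """Check every marker lies inside an image of the given (H, W) extent."""
    if len(markers) == 0:
        return
    h, w = shape
    if (
        (markers["x"] < 0).any()
        or (markers["x"] >= w).any()
        or (markers["y"] < 0).any()
        or (markers["y"] >= h).any()
    ):
        raise ValidationError("marker outside image extent")
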