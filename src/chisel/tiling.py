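"""ROI tiling, border padding, patch quality control and ROI sampling.

Large images are processed in square ROIs laid out on a regular grid
(scheme A).  Schemes B and C add copies of every tile shifted by half the
adaptive-threshold window (right/down for B; all four directions for C), so
that objects cut by a tile border are seen whole by an overlapping tile and
can be recovered by the majority-vote fusion in :mod:`chisel.assembly`.

A small fully connected network (the patch QC model) can skip ROIs that are
empty or too blurred to be worth processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import ParameterError, StateError, ValidationError
from .mlp import TinyMLP
from .segmentation import value_channel

TILE_KINDS = ("base", "shifted-right", "shifted-down", "shifted-left", "shifted-up")


@dataclass(frozen=True)
class Tile:
    """One ROI rectangle, half-open ``[r0, r1) x [c0, c1)`` in image coords.

    The rectangle may extend past the image; :func:`extract_tile` fills the
    missing area by edge replication.
    """

    r0: int
    c0: int
    r1: int
    c1: int
    kind: str = "base"

    def pad_for(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """(top, bottom, left, right) padding needed against an (H, W) image."""
        h, w = shape
        return (
            max(0, -self.r0),
            max(0, self.r1 - h),
            max(0, -self.c0),
            max(0, self.c1 - w),
        )


@dataclass
class TileGrid:
    tiles: list[Tile]
    height: int
    width: int
    roi_size: int
    shift: int
    scheme: str


def _anchored_starts(extent: int, roi: int) -> list[int]:
    # last tile anchored to the far edge so padding only occurs when the
    # image is smaller than one ROI
    if extent <= roi:
        return [0]
    starts = list(range(0, extent - roi, roi))
    starts.append(extent - roi)
    return starts


def compute_tile_grid(
    height: int, width: int, roi_size: int, window: int, scheme: str = "B"
) -> TileGrid:
    """Precompute base (and scheme-shifted) ROI rectangles for an image.

    Base tiles form a cover of the image on a regular grid with stride
    ``roi_size`` (the last row/column anchored to the image edge).  Scheme B
    appends, per base tile, copies shifted by ``window // 2`` px right and
    down; scheme C shifts in all four main directions.
    """
    if roi_size <= 0 or window <= 0:
        raise ParameterError("roi_size and window must be positive")
    if scheme not in ("A", "B", "C"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    shift = window // 2
    tiles = [
        Tile(r, c, r + roi_size, c + roi_size)
        for r in _anchored_starts(height, roi_size)
        for c in _anchored_starts(width, roi_size)
    ]
    base = list(tiles)
    if scheme in ("B", "C"):
        for t in base:
            tiles.append(Tile(t.r0, t.c0 + shift, t.r1, t.c1 + shift, "shifted-right"))
            tiles.append(Tile(t.r0 + shift, t.c0, t.r1 + shift, t.c1, "shifted-down"))
    if scheme == "C":
        for t in base:
            tiles.append(Tile(t.r0, t.c0 - shift, t.r1, t.c1 - shift, "shifted-left"))
            tiles.append(Tile(t.r0 - shift, t.c0, t.r1 - shift, t.c1, "shifted-up"))
    return TileGrid(tiles, height, width, roi_size, shift, scheme)


def extract_tile(image: np.ndarray, tile: Tile) -> np.ndarray:
    """Crop a tile from the image, edge-replicating outside the border."""
    h, w = image.shape[:2]
    r0, c0 = max(tile.r0, 0), max(tile.c0, 0)
    r1, c1 = min(tile.r1, h), min(tile.c1, w)
    if r0 >= r1 or c0 >= c1:
        raise ParameterError("tile lies fully outside the image")
    patch = image[r0:r1, c0:c1]
    top, bottom, left, right = tile.pad_for((h, w))
    if any((top, bottom, left, right)):
        pad = [(top, bottom), (left, right)] + [(0, 0)] * (image.ndim - 2)
        patch = np.pad(patch, pad, mode="edge")
    return patch


def sample_rois_two_circle(
    core_center: tuple[float, float],
    roi_size: int,
    n: int,
    seed: int = 0,
    r1: float = 500.0,
    r2: float = 2000.0,
) -> list[Tile]:
    """Sample ROI tiles whose upper-left corners lie on two circles.

    The circle (radius ``r1`` or ``r2``, centered on the tissue core) is
    chosen uniformly, then an angle uniformly; corners are rounded to
    integer pixels.  ROIs may extend past the image; the caller pads.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cx, cy = core_center
    tiles = []
    for _ in range(n):
        r = r1 if rng.integers(2) == 0 else r2
        ang = rng.uniform(0, 2 * np.pi)
        c0 = int(round(cx + r * np.cos(ang)))
        r0 = int(round(cy + r * np.sin(ang)))
        tiles.append(Tile(r0, c0, r0 + roi_size, c0 + roi_size))
    return tiles


# ---------------------------------------------------------------------------
# Patch quality control
# ---------------------------------------------------------------------------

QC_CLASSES = ("keep", "skip")


def qc_features(patch: np.ndarray) -> np.ndarray:
    """Summary features of a patch for the QC network.

    16-bin Value-channel histogram (density), log Laplacian energy (a blur
    indicator) and the foreground fraction at the Otsu cut (an emptiness
    indicator): 18 values.
    """
    v = value_channel(patch)
    hist, _ = np.histogram(v, bins=16, range=(0.0, 1.0))
    hist = hist / v.size
    lap = ndi.laplace(v)
    lap_energy = np.log10(np.mean(lap**2) + 1e-12)
    if v.max() - v.min() < 1e-6:
        fg_frac = 0.0
    else:
        fg_frac = float(np.mean(v < threshold_otsu(v)))
    return np.concatenate([hist, [lap_energy, fg_frac]])


@dataclass
class PatchQCModel:
    """Trained QC network plus its feature scaler and held-out accuracy."""

    mlp: TinyMLP | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    holdout_accuracy: float | None = None

    @property
    def trained(self) -> bool:
        return self.mlp is not None

    def keep_probability(self, patch: np.ndarray) -> float:
        if not self.trained:
            raise StateError("QC model is not trained")
        x = (qc_features(patch) - self.mean) / self.std
        return float(self.mlp.predict_proba(x[None, :])[0, 0])

    def to_json(self, path: str | Path) -> None:
        if not self.trained:
            raise StateError("QC model is not trained")
        payload = {
            "mlp": self.mlp.to_dict(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "holdout_accuracy": self.holdout_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatchQCModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mlp=TinyMLP.from_dict(d["mlp"]),
            mean=np.asarray(d["mean"]),
            std=np.asarray(d["std"]),
            holdout_accuracy=d["holdout_accuracy"],
        )


def train_patch_qc(
    patches: list[np.ndarray],
    labels: list[str],
    seed: int = 0,
    hidden: int = 10,
    epochs: int = 300,
    holdout_fraction: float = 0.2,
) -> PatchQCModel:
    """Train the patch QC network on labeled ``keep``/``skip`` patches."""
    if len(patches) == 0:
        raise ValidationError("empty training set")
    if len(patches) != len(labels):
        raise ValidationError("patches and labels length mismatch")
    bad = set(labels) - set(QC_CLASSES)
    if bad:
        raise ValidationError(f"unknown QC labels {bad}")
    if len(set(labels)) < 2:
        raise ValidationError("need both keep and skip examples")
    X = np.stack([qc_features(p) for p in patches])
    y = np.array([QC_CLASSES.index(l) for l in labels])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_hold = max(1, int(round(holdout_fraction * len(y))))
    hold, train = order[:n_hold], order[n_hold:]
    if len(set(y[train])) < 2:  # degenerate shuffle on tiny sets
        train, hold = order, order[:n_hold]
    mean = X[train].mean(axis=0)
    std = X[train].std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std
    mlp = TinyMLP.train(
        Xs[train], y[train], n_classes=2, hidden=hidden, seed=seed, epochs=epochs
    )
    acc = float(np.mean(mlp.predict_proba(Xs[hold]).argmax(axis=1) == y[hold]))
    return PatchQCModel(mlp=mlp, mean=mean, std=std, holdout_accuracy=acc)


def qc_patch(patch: np.ndarray, model: PatchQCModel, threshold: float = 0.5) -> str:
    """Decide whether a patch is worth processing: ``"keep"`` or ``"skip"``."""
    return "keep" if model.keep_probability(patch) >= threshold else "skip"
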