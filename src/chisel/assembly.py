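"""Seam-free fusion of per-ROI masks by per-pixel majority vote.

Each processed ROI contributes its binary mask; for every image pixel we
count the number of ROIs covering it (``coverage``) and the number voting
foreground (``votes``).  A pixel becomes foreground only under a strict
majority (``votes > coverage / 2``; ties and uncovered pixels are
background).  Padded tile areas and QC-skipped tiles contribute to neither
count, so border padding cannot outvote real observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .splitting import relabel_raster
from .tiling import TileGrid


@dataclass
class VoteMap:
    votes: np.ndarray  # int, foreground votes per pixel
    coverage: np.ndarray  # int, number of contributing ROIs per pixel


def accumulate_votes(grid: TileGrid, tile_masks: list[np.ndarray | None]) -> VoteMap:
    """Accumulate per-pixel foreground votes from processed ROI masks.

    ``tile_masks`` is aligned with ``grid.tiles``; ``None`` marks a
    QC-skipped tile (contributing nothing).  Each mask covers the full
    padded ``roi_size x roi_size`` patch; only its unpadded part is used.
    """
    if len(tile_masks) != len(grid.tiles):
        raise ValidationError(
            f"{len(tile_masks)} masks for {len(grid.tiles)} tiles"
        )
    h, w = grid.height, grid.width
    votes = np.zeros((h, w), dtype=np.int32)
    coverage = np.zeros((h, w), dtype=np.int32)
    s = grid.roi_size
    for tile, mask in zip(grid.tiles, tile_masks):
        if mask is None:
            continue
        if mask.shape != (s, s):
            raise ValidationError(f"tile mask shape {mask.shape} != ({s}, {s})")
        top, bottom, left, right = tile.pad_for((h, w))
        core = mask[top : s - bottom, left : s - right]
        r0, c0 = tile.r0 + top, tile.c0 + left
        sl = (slice(r0, r0 + core.shape[0]), slice(c0, c0 + core.shape[1]))
        votes[sl] += core
        coverage[sl] += 1
    return VoteMap(votes=votes, coverage=coverage)


def majority_mask(vm: VoteMap) -> np.ndarray:
    """Strict-majority fusion: foreground iff ``votes > coverage / 2``."""
    if vm.votes.shape != vm.coverage.shape:
        raise ValidationError("votes/coverage shape mismatch")
    return (2 * vm.votes > vm.coverage) & (vm.coverage > 0)


def label_objects(mask: np.ndarray) -> np.ndarray:
    """8-connected components labeled 1..N in raster order of first pixel."""
    labels, _ = ndi.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3)))
    return relabel_raster(labels.astype(np.int32))
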