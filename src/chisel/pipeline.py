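"""End-to-end pipeline driver: tile, segment, split, fuse, classify.

Stages follow the processing order of the framework: the image is tiled
(with scheme-shifted overlap), each kept tile is thresholded on the Value
channel, refined with the active contour, cluster-split and cleaned of
sub-``min_area`` artifacts; tile masks are fused by per-pixel majority
vote; the fused mask is split once more at image level (per-tile label
identities do not survive fusion) and cleaned again; finally each object is
featurized and classified.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .assembly import accumulate_votes, majority_mask
from .classify import ClassifierModel, NucleusRecord, extract_features, predict
from .config import PipelineConfig
from .errors import ParameterError
from .segmentation import bradley_threshold, refine_boundaries, value_channel
from .splitting import SplitParams, recursive_split, remove_small
from .tiling import PatchQCModel, compute_tile_grid, extract_tile, qc_patch

logger = logging.getLogger("chisel")


@dataclass
class ResultTable:
    """Detected nuclei plus summary counts."""

    records: list[NucleusRecord] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.predicted_class == "positive" for r in self.records)

    @property
    def n_negative(self) -> int:
        return sum(r.predicted_class == "negative" for r in self.records)

    @property
    def positive_ratio(self) -> float | None:
        """Share of immunopositive nuclei — the diagnostic readout.

        ``None`` (flagged, not 0) when no nuclei were detected.
        """
        return self.n_positive / self.n_total if self.n_total else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label_id": r.label_id,
                    "x": r.centroid_x,
                    "y": r.centroid_y,
                    "area": r.area,
                    "perimeter": r.perimeter,
                    "class": r.predicted_class,
                    "probability": r.probability,
                }
                for r in self.records
            ],
            columns=["label_id", "x", "y", "area", "perimeter", "class", "probability"],
        )

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "positive_ratio": self.positive_ratio,
        }


def _split_params(cfg: PipelineConfig) -> SplitParams:
    return SplitParams(
        T=cfg.split_T, dT=cfg.split_dT,
        max_recurrences=cfg.max_recurrences, min_seed_area=cfg.min_seed_area,
    )


def detect_nuclei(
    image: np.ndarray,
    cfg: PipelineConfig | None = None,
    qc_model: PatchQCModel | None = None,
) -> np.ndarray:
    """Run the detection stages and return the image-level label mask."""
    cfg = cfg or PipelineConfig()
    h, w = image.shape[:2]
    if min(h, w) <= cfg.window:
        raise ParameterError(
            f"image side {min(h, w)} must exceed the adaptive-threshold window "
            f"{cfg.window}; reduce --window"
        )
    t0 = time.perf_counter()
    grid = compute_tile_grid(h, w, cfg.roi_size, cfg.window, cfg.scheme)
    logger.info("tiling: %d tiles (scheme %s)", len(grid.tiles), cfg.scheme)
    sp = _split_params(cfg)
    masks: list[np.ndarray | None] = []
    n_skipped = 0
    for tile in grid.tiles:
        patch = extract_tile(image, tile)
        if qc_model is not None and qc_patch(patch, qc_model) == "skip":
            masks.append(None)
            n_skipped += 1
            continue
        v = value_channel(patch)
        m = bradley_threshold(v, cfg.window, cfg.threshold_t)
        m = refine_boundaries(v, m, cfg.ac_iterations)
        lab = remove_small(recursive_split(m, sp), cfg.min_area)
        masks.append(lab > 0)
    logger.info(
        "tiles processed: %d kept, %d skipped (%.1fs)",
        len(grid.tiles) - n_skipped, n_skipped, time.perf_counter() - t0,
    )
    merged = majority_mask(accumulate_votes(grid, masks))
    labels = remove_small(recursive_split(merged, sp), cfg.min_area)
    logger.info(
        "fusion: %d objects after image-level re-split (%.1fs)",
        int(labels.max()), time.perf_counter() - t0,
    )
    return labels


def classify_objects(
    image: np.ndarray, labels: np.ndarray, model: ClassifierModel
) -> ResultTable:
    """Featurize and classify every labeled object."""
    table = ResultTable()
    for props in measure.regionprops(labels):
        fv = extract_features(image, labels, props.label)
        cls, prob = predict(model, fv)
        cr, cc = props.centroid
        table.records.append(
            NucleusRecord(
                label_id=props.label, centroid_x=float(cc), centroid_y=float(cr),
                area=int(props.area), perimeter=float(props.perimeter),
                predicted_class=cls, probability=prob,
            )
        )
    return table


def run_pipeline(
    image: np.ndarray,
    cfg: PipelineConfig | None = None,
    model: ClassifierModel | None = None,
    qc_model: PatchQCModel | None = None,
) -> tuple[np.ndarray, ResultTable]:
    """Full pipeline: label mask plus one classified record per object.

    Without a classifier model, detection still runs and every record's
    class is ``"unspecified"`` with probability 1.
    """
    cfg = cfg or PipelineConfig()
    labels = detect_nuclei(image, cfg, qc_model)
    if model is not None:
        table = classify_objects(image, labels, model)
    else:
        table = ResultTable()
        for props in measure.regionprops(labels):
            cr, cc = props.centroid
            table.records.append(
                NucleusRecord(
                    label_id=props.label, centroid_x=float(cc), centroid_y=float(cr),
                    area=int(props.area), perimeter=float(props.perimeter),
                    predicted_class="unspecified", probability=1.0,
                )
            )
    logger.info("result: %s", table.summary())
    return labels, table
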