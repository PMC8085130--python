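"""Object-wise and pixel-wise scoring, and precision–recall parameter sweeps.

Detection is scored against point markers by containment: a marker matches
the labeled object whose pixels contain it.  Each object containing at
least one marker is one true positive; surplus markers in the same object
are false negatives (one-to-one matching), objects without markers are
false positives, and unmatched markers false negatives.  PPV = TP/(TP+FP),
TPR = TP/(TP+FN), F1 = harmonic mean; 0/0 counts as 0.

Aggregation over images defaults to macro (per-image metrics averaged);
pooled counts are also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import validate_markers


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    scope: str = "detection"

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.TP + other.TP, self.FP + other.FP,
                          self.FN + other.FN, self.scope)


def match_objects(labels: np.ndarray, markers: pd.DataFrame) -> EvalCounts:
    """One-to-one containment matching of labeled objects to point markers."""
    labels = np.asarray(labels)
    validate_markers(markers, labels.shape)
    n_objects = int(labels.max())
    hits = np.zeros(n_objects + 1, dtype=np.int64)
    fn_outside = 0
    for x, y in zip(markers["x"].to_numpy(), markers["y"].to_numpy()):
        lab = int(labels[y, x])
        if lab == 0:
            fn_outside += 1
        else:
            hits[lab] += 1
    matched = int(np.count_nonzero(hits[1:]))
    surplus = int(hits[1:][hits[1:] > 0].sum() - matched)
    return EvalCounts(
        TP=matched, FP=n_objects - matched, FN=surplus + fn_outside
    )


def detection_metrics(counts: EvalCounts) -> tuple[float, float, float]:
    """(PPV, TPR, F1) from TP/FP/FN; any 0/0 ratio is 0 by convention."""
    ppv = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    tpr = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f1 = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr else 0.0
    return ppv, tpr, f1


def classwise_counts(
    labels: np.ndarray,
    predicted_classes: dict[int, str],
    markers: pd.DataFrame,
) -> dict[str, EvalCounts]:
    """Detection+classification counts per class (positive / negative).

    Matching follows :func:`match_objects`; a matched pair is a TP of its
    class only when the object's predicted class agrees with the marker
    class (the first marker, in table order, when an object holds several).
    A mismatched pair counts FP for the predicted class and FN for the
    marker class.  Surplus/unmatched markers are FN of their class;
    unmatched objects FP of their predicted class.
    """
    labels = np.asarray(labels)
    validate_markers(markers, labels.shape)
    if (markers["class"] == "unspecified").any():
        raise ValidationError("class-wise scoring needs class-labeled markers")
    counts = {c: EvalCounts(scope=f"{c}-class") for c in ("positive", "negative")}
    first_marker: dict[int, str] = {}
    for x, y, mc in zip(markers["x"], markers["y"], markers["class"]):
        lab = int(labels[y, x])
        if lab == 0 or lab in first_marker:
            counts[mc].FN += 1  # unmatched or surplus marker
        else:
            first_marker[lab] = mc
    for lab, pred in predicted_classes.items():
        if pred not in counts:
            raise ValidationError(f"unknown predicted class {pred!r}")
        mc = first_marker.get(lab)
        if mc is None:
            counts[pred].FP += 1
        elif mc == pred:
            counts[pred].TP += 1
        else:
            counts[pred].FP += 1
            counts[mc].FN += 1
    return counts


def classwise_metrics(
    labels: np.ndarray,
    predicted_classes: dict[int, str],
    markers: pd.DataFrame,
) -> dict[str, tuple[float, float, float]]:
    """(PPV, TPR, F1) per class for detection followed by classification."""
    return {
        c: detection_metrics(cnt)
        for c, cnt in classwise_counts(labels, predicted_classes, markers).items()
    }


def pixel_metrics(
    pred: np.ndarray, gt: np.ndarray, region: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Pixel-wise (PPV, TPR, F1), optionally restricted to a region mask."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    region = np.ones_like(pred) if region is None else np.asarray(region, dtype=bool)
    if pred.shape != gt.shape or pred.shape != region.shape:
        raise ValidationError("mask shape mismatch")
    p, g = pred[region], gt[region]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return detection_metrics(EvalCounts(TP=tp, FP=fp, FN=fn, scope="pixel"))


@dataclass
class PRCurve:
    """Precision–recall points of one parameter sweep."""

    parameter: str
    values: list[float]
    ppv: list[float]
    tpr: list[float]
    f1: list[float]
    aggregation: str = "macro"

    @property
    def best_value(self) -> float:
        return self.values[int(np.argmax(self.f1))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "ppv": self.ppv, "tpr": self.tpr, "f1": self.f1}
        )


SWEEPABLE = ("threshold_t", "split_T")


def _aggregate(per_image: list[EvalCounts], aggregation: str):
    if aggregation == "pooled":
        total = EvalCounts()
        for c in per_image:
            total = total + c
        return detection_metrics(total)
    mats = np.array([detection_metrics(c) for c in per_image])
    return tuple(mats.mean(axis=0))


def sweep_parameter(
    images: list[np.ndarray],
    markersets: list[pd.DataFrame],
    parameter: str,
    values: list[float],
    cfg,
    qc_model=None,
    aggregation: str = "macro",
) -> PRCurve:
    """Run detection over a parameter grid and score each setting.

    Per value the detection pipeline runs on every image and the per-image
    (PPV, TPR, F1) are macro-averaged (or pooled).  Deterministic.
    """
    from .pipeline import detect_nuclei  # deferred: avoid import cycle

    if parameter not in SWEEPABLE:
        raise ParameterError(f"parameter must be one of {SWEEPABLE}")
    if not values:
        raise ParameterError("empty value list")
    if not images or len(images) != len(markersets):
        raise ValidationError("need >= 1 image with a marker set each")
    ppvs, tprs, f1s = [], [], []
    for val in values:
        cfg_v = cfg.from_dict({**cfg.to_dict(), parameter: val})
        per_image = [
            match_objects(detect_nuclei(img, cfg_v, qc_model), mk)
            for img, mk in zip(images, markersets)
        ]
        p, t, f = _aggregate(per_image, aggregation)
        ppvs.append(p); tprs.append(t); f1s.append(f)
    return PRCurve(parameter, list(values), ppvs, tprs, f1s, aggregation)


def tune_twofold(
    images: list[np.ndarray],
    markersets: list[pd.DataFrame],
    parameter: str,
    values: list[float],
    cfg,
    seed: int = 0,
) -> dict:
    """Twofold cross-validated tuning: pick per-fold best value on one half,
    score it on the held-out half.  Folds split by image, seeded."""
    if len(images) < 2:
        raise ValidationError("twofold CV needs at least 2 images")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    folds = [order[::2], order[1::2]]
    report = {"parameter": parameter, "folds": []}
    for k in (0, 1):
        fit_idx, eval_idx = folds[k], folds[1 - k]
        curve = sweep_parameter(
            [images[i] for i in fit_idx], [markersets[i] for i in fit_idx],
            parameter, values, cfg,
        )
        best = curve.best_value
        eval_curve = sweep_parameter(
            [images[i] for i in eval_idx], [markersets[i] for i in eval_idx],
            parameter, [best], cfg,
        )
        report["folds"].append(
            {"best_value": best, "holdout_f1": eval_curve.f1[0]}
        )
    return report
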