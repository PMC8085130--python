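"""Per-nucleus feature extraction: 103 features per RGB channel.

Per channel the descriptor concatenates 11 geometric features, a 9-bin
histogram of oriented gradients, 44 gray-level run-length (GLRLM)
statistics (11 statistics x 4 directions), 5 autoregression-model features,
20 Haar-wavelet subband energies (4 subbands x 5 levels), 5 gradient
features and 9 intensity-histogram features — 103 in total, 309 over the
three channels.  Geometric features depend only on the label geometry and
are therefore identical across channels; they are kept per channel by
default for a fixed literal layout, with an optional deduplicated layout
(11 + 92 x 3 = 287).

Texture blocks are computed on a square window (default 64 px) centered at
the object centroid, with non-object pixels replaced by the mean of the
background pixels inside the window, so features are invariant to
translating the object together with its surroundings.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage as ndi
from scipy import stats
from skimage import measure

from .errors import ValidationError

TEXTURE_WINDOW = 64
GLRLM_LEVELS = 16

GEOMETRIC_NAMES = [
    "area", "perimeter", "circularity", "eccentricity", "major_axis",
    "minor_axis", "equivalent_diameter", "solidity", "extent",
    "convex_area", "orientation",
]
HOG_NAMES = [f"hog_{i}" for i in range(9)]
GLRLM_STATS = [
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge",
]
GLRLM_NAMES = [f"glrlm_{d}_{s}" for d in (0, 45, 90, 135) for s in GLRLM_STATS]
AR_NAMES = [f"ar_{i}" for i in range(1, 5)] + ["ar_resid_sd"]
HAAR_NAMES = [f"haar_l{l}_{sb}" for l in range(1, 6) for sb in ("ll", "lh", "hl", "hh")]
GRADIENT_NAMES = ["grad_mean", "grad_var", "grad_skew", "grad_kurt", "grad_nonzero"]
HISTOGRAM_NAMES = [
    "hist_mean", "hist_var", "hist_skew", "hist_kurt",
    "hist_p01", "hist_p10", "hist_p50", "hist_p90", "hist_p99",
]

CHANNEL_BLOCK = (
    GEOMETRIC_NAMES + HOG_NAMES + GLRLM_NAMES + AR_NAMES
    + HAAR_NAMES + GRADIENT_NAMES + HISTOGRAM_NAMES
)
assert len(CHANNEL_BLOCK) == 103

FEATURE_NAMES = [f"{ch}_{name}" for ch in "rgb" for name in CHANNEL_BLOCK]
FEATURE_NAMES_DEDUP = GEOMETRIC_NAMES + [
    f"{ch}_{name}" for ch in "rgb" for name in CHANNEL_BLOCK[11:]
]


def geometric_features(obj_mask: np.ndarray) -> np.ndarray:
    """Shape features of one object from its binary mask."""
    props = measure.regionprops(obj_mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter)
    circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    return np.array([
        area, perim, circ, props.eccentricity, props.axis_major_length,
        props.axis_minor_length, props.equivalent_diameter_area,
        props.solidity, props.extent, float(props.area_convex),
        props.orientation,
    ])


def _moments4(x: np.ndarray) -> tuple[float, float, float, float]:
    m = float(np.mean(x))
    v = float(np.var(x))
    if v < 1e-24:
        return m, v, 0.0, 0.0
    return m, v, float(stats.skew(x, axis=None)), float(stats.kurtosis(x, axis=None))


def histogram_features(win: np.ndarray) -> np.ndarray:
    m, v, sk, ku = _moments4(win)
    pcts = np.percentile(win, [1, 10, 50, 90, 99])
    return np.concatenate([[m, v, sk, ku], pcts])


def gradient_features(win: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(win)
    mag = np.hypot(gx, gy)
    m, v, sk, ku = _moments4(mag)
    nonzero = float(np.mean(mag > 1e-3))
    return np.array([m, v, sk, ku, nonzero])


def hog_features(win: np.ndarray, bins: int = 9) -> np.ndarray:
    """Signed-orientation gradient histogram, L2-normalized."""
    gy, gx = np.gradient(win)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)  # [-pi, pi]
    hist, _ = np.histogram(ang, bins=bins, range=(-np.pi, np.pi), weights=mag)
    norm = np.linalg.norm(hist)
    return hist / norm if norm > 0 else hist


def _runs_of_line(line: np.ndarray, out: np.ndarray) -> None:
    # accumulate (gray level, run length) counts of one quantized line
    if line.size == 0:
        return
    breaks = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [line.size]])
    lengths = np.minimum(ends - starts, out.shape[1])
    np.add.at(out, (line[starts], lengths - 1), 1)


def glrlm_matrix(q: np.ndarray, direction: int, levels: int = GLRLM_LEVELS) -> np.ndarray:
    """Run-length matrix ``P[level, run_length-1]`` along one direction."""
    n = max(q.shape)
    out = np.zeros((levels, n), dtype=np.int64)
    if direction == 0:
        lines = list(q)
    elif direction == 90:
        lines = list(q.T)
    elif direction == 45:
        f = np.fliplr(q)
        lines = [f.diagonal(k) for k in range(-q.shape[0] + 1, q.shape[1])]
    elif direction == 135:
        lines = [q.diagonal(k) for k in range(-q.shape[0] + 1, q.shape[1])]
    else:
        raise ValidationError(f"unsupported GLRLM direction {direction}")
    for line in lines:
        _runs_of_line(np.ascontiguousarray(line), out)
    return out


def glrlm_stats(p: np.ndarray, n_pixels: int) -> np.ndarray:
    """The 11 classic run-length statistics of one run-length matrix."""
    nr = p.sum()
    if nr == 0:
        return np.zeros(11)
    j = np.arange(1, p.shape[1] + 1, dtype=np.float64)  # run lengths
    g = np.arange(1, p.shape[0] + 1, dtype=np.float64)  # gray levels (1-based)
    pj = p.sum(axis=0).astype(np.float64)
    pg = p.sum(axis=1).astype(np.float64)
    j2, g2 = j**2, g**2
    sre = (pj / j2).sum() / nr
    lre = (pj * j2).sum() / nr
    gln = (pg**2).sum() / nr
    rln = (pj**2).sum() / nr
    rp = nr / n_pixels
    lgre = (pg / g2).sum() / nr
    hgre = (pg * g2).sum() / nr
    srlge = (p / np.outer(g2, j2)).sum() / nr
    srhge = (p * np.outer(g2, 1.0 / j2)).sum() / nr
    lrlge = (p * np.outer(1.0 / g2, j2)).sum() / nr
    lrhge = (p * np.outer(g2, j2)).sum() / nr
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


def glrlm_features(win: np.ndarray, levels: int = GLRLM_LEVELS) -> np.ndarray:
    q = np.clip((win * levels).astype(np.int64), 0, levels - 1)
    return np.concatenate(
        [glrlm_stats(glrlm_matrix(q, d, levels), q.size) for d in (0, 45, 90, 135)]
    )


def ar_features(win: np.ndarray) -> np.ndarray:
    """Causal autoregression: v[i,j] ~ W, N, NW, NE neighbors; 4 params + residual sd."""
    y = win[1:, 1:-1].ravel()
    X = np.stack([
        win[1:, :-2].ravel(),   # west
        win[:-1, 1:-1].ravel(),  # north
        win[:-1, :-2].ravel(),   # north-west
        win[:-1, 2:].ravel(),    # north-east
    ], axis=1)
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    return np.concatenate([theta, [float(np.std(resid))]])


def haar_features(win: np.ndarray, levels: int = 5) -> np.ndarray:
    """Mean energies of the LL/LH/HL/HH Haar subbands at each level."""
    out = []
    current = win
    for _ in range(levels):
        ll, (lh, hl, hh) = pywt.dwt2(current, "haar")
        out.extend(float(np.mean(b**2)) for b in (ll, lh, hl, hh))
        current = ll
    return np.array(out)


def texture_window(
    channel: np.ndarray,
    obj_mask: np.ndarray,
    centroid_rc: tuple[float, float],
    size: int = TEXTURE_WINDOW,
) -> np.ndarray:
    """Centered window with non-object pixels set to the background mean."""
    h, w = channel.shape
    r0 = int(round(centroid_rc[0])) - size // 2
    c0 = int(round(centroid_rc[1])) - size // 2
    rows = np.clip(np.arange(r0, r0 + size), 0, h - 1)
    cols = np.clip(np.arange(c0, c0 + size), 0, w - 1)
    win = channel[np.ix_(rows, cols)].astype(np.float64)
    m = obj_mask[np.ix_(rows, cols)]
    bg = win[~m]
    bg_mean = float(bg.mean()) if bg.size else float(win.mean())
    out = np.full_like(win, bg_mean)
    out[m] = win[m]
    return out


def channel_texture_features(win: np.ndarray) -> np.ndarray:
    return np.concatenate([
        hog_features(win),
        glrlm_features(win),
        ar_features(win),
        haar_features(win),
        gradient_features(win),
        histogram_features(win),
    ])


def extract_features(
    image: np.ndarray,
    labels: np.ndarray,
    label_id: int,
    dedup_geometric: bool = False,
    window: int = TEXTURE_WINDOW,
) -> np.ndarray:
    """Feature vector of one labeled object (length 309, or 287 deduplicated)."""
    obj_mask = labels == label_id
    if not obj_mask.any():
        raise LookupError(f"label {label_id} not present in mask")
    geo = geometric_features(obj_mask)
    centroid = ndi.center_of_mass(obj_mask)
    blocks = []
    for ch in range(3):
        channel = image[:, :, ch].astype(np.float64) / 255.0
        win = texture_window(channel, obj_mask, centroid, window)
        tex = channel_texture_features(win)
        blocks.append(tex if dedup_geometric else np.concatenate([geo, tex]))
    parts = ([geo] if dedup_geometric else []) + blocks
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"non-finite feature for label {label_id}")
    return vec


def feature_names(dedup_geometric: bool = False) -> list[str]:
    return list(FEATURE_NAMES_DEDUP if dedup_geometric else FEATURE_NAMES)
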