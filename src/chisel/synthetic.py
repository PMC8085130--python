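"""Synthetic DAB&H-like scenes with exact ground truth.

Scenes emulate the appearance that drives every stage of the pipeline:
elliptical nuclei darker than the background in the HSV Value channel,
DAB-brown for immunopositive and hematoxylin-blue for immunonegative
nuclei, with a configurable share of nuclei overlapping a neighbor (the
cluster-splitting workload), Gaussian blur and pixel noise.  Shape presets
match the two study tissue types: ``iispv`` (breast-cancer T cells,
area 311±35 px, circularity 0.50±0.07) and ``wbcd`` (pancreatic beta
cells, area 144±11 px, circularity 0.70±0.08).

Ground truth is exact by construction: a label mask (overlaps resolved by
z-order, later nuclei on top), one class-labeled marker per nucleus placed
inside its own label, and the spec echo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

from .errors import CapacityError, ParameterError


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (lengths in pixels, V in [0, 1])."""

    height: int = 1000
    width: int = 1000
    n_nuclei: int = 100
    positive_fraction: float = 0.3
    area_mean: float = 311.0
    area_sd: float = 35.0
    circularity_mean: float = 0.50
    circularity_sd: float = 0.07
    cluster_fraction: float = 0.3
    background_v: float = 0.93
    positive_hsv: tuple[float, float, float] = (0.07, 0.60, 0.42)  # DAB brown
    negative_hsv: tuple[float, float, float] = (0.60, 0.55, 0.38)  # hematoxylin blue
    noise_sd: float = 0.01
    blur_sigma: float = 0.5
    #: sd (in V units) of a smooth background-texture field emulating faint
    #: tissue structure; 0 disables it.  Correlation length bg_texture_scale px.
    bg_texture_sd: float = 0.0
    bg_texture_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positive_hsv[2] >= self.background_v or self.negative_hsv[2] >= self.background_v:
            raise ParameterError("class V must be strictly below background V")
        if not 0 <= self.positive_fraction <= 1 or not 0 <= self.cluster_fraction <= 1:
            raise ParameterError("fractions must be in [0, 1]")
        if self.area_mean <= 50:
            raise ParameterError("area_mean must exceed the artifact cut-off")


#: Shape presets for the two tissue types exercised by the tests.
PRESETS = {
    "iispv": dict(area_mean=311.0, area_sd=35.0,
                  circularity_mean=0.50, circularity_sd=0.07),
    "wbcd": dict(area_mean=144.0, area_sd=11.0,
                 circularity_mean=0.70, circularity_sd=0.08),
}


def preset_spec(name: str, **overrides) -> SceneSpec:
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SceneSpec(**{**PRESETS[name], **overrides})


@dataclass
class SyntheticScene:
    image: np.ndarray  # uint8 RGB
    gt_labels: np.ndarray  # int32, z-order resolved
    gt_markers: pd.DataFrame  # x, y, class
    spec: SceneSpec


def _ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _ellipse_circularity(q: float) -> float:
    # analytic circularity 4*pi*A/P^2 of an ellipse with aspect ratio q = b/a
    a, b = 1.0, q
    return 4.0 * np.pi * (np.pi * a * b) / _ramanujan_perimeter(a, b) ** 2


def aspect_from_circularity(c: float) -> float:
    """Invert circularity -> aspect ratio b/a of an ellipse (bisection)."""
    c = float(np.clip(c, 0.05, 0.999))
    lo, hi = 1e-3, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _ellipse_circularity(mid) < c:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_shape(spec: SceneSpec, rng: np.random.Generator):
    area = 0.0
    while area < 60.0:  # truncate: stay clear of the artifact cut-off
        area = rng.normal(spec.area_mean, spec.area_sd)
    circ = float(np.clip(rng.normal(spec.circularity_mean, spec.circularity_sd), 0.10, 0.98))
    q = aspect_from_circularity(circ)
    a = np.sqrt(area / (np.pi * q))  # semi-major
    return a, q * a, rng.uniform(0, np.pi)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene and its exact ground truth; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    total_area = spec.n_nuclei * spec.area_mean
    if total_area > 0.4 * spec.height * spec.width:
        raise CapacityError(
            f"requested nucleus area {total_area:.0f} px exceeds 40% of the scene"
        )

    shapes = []  # (row, col, a, b, rot, is_positive)
    n_cluster = int(round(spec.cluster_fraction * spec.n_nuclei))
    margin = 4.0
    for i in range(spec.n_nuclei):
        a, b, rot = _sample_shape(spec, rng)
        r_eq = np.sqrt(a * b)
        clustered = bool(shapes) and i >= spec.n_nuclei - n_cluster
        for _ in range(3000):
            if clustered:
                pr, pc, pa, pb, *_ = shapes[rng.integers(len(shapes))]
                p_eq = np.sqrt(pa * pb)
                overlap = rng.uniform(0.2, 0.4) * min(r_eq, p_eq)
                d = r_eq + p_eq - overlap
                ang = rng.uniform(0, 2 * np.pi)
                row = pr + d * np.sin(ang)
                col = pc + d * np.cos(ang)
                # the chosen partner is allowed (meant) to overlap
                others = [s for s in shapes if (s[0], s[1]) != (pr, pc)]
            else:
                row = rng.uniform(a, spec.height - a)
                col = rng.uniform(a, spec.width - a)
                others = shapes
            if not (a <= row <= spec.height - a and a <= col <= spec.width - a):
                continue
            ok = all(
                np.hypot(row - s[0], col - s[1]) >= a + s[2] + margin for s in others
            )
            if ok:
                break
        else:
            raise CapacityError("could not place nucleus; reduce n_nuclei or sizes")
        positive = rng.uniform() < spec.positive_fraction
        shapes.append((row, col, a, b, rot, positive))

    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    img[:] = hsv2rgb(np.array([[[0.08, 0.04, spec.background_v]]]))[0, 0]
    if spec.bg_texture_sd > 0:
        field = ndi.gaussian_filter(
            rng.standard_normal(labels.shape), spec.bg_texture_scale
        )
        img += (spec.bg_texture_sd * field / field.std())[:, :, None]
    for idx, (row, col, a, b, rot, positive) in enumerate(shapes, start=1):
        rr, cc = draw_ellipse(row, col, a, b, shape=labels.shape, rotation=rot)
        base = spec.positive_hsv if positive else spec.negative_hsv
        jitter = rng.normal(0.0, 0.02)
        hsv = (base[0], base[1], float(np.clip(base[2] + jitter, 0.05, spec.background_v - 0.05)))
        img[rr, cc] = hsv2rgb(np.array([[hsv]]))[0, 0]
        labels[rr, cc] = idx  # z-order: later nuclei overwrite

    if spec.blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = ndi.gaussian_filter(img[:, :, ch], spec.blur_sigma)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)

    # one marker per nucleus: the label's own pixel nearest to its centroid
    xs, ys, classes = [], [], []
    for idx, (_, _, _, _, _, positive) in enumerate(shapes, start=1):
        pix = np.argwhere(labels == idx)
        if pix.size == 0:
            raise CapacityError("a nucleus was fully occluded; use a different seed")
        cr, cc_ = pix.mean(axis=0)
        r, c = pix[np.argmin((pix[:, 0] - cr) ** 2 + (pix[:, 1] - cc_) ** 2)]
        xs.append(int(c)); ys.append(int(r))
        classes.append("positive" if positive else "negative")
    markers = pd.DataFrame({"x": xs, "y": ys, "class": classes})
    return SyntheticScene(image=image, gt_labels=labels, gt_markers=markers, spec=spec)


def degrade_patch(
    patch: np.ndarray, mode: str, magnitude: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Degrade a patch for QC training: ``blank`` or ``blur``.

    ``blank`` replaces the content with background color plus Gaussian noise
    of sd ``magnitude`` (in [0, 1] units); ``blur`` applies a Gaussian blur
    with sigma ``magnitude`` px.
    """
    patch = np.asarray(patch, dtype=np.uint8)
    if mode == "blank":
        rng = np.random.default_rng(seed)
        bg = hsv2rgb(np.array([[[0.08, 0.04, 0.93]]]))[0, 0]
        out = np.broadcast_to(bg, patch.shape).astype(np.float64).copy()
        out += rng.normal(0.0, magnitude, size=out.shape)
        return (np.clip(out, 0, 1) * 255).round().astype(np.uint8)
    if mode == "blur":
        if magnitude == 0:
            return patch.copy()
        out = np.stack(
            [ndi.gaussian_filter(patch[:, :, c].astype(np.float64), magnitude)
             for c in range(3)], axis=-1,
        )
        return np.clip(out, 0, 255).round().astype(np.uint8)
    raise ParameterError(f"unknown degradation mode {mode!r}")
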