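"""Pipeline configuration and physical-unit helpers.

The two parameters that matter most for detection quality are
``threshold_t`` (the relative cut-off of the adaptive threshold, in percent
below the local window mean) and ``split_T`` (the starting level of the
distance-transform cluster-splitting recursion, in pixels).  Both are
exposed in :class:`PipelineConfig` and can be tuned with
:func:`chisel.evaluation.sweep_parameter`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ParameterError

#: Physical pixel pitch in micrometres at the two supported magnifications.
PIXEL_SIZE_40X = 0.25
PIXEL_SIZE_20X = 0.5


def px_area_to_um2(area_px: float, pixel_size_um: float = PIXEL_SIZE_20X) -> float:
    """Convert an area in pixels to square micrometres.

    ``area_px`` pixels at a pitch of ``pixel_size_um`` µm/pixel cover
    ``area_px * pixel_size_um**2`` µm².  At 20× (0.5 µm/pixel) the default
    50-pixel artifact cut-off corresponds to 12.5 µm²; at 40× (0.25 µm/pixel)
    to 3.125 µm².
    """
    if area_px < 0 or pixel_size_um <= 0:
        raise ParameterError("area must be >= 0 and pixel size > 0")
    return area_px * pixel_size_um**2


@dataclass
class PipelineConfig:
    """Tunable parameters of the detection/classification pipeline.

    Attributes
    ----------
    roi_size:
        Side of the square ROI tiles in pixels.
    scheme:
        Tiling scheme: ``"A"`` plain grid, ``"B"`` adds right/down shifted
        copies of every tile, ``"C"`` adds shifts in all four directions.
    threshold_t:
        Adaptive-threshold sensitivity in percent: a pixel is foreground if
        its value is more than ``threshold_t`` % below the local mean.
    window:
        Side of the (odd) local-mean window of the adaptive threshold, px.
    split_T:
        Starting threshold of the distance-transform splitting recursion, px.
    split_dT:
        Threshold increment per recurrence, px.
    max_recurrences:
        Cap on threshold evaluations per component chain.
    min_area:
        Objects below this area (px) are discarded as artifacts.
    ac_iterations:
        Iterations of the region-based active-contour boundary refinement.
    min_seed_area:
        Minimum area (px) for a distance-transform peak to count as a seed.
    pixel_size_um:
        Physical pixel pitch, only used for optional µm² reporting.
    seed:
        Seed forwarded to any stochastic helper (training, CV splits).
    """

    roi_size: int = 1000
    scheme: str = "B"
    threshold_t: float = 15.0
    window: int = 51
    split_T: float = 3.0
    split_dT: float = 1.0
    max_recurrences: int = 10
    min_area: int = 50
    ac_iterations: int = 50
    min_seed_area: int = 5
    pixel_size_um: float = PIXEL_SIZE_20X
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.roi_size > self.window > 0):
            raise ParameterError(
                f"need roi_size > window > 0, got {self.roi_size}, {self.window}"
            )
        if self.scheme not in ("A", "B", "C"):
            raise ParameterError(f"unknown tiling scheme {self.scheme!r}")
        if not 0 < self.threshold_t < 100:
            raise ParameterError("threshold_t must be in (0, 100) percent")
        if self.split_T <= 0 or self.split_dT <= 0:
            raise ParameterError("split_T and split_dT must be positive")
        if self.max_recurrences < 1:
            raise ParameterError("max_recurrences must be >= 1")
        if self.min_area < 0:
            raise ParameterError("min_area must be >= 0")
        if self.ac_iterations < 0:
            raise ParameterError("ac_iterations must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
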