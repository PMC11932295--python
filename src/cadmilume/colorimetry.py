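"""Robust per-well color measurement and chromaticity normalization.

A well's color is summarized by the per-channel median over a shrunken
core disk (avoiding the blurred rim), with saturated pixels excluded and
the local background subtracted.  Normalizing the channels by their sum
gives chromatic coordinates (r, g, b) with r + g + b = 1, which removes
overall brightness — the property that makes the green/red ratio
insensitive to exposure and lighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BackgroundUnavailableError,
    EmptyROIError,
    InputError,
    InvalidColorError,
    RatioUndefinedError,
    SaturationError,
)
from .imaging import RasterImage, WellDetection

#: Above this fraction of saturated core pixels the measurement is rejected.
SATURATION_LIMIT = 0.5


@dataclass
class ColorMeasurement:
    """Background-subtracted RGB medians for one well."""

    red: float
    green: float
    blue: float
    n_pixels: int
    saturated_fraction: float
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n_pixels < 1:
            raise InputError("a color measurement needs at least one pixel")
        if min(self.red, self.green, self.blue) < 0:
            raise InputError("background-subtracted intensities must be >= 0")


@dataclass
class ChromaticCoords:
    """Sum-normalized chromaticity and the green/red ratio.

    ``green_red_ratio`` equals G/R on raw intensities, identically g/r on
    the normalized coordinates.
    """

    r: float
    g: float
    b: float
    green_red_ratio: float


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def estimate_background(
    image: RasterImage,
    well: WellDetection,
    annulus: tuple[float, float] = (1.2, 1.5),
    all_wells: list[WellDetection] | None = None,
) -> tuple[float, float, float]:
    """Per-channel median over an annulus around the well.

    The annulus spans ``annulus[0] * radius`` to ``annulus[1] * radius``,
    clipped to the image bounds, excluding pixels that belong to any
    detected well (so a close neighbor cannot leak into the estimate).
    Dark-box frames still have a nonzero floor (read noise, stray light),
    which this estimate removes.
    """
    inner, outer = annulus
    if not 0 < inner < outer:
        raise InputError(f"annulus scales must satisfy 0 < inner < outer, got {annulus}")
    shape = (image.height, image.width)
    ring = _disk_mask(shape, well.center_x, well.center_y, outer * well.radius) & ~_disk_mask(
        shape, well.center_x, well.center_y, inner * well.radius
    )
    for other in all_wells or []:
        ring &= ~_disk_mask(shape, other.center_x, other.center_y, other.radius)
    if not ring.any():
        raise BackgroundUnavailableError(
            f"background annulus for well at ({well.center_x:.1f}, {well.center_y:.1f}) "
            "is empty; pass a zero background explicitly if acceptable"
        )
    pix = image.pixels[ring]
    return tuple(float(np.median(pix[:, ch])) for ch in range(3))


def extract_color(
    image: RasterImage,
    well: WellDetection,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    core_scale: float = 0.7,
    saturation_limit: float = SATURATION_LIMIT,
) -> ColorMeasurement:
    """Median RGB over the well core, saturation-screened, background-subtracted.

    The core disk is the well shrunk to ``core_scale`` of its radius,
    avoiding the intensity gradient at the rim.  Pixels saturated in any
    channel are excluded; if more than ``saturation_limit`` of the core is
    saturated the measurement is rejected outright (a saturated ratio is
    biased toward 1 and must not be reported silently).
    """
    core = _disk_mask((image.height, image.width), well.center_x, well.center_y,
                      core_scale * well.radius)
    pix = image.pixels[core]
    if pix.shape[0] == 0:
        raise EmptyROIError("well core contains no pixels")
    saturated = (pix == image.max_value).any(axis=1)
    sat_frac = float(saturated.mean())
    if sat_frac > saturation_limit:
        raise SaturationError(
            f"{sat_frac:.0%} of core pixels saturated (limit {saturation_limit:.0%}); "
            "retake photo at lower exposure"
        )
    usable = pix[~saturated]
    if usable.shape[0] == 0:
        raise EmptyROIError("no unsaturated pixels in well core")
    med = np.median(usable, axis=0)
    rgb = np.maximum(med - np.asarray(background, dtype=float), 0.0)
    return ColorMeasurement(
        red=float(rgb[0]),
        green=float(rgb[1]),
        blue=float(rgb[2]),
        n_pixels=int(usable.shape[0]),
        saturated_fraction=sat_frac,
        background=tuple(float(b) for b in background),
    )


def chromatic_coords(measurement: ColorMeasurement) -> ChromaticCoords:
    """Normalize RGB to chromatic coordinates and form the green/red ratio.

    Raises :class:`RatioUndefinedError` when red is zero; the exception
    carries the (still valid) coordinates in its ``coords`` attribute.
    """
    total = measurement.red + measurement.green + measurement.blue
    if total <= 0:
        raise InvalidColorError("zero-sum measurement: chromaticity undefined")
    r = measurement.red / total
    g = measurement.green / total
    b = measurement.blue / total
    if measurement.red == 0:
        coords = ChromaticCoords(r, g, b, float("nan"))
        raise RatioUndefinedError("red channel is zero: green/red ratio undefined",
                                  coords=coords)
    return ChromaticCoords(r, g, b, measurement.green / measurement.red)
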