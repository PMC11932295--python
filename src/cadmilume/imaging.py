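"""Well detection in dark-box plate photographs.

The photograph shows luminescent wells as bright disks on a nearly black
background.  Detection proceeds in four steps: collapse the RGB image to a
single detection channel (per-pixel channel maximum, so green and orange
wells are equally bright), binarize it (Otsu by default), trace connected
components with shape filters, and map the surviving detections onto the
plate grid.

Coordinates are 0-based with the origin at the top-left corner; x grows
rightward, y downward; all geometry is in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, GridInferenceError, InputError, LayoutMismatchError
from .layout import PlateLayout

# Circularity slightly exceeds 1 on small discretized disks because the
# polygonal perimeter underestimates the true circumference; values up to
# this tolerance are clamped to 1, larger values indicate a bug upstream.
_CIRCULARITY_TOL = 1.1


@dataclass
class RasterImage:
    """An H x W x 3 pixel grid in red-green-blue channel order."""

    pixels: np.ndarray  # (H, W, 3) unsigned integer
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(f"expected an (H, W, 3) image, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise InputError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise InputError("pixel intensities outside [0, 2^bit_depth - 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def read_image(path: Union[str, Path]) -> RasterImage:
    """Read a PNG/JPEG/TIFF raster; 8-bit required, 16-bit used natively."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path}: expected a 3-channel RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise InputError(f"{path}: unsupported pixel type {arr.dtype}")
    return RasterImage(arr, bit_depth=depth)


def write_image(image: RasterImage, path: Union[str, Path]) -> None:
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(path, image.pixels.astype(dtype))


@dataclass
class WellDetection:
    """A localized luminescent well.

    ``radius`` is the equivalent-circle radius sqrt(area/pi); circularity
    is 4*pi*A/P^2 with the polygonal contour perimeter, clamped to 1.
    Grid indices are None until :func:`assign_grid` runs.
    """

    center_x: float
    center_y: float
    radius: float
    area: float
    circularity: float
    grid_row: int | None = None
    grid_col: int | None = None

    def __post_init__(self):
        if self.area <= 0:
            raise InputError("detection area must be positive")
        if not 0 < self.circularity <= _CIRCULARITY_TOL:
            raise InputError(f"circularity {self.circularity} outside (0, {_CIRCULARITY_TOL}]")
        self.circularity = min(self.circularity, 1.0)


def to_detection_channel(image: RasterImage) -> np.ndarray:
    """Per-pixel maximum over the three channels.

    The channel max is hue-independent: a pure-green well and a pure-red
    well of equal brightness score the same, which a luminance weighting
    would not give.
    """
    if image.pixels.ndim != 3 or image.pixels.shape[2] != 3:
        raise InputError("detection channel requires a 3-channel image")
    return image.pixels.max(axis=2)


def binarize(
    channel: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    opening_radius: int = 1,
) -> tuple[np.ndarray, float]:
    """Threshold the detection channel into a foreground mask.

    Otsu picks the threshold maximizing between-class variance of the
    intensity histogram; ``fixed`` uses ``fixed_threshold`` directly.
    Foreground is strictly above the threshold.  A morphological opening
    with a disk of ``opening_radius`` removes specks smaller than the
    structuring element, a matching closing plus hole filling regularizes
    the boundary — shot noise at the rim of a dim well otherwise produces
    a ragged outline whose inflated perimeter would fail the circularity
    filter downstream.

    Returns ``(mask, threshold)``.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise InputError("empty intensity grid")
    if method == "otsu":
        if channel.min() == channel.max():
            raise DegenerateHistogramError(
                "constant-intensity image: Otsu has no separable classes"
            )
        thresh = float(threshold_otsu(channel))
    elif method == "fixed":
        if fixed_threshold is None:
            raise InputError("method='fixed' requires fixed_threshold")
        thresh = float(fixed_threshold)
    else:
        raise InputError(f"unknown threshold method {method!r}")
    mask = channel > thresh
    if opening_radius > 0:
        selem = morphology.disk(opening_radius)
        mask = morphology.opening(mask, selem)
        mask = morphology.closing(mask, selem)
        mask = ndi.binary_fill_holes(mask)
    return mask, thresh


def detect_wells(
    mask: np.ndarray,
    min_area: float = 100.0,
    min_circularity: float = 0.6,
) -> list[WellDetection]:
    """Trace connected foreground components and keep the well-like ones.

    Components below ``min_area`` (specks, dust) or below
    ``min_circularity`` (glare streaks) are discarded.  Centroids are
    intensity-unweighted.  The result is sorted by (center_y, center_x).
    """
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    detections: list[WellDetection] = []
    for props in measure.regionprops(labeled):
        area = float(props.area)
        if area < min_area:
            continue
        perimeter = float(props.perimeter)
        if perimeter <= 0:
            continue
        circ = 4.0 * np.pi * area / perimeter**2
        circ = min(circ, _CIRCULARITY_TOL)
        if circ < min_circularity:
            continue
        cy, cx = props.centroid
        detections.append(
            WellDetection(
                center_x=float(cx),
                center_y=float(cy),
                radius=float(np.sqrt(area / np.pi)),
                area=area,
                circularity=circ,
            )
        )
    detections.sort(key=lambda d: (d.center_y, d.center_x))
    return detections


def assign_grid(detections: list[WellDetection], layout: PlateLayout) -> list[WellDetection]:
    """Map detections onto the occupied cells of the plate grid.

    Rows are formed by sorting centers by y and splitting wherever the
    y-gap between consecutive centers exceeds half the median detection
    diameter; within a row, detections are ordered by x.  Rows map
    top-to-bottom onto layout rows and columns left-to-right onto the
    occupied cells of each row.  This tolerates the small (<= ~5 degree)
    rotations of a plate photographed face-on in a fixed box; it is not a
    perspective correction.
    """
    n_cells = layout.n_occupied()
    if len(detections) != n_cells:
        raise LayoutMismatchError(
            f"{len(detections)} detections but layout has {n_cells} occupied cells"
        )
    # ties in y broken by x, then by original list order (stable sort)
    order = sorted(range(len(detections)),
                   key=lambda i: (detections[i].center_y, detections[i].center_x, i))
    sorted_dets = [detections[i] for i in order]

    median_diameter = 2.0 * float(np.median([d.radius for d in sorted_dets]))
    gap = median_diameter / 2.0
    rows: list[list[WellDetection]] = [[sorted_dets[0]]]
    for prev, cur in zip(sorted_dets, sorted_dets[1:]):
        if cur.center_y - prev.center_y > gap:
            rows.append([cur])
        else:
            rows[-1].append(cur)

    occupancy = [n for n in layout.row_occupancy() if n > 0]
    if [len(r) for r in rows] != occupancy:
        raise GridInferenceError(
            f"inferred row sizes {[len(r) for r in rows]} do not match "
            f"layout occupancy {occupancy}"
        )

    layout_rows = [
        (r, [c for c in range(layout.n_cols) if layout.cells[r][c].role != "empty"])
        for r in range(layout.n_rows)
        if any(cell.role != "empty" for cell in layout.cells[r])
    ]
    assigned: list[WellDetection] = []
    for (layout_row, cols), row_dets in zip(layout_rows, rows):
        row_dets = sorted(row_dets, key=lambda d: d.center_x)
        for col, det in zip(cols, row_dets):
            assigned.append(replace(det, grid_row=layout_row, grid_col=col))
    assigned.sort(key=lambda d: (d.grid_row, d.grid_col))
    return assigned
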