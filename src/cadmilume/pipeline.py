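"""End-to-end analysis: image -> detections -> colors -> calibration -> report.

The pipeline chains the stages deterministically: detect wells on the
channel-max image, assign them to the plate grid, measure each well's
background-subtracted color, fit the green/red-ratio calibration line on
the control + standard cells, and invert it for the sample cells.  A
failure confined to one well (saturation, undefined ratio) marks that
record ``invalid`` without aborting the run; only a calibration failure
is fatal, since nothing can be quantified without the line.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from . import __version__
from .calibration import (
    CalibrationModel,
    QuantResult,
    apply_concentration_factor,
    fit_calibration,
    mm_to_ppm,
    predict_concentration,
)
from .colorimetry import (
    BackgroundUnavailableError,
    chromatic_coords,
    estimate_background,
    extract_color,
)
from .errors import CadmilumeError, RatioUndefinedError
from .imaging import RasterImage, assign_grid, binarize, detect_wells, to_detection_channel
from .layout import PlateLayout


@dataclass
class AnalysisParams:
    """Tunable detection and measurement parameters."""

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    opening_radius: int = 1
    min_area: float = 100.0
    min_circularity: float = 0.6
    core_scale: float = 0.7
    annulus: tuple[float, float] = (1.2, 1.5)
    concentration_factor: float | None = None
    ppm_molar_mass: float | None = None  # set to report ppm


@dataclass
class WellRecord:
    """One row of the analysis report."""

    grid_row: int
    grid_col: int
    role: str
    label: str
    red: float | None = None
    green: float | None = None
    blue: float | None = None
    r: float | None = None
    g: float | None = None
    b: float | None = None
    ratio: float | None = None
    n_pixels: int | None = None
    saturated_fraction: float | None = None
    conc_mM: float | None = None
    se_mM: float | None = None
    flag: str = ""
    orig_conc_uM: float | None = None
    ppm: float | None = None
    error: str | None = None
    center_x: float | None = None
    center_y: float | None = None
    radius_px: float | None = None


@dataclass
class AnalysisReport:
    """Per-well records plus the calibration summary and provenance."""

    records: list[WellRecord]
    calibration: CalibrationModel
    provenance: dict = field(default_factory=dict)

    CSV_COLUMNS = (
        "row", "col", "role", "label", "ratio", "conc_mM", "se_mM", "flag",
        "orig_conc_uM", "ppm",
    )

    def sample_records(self) -> list[WellRecord]:
        return [rec for rec in self.records if rec.role == "sample"]

    def to_csv(self, path: Union[str, Path, None] = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(self.CSV_COLUMNS)
        for rec in self.records:
            writer.writerow([
                rec.grid_row, rec.grid_col, rec.role, rec.label,
                _fmt(rec.ratio), _fmt(rec.conc_mM), _fmt(rec.se_mM), rec.flag,
                _fmt(rec.orig_conc_uM), _fmt(rec.ppm),
            ])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "wells": [
                {k: v for k, v in vars(rec).items() if v is not None}
                for rec in self.records
            ],
            "calibration": json.loads(self.calibration.to_json()),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:.6g}"


def run_pipeline(
    image: RasterImage,
    layout: PlateLayout,
    params: AnalysisParams | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Analyze one plate photograph against a layout.

    Raises :class:`CadmilumeError` subclasses on detection/grid failures
    and on calibration failure; per-well measurement errors only flag the
    affected record.
    """
    params = params or AnalysisParams()
    channel = to_detection_channel(image)
    mask, threshold = binarize(
        channel,
        method=params.threshold_method,
        fixed_threshold=params.fixed_threshold,
        opening_radius=params.opening_radius,
    )
    detections = detect_wells(mask, min_area=params.min_area,
                              min_circularity=params.min_circularity)
    detections = assign_grid(detections, layout)

    records: list[WellRecord] = []
    measured: dict[tuple[int, int], float] = {}  # grid cell -> ratio
    for det in detections:
        cell = layout.cells[det.grid_row][det.grid_col]
        rec = WellRecord(
            grid_row=det.grid_row, grid_col=det.grid_col,
            role=cell.role, label=cell.label or "",
            center_x=det.center_x, center_y=det.center_y, radius_px=det.radius,
        )
        try:
            try:
                background = estimate_background(image, det, annulus=params.annulus,
                                                 all_wells=detections)
            except BackgroundUnavailableError:
                background = (0.0, 0.0, 0.0)
            meas = extract_color(image, det, background=background,
                                 core_scale=params.core_scale)
            rec.red, rec.green, rec.blue = meas.red, meas.green, meas.blue
            rec.n_pixels = meas.n_pixels
            rec.saturated_fraction = meas.saturated_fraction
            coords = chromatic_coords(meas)
            rec.r, rec.g, rec.b = coords.r, coords.g, coords.b
            rec.ratio = coords.green_red_ratio
            measured[(det.grid_row, det.grid_col)] = rec.ratio
        except RatioUndefinedError as exc:
            if exc.coords is not None:
                rec.r, rec.g, rec.b = exc.coords.r, exc.coords.g, exc.coords.b
            rec.flag = "invalid"
            rec.error = str(exc)
        except CadmilumeError as exc:
            rec.flag = "invalid"
            rec.error = str(exc)
        records.append(rec)

    cal_points = [
        (cell.calibration_conc, measured[(r, c)])
        for r, c, cell in layout.calibration_cells()
        if (r, c) in measured
    ]
    model = fit_calibration(cal_points)  # raises on calibration failure

    for rec in records:
        if rec.role != "sample" or rec.flag == "invalid":
            continue
        result = predict_concentration(model, rec.ratio, label=rec.label)
        if params.concentration_factor is not None:
            result = apply_concentration_factor(result, params.concentration_factor)
            rec.orig_conc_uM = result.orig_conc_uM
        rec.conc_mM = result.concentration
        rec.se_mM = result.std_error
        rec.flag = result.flag
        if params.ppm_molar_mass is not None and result.concentration >= 0:
            rec.ppm = mm_to_ppm(result.concentration, params.ppm_molar_mass)

    records.sort(key=lambda rec: (rec.grid_row, rec.grid_col))
    prov = dict(provenance or {})
    prov.setdefault("software_version", __version__)
    prov["threshold_used"] = threshold
    prov["params"] = {
        "threshold_method": params.threshold_method,
        "fixed_threshold": params.fixed_threshold,
        "opening_radius": params.opening_radius,
        "min_area": params.min_area,
        "min_circularity": params.min_circularity,
        "core_scale": params.core_scale,
        "annulus": list(params.annulus),
        "concentration_factor": params.concentration_factor,
        "ppm_molar_mass": params.ppm_molar_mass,
    }
    return AnalysisReport(records=records, calibration=model, provenance=prov)


def annotate_image(image: RasterImage, report: AnalysisReport,
                   path: Union[str, Path]) -> None:
    """Write a PNG overlay: well outlines plus the estimated mM per well."""
    from PIL import Image, ImageDraw

    if image.bit_depth == 8:
        base = image.pixels.astype("uint8")
    else:
        base = (image.pixels / 257.0).round().astype("uint8")
    im = Image.fromarray(base, mode="RGB")
    draw = ImageDraw.Draw(im)
    for rec in report.records:
        if rec.center_x is None:
            continue
        x, y, rad = rec.center_x, rec.center_y, rec.radius_px
        draw.ellipse([x - rad, y - rad, x + rad, y + rad], outline=(255, 255, 255))
        if rec.conc_mM is not None:
            text = f"{rec.conc_mM:.2f}"
        else:
            text = rec.label or rec.role[:4]
        draw.text((x - rad, y + rad + 2), text, fill=(255, 255, 0))
    im.save(path)
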