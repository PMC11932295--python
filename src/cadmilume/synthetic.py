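"""Seeded synthetic plate photographs with known per-well cadmium truth.

No raw plate photographs are distributed with the assay, so this module
renders physically motivated stand-ins: dark background, disk-shaped
luminescent wells whose color shifts green -> yellow -> orange with
cadmium concentration, imaged by an idealized RGB camera with Poisson
shot noise and Gaussian read noise.

Ground truth is defined in ratio space — the green/red ratio is linear in
concentration, rho(C) = ratio0 + ratio_slope * C — and the optional
spectral mode (a two-emitter Gaussian mixture, green peak plus red-shifted
peak) is fitted to that same line, so the generator satisfies the assay's
stated linearity exactly and calibration recovery is a sharp test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import SpecError
from .imaging import RasterImage
from .layout import PlateLayout, default_layout

#: Wavelength grid (nm) for the spectral mode.
WAVELENGTHS = np.arange(400.0, 701.0, 1.0)

#: Idealized camera channel sensitivity centers and common width (nm).
CAMERA_CENTERS = (610.0, 540.0, 460.0)  # R, G, B
CAMERA_WIDTH = 30.0


@dataclass
class EmissionModel:
    """Bioluminescence color model.

    The enzyme emits green light that red-shifts as cadmium binds; the
    default peaks (550 nm green, 610 nm red-shifted) are nominal values
    for a green firefly luciferase and its red form, and are configurable.
    ``ratio0`` and ``ratio_slope`` define the ground-truth line
    rho(C) = ratio0 + ratio_slope * C (per-mM slope, negative: green
    falls as cadmium rises).
    """

    lambda_green: float = 550.0
    lambda_red: float = 610.0
    sigma_peak: float = 30.0
    ratio0: float = 2.0
    ratio_slope: float = -0.75
    mode: str = "ratio_linear"  # or "spectral"

    def __post_init__(self):
        if self.lambda_green >= self.lambda_red:
            raise SpecError("green peak must be bluer than the red peak")
        if self.mode not in ("ratio_linear", "spectral"):
            raise SpecError(f"unknown emission mode {self.mode!r}")


def ratio_curve(concentration: float, emission: EmissionModel) -> float:
    """Ground-truth green/red ratio at a cadmium concentration (mM)."""
    if concentration < 0:
        raise SpecError("concentration must be >= 0")
    rho = emission.ratio0 + emission.ratio_slope * concentration
    if rho <= 0:
        raise SpecError(
            f"ratio {rho:.3g} at {concentration} mM is not positive; "
            "shrink the concentration range or the slope"
        )
    return rho


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def camera_sensitivities() -> np.ndarray:
    """(3, n_lambda) Gaussian channel sensitivities (peak 1) in RGB order."""
    return np.stack([_gauss(WAVELENGTHS, mu, CAMERA_WIDTH) for mu in CAMERA_CENTERS])


def _mixture_channels(alpha: float, emission: EmissionModel) -> np.ndarray:
    spec = emission_mixture(alpha, emission)
    return camera_sensitivities() @ spec  # 1 nm Riemann sum


def emission_mixture(alpha: float, emission: EmissionModel) -> np.ndarray:
    """Two-peak emission spectrum at mixing fraction alpha, unit total."""
    s = (1.0 - alpha) * _gauss(WAVELENGTHS, emission.lambda_green, emission.sigma_peak) \
        + alpha * _gauss(WAVELENGTHS, emission.lambda_red, emission.sigma_peak)
    return s / s.sum()


def solve_alpha(concentration: float, emission: EmissionModel) -> float:
    """Mixing fraction of the red-shifted emitter reproducing rho(C).

    Solves the monotone map alpha -> camera-integrated G/R ratio for the
    target ratio by root bracketing on [0, 1].
    """
    target = ratio_curve(concentration, emission)

    def f(alpha: float) -> float:
        ch = _mixture_channels(alpha, emission)
        return ch[1] / ch[0] - target

    lo, hi = f(0.0), f(1.0)
    if lo < 0 or hi > 0:
        raise SpecError(
            f"target ratio {target:.3g} outside the camera gamut "
            f"[{_ratio_at(1.0, emission):.3g}, {_ratio_at(0.0, emission):.3g}] "
            "for these emission peaks"
        )
    if lo == 0:
        return 0.0
    return float(brentq(f, 0.0, 1.0, xtol=1e-12))


def _ratio_at(alpha: float, emission: EmissionModel) -> float:
    ch = _mixture_channels(alpha, emission)
    return float(ch[1] / ch[0])


def emission_spectrum(concentration: float, emission: EmissionModel) -> np.ndarray:
    """Spectrum on the 400-700 nm, 1 nm grid whose camera G/R equals rho(C)."""
    if emission.mode != "spectral":
        raise SpecError("emission_spectrum requires mode='spectral'")
    return emission_mixture(solve_alpha(concentration, emission), emission)


@dataclass
class SyntheticPlateSpec:
    """Full generative description of one plate photograph.

    Geometry is in pixels; ``exposure`` sets the red-channel (ratio_linear
    mode) or overall (spectral mode) brightness in counts; the noise model
    is the standard CCD pair of Poisson shot noise (``photon_gain`` counts
    per photon-equivalent; 0 disables it) and Gaussian read noise
    (``read_sd`` counts; 0 disables it).  Identical spec + seed gives a
    bit-identical image.
    """

    layout: PlateLayout = field(default_factory=default_layout)
    sample_concs_mM: tuple[float, ...] = (0.5, 1.0, 1.5)
    emission: EmissionModel = field(default_factory=EmissionModel)
    well_radius: float = 18.0
    pitch: float = 60.0
    origin: tuple[float, float] = (40.0, 40.0)  # (x, y) of cell (0, 0)
    rotation_deg: float = 0.0
    center_jitter: float = 1.0
    exposure: float = 90.0
    photon_gain: float = 1.0
    read_sd: float = 2.0
    background_level: float = 5.0
    image_size: tuple[int, int] = (144, 560)  # (height, width)
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.pitch < 3.0 * self.well_radius:
            raise SpecError("pitch must be >= 3x well radius so wells never overlap")
        n_samples = len(self.layout.sample_cells())
        if len(self.sample_concs_mM) != n_samples:
            raise SpecError(
                f"{n_samples} sample cells but {len(self.sample_concs_mM)} sample concentrations"
            )
        h, w = self.image_size
        for _, _, _, x, y in self.well_positions():
            if not (self.well_radius <= x <= w - self.well_radius
                    and self.well_radius <= y <= h - self.well_radius):
                raise SpecError(f"well at ({x:.1f}, {y:.1f}) not fully inside the frame")
        for conc in self.truth_concentrations().values():
            ratio_curve(conc, self.emission)  # ratio must stay positive

    def well_positions(self) -> list[tuple[int, int, object, float, float]]:
        """(row, col, role, x, y) for every occupied cell, before jitter."""
        h, w = self.image_size
        cx0, cy0 = w / 2.0, h / 2.0
        theta = np.deg2rad(self.rotation_deg)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        out = []
        for r, c, cell in self.layout.occupied():
            x = self.origin[0] + c * self.pitch
            y = self.origin[1] + r * self.pitch
            xr = cx0 + (x - cx0) * cos_t - (y - cy0) * sin_t
            yr = cy0 + (x - cx0) * sin_t + (y - cy0) * cos_t
            out.append((r, c, cell, xr, yr))
        return out

    def truth_concentrations(self) -> dict[tuple[int, int], float]:
        """Per-well true cadmium concentration (mM), keyed by grid cell."""
        concs: dict[tuple[int, int], float] = {}
        samples = iter(self.sample_concs_mM)
        for r, c, cell in self.layout.occupied():
            if cell.is_calibration:
                concs[(r, c)] = cell.calibration_conc
            else:
                concs[(r, c)] = float(next(samples))
        return concs

    def spec_hash(self) -> str:
        """Stable short hash identifying this spec (provenance)."""
        payload = json.dumps(
            {
                "layout": self.layout.to_dict(),
                "sample_concs_mM": list(self.sample_concs_mM),
                "emission": vars(self.emission),
                "geometry": [self.well_radius, self.pitch, list(self.origin),
                             self.rotation_deg, self.center_jitter],
                "camera": [self.exposure, self.photon_gain, self.read_sd,
                           self.background_level, list(self.image_size), self.bit_depth],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def expected_rgb(concentration: float, spec: SyntheticPlateSpec) -> tuple[float, float, float]:
    """Noiseless peak RGB (counts) for a well at the given concentration.

    In ratio_linear mode R = exposure, G = exposure * rho(C), and blue is
    a fixed 10% floor; in spectral mode each channel integrates the fitted
    emission spectrum against the camera sensitivities.  Both modes give
    G/R = rho(C) by construction.
    """
    rho = ratio_curve(concentration, spec.emission)
    if spec.emission.mode == "ratio_linear":
        return (spec.exposure, spec.exposure * rho, 0.1 * spec.exposure)
    s = emission_spectrum(concentration, spec.emission)
    ch = camera_sensitivities() @ s
    return tuple(float(spec.exposure * v) for v in ch)


def _radial_profile(dist: np.ndarray, radius: float) -> np.ndarray:
    """Flat core to 0.8 r, cosine falloff to the rim, zero outside."""
    prof = np.zeros_like(dist)
    core = dist <= 0.8 * radius
    edge = (dist > 0.8 * radius) & (dist <= radius)
    prof[core] = 1.0
    prof[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - 0.8 * radius) / (0.2 * radius)))
    return prof


def render_plate(spec: SyntheticPlateSpec) -> tuple[RasterImage, pd.DataFrame]:
    """Render the plate photograph and return it with its truth table.

    The truth table has one row per occupied cell: grid index, role,
    label, true concentration, true ratio, and the noiseless peak RGB.
    All randomness (center jitter, shot noise, read noise) comes from a
    single generator seeded with ``spec.seed``.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w, 3), float(spec.background_level))
    yy, xx = np.mgrid[0:h, 0:w]

    truth_rows = []
    concs = spec.truth_concentrations()
    for r, c, cell, x, y in spec.well_positions():
        if spec.center_jitter > 0:
            x += rng.uniform(-spec.center_jitter, spec.center_jitter)
            y += rng.uniform(-spec.center_jitter, spec.center_jitter)
        conc = concs[(r, c)]
        rgb = expected_rgb(conc, spec)
        dist = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
        prof = _radial_profile(dist, spec.well_radius)
        img += prof[:, :, None] * np.asarray(rgb)
        truth_rows.append(
            {
                "grid_row": r,
                "grid_col": c,
                "role": cell.role,
                "label": cell.label or "",
                "conc_mM": conc,
                "true_ratio": ratio_curve(conc, spec.emission),
                "R0": rgb[0],
                "G0": rgb[1],
                "B0": rgb[2],
            }
        )

    if spec.photon_gain > 0:
        img = rng.poisson(img / spec.photon_gain) * spec.photon_gain
    if spec.read_sd > 0:
        img = img + rng.normal(0.0, spec.read_sd, size=img.shape)

    max_val = (1 << spec.bit_depth) - 1
    quantized = np.clip(np.rint(img), 0, max_val)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = RasterImage(quantized.astype(dtype), bit_depth=spec.bit_depth)
    truth = pd.DataFrame(truth_rows).sort_values(["grid_row", "grid_col"]).reset_index(drop=True)
    return image, truth


def spec_from_json(config: dict) -> SyntheticPlateSpec:
    """Build a spec from a parsed JSON config (CLI entry point).

    Recognized keys mirror the dataclass fields; ``layout`` may be an
    inline layout object.  Unknown keys raise a spec error.
    """
    from .layout import parse_layout

    cfg = dict(config)
    kwargs = {}
    if "layout" in cfg:
        kwargs["layout"] = parse_layout(cfg.pop("layout"))
    if "emission" in cfg:
        kwargs["emission"] = EmissionModel(**cfg.pop("emission"))
    for key in ("sample_concs_mM", "origin", "image_size"):
        if key in cfg:
            kwargs[key] = tuple(cfg.pop(key))
    scalar_keys = ("well_radius", "pitch", "rotation_deg", "center_jitter", "exposure",
                   "photon_gain", "read_sd", "background_level", "bit_depth", "seed")
    for key in scalar_keys:
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if cfg:
        raise SpecError(f"unknown synthetic-plate config keys: {sorted(cfg)}")
    return SyntheticPlateSpec(**kwargs)
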