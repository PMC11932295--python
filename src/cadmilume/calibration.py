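"""Linear ratio-vs-concentration calibration and inverse prediction.

The assay is ratiometric: the green/red luminescence ratio rho falls
linearly with cadmium concentration C over the working range, so the
standards row fits an ordinary-least-squares line

    rho = beta0 + beta1 * C,      beta1 < 0

and an unknown well's concentration is read off the inverted line,
C_hat = (rho - beta0) / beta1, with the classical inverse-prediction
(delta-method) standard error

    se(C_hat) = (s / |beta1|) * sqrt(1 + 1/n + (rho - rho_bar)^2 / (beta1^2 * Sxx))

where s is the residual standard deviation and Sxx = sum (C_i - C_bar)^2.
Estimates outside the standards' range are flagged, never clamped.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import InputError, InsufficientCalibrationError, NonMonotoneCalibrationError

#: Molar masses (g/mol) for the ppm conversion bases.
MOLAR_MASS_CDSO4 = 208.47
MOLAR_MASS_CD = 112.41


@dataclass
class CalibrationModel:
    """Fitted line rho = beta0 + beta1*C with inverse-prediction diagnostics."""

    beta0: float
    beta1: float
    r_squared: float
    residual_sd: float
    n_points: int
    conc_range: tuple[float, float]
    mean_ratio: float
    sxx: float

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        d = asdict(self)
        d["conc_range"] = list(self.conc_range)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CalibrationModel":
        if isinstance(source, Path) or source.strip().endswith(".json"):
            source = Path(source).read_text()
        d = json.loads(source)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


@dataclass
class QuantResult:
    """Concentration estimate for one well, with range flag."""

    concentration: float  # mM (in-well)
    std_error: float  # mM
    flag: str  # in_range | below_range | above_range | invalid
    well_label: str = ""
    orig_conc_uM: float | None = None  # pre-concentration, after factor division
    orig_se_uM: float | None = None


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of ratio on concentration.

    ``points`` are (concentration mM, green/red ratio) pairs from the
    control and standard wells; replicates at one concentration are
    legitimate and enter individually.  Requires >= 3 points spanning
    >= 2 distinct concentrations, and a strictly negative slope — a flat
    or rising fit means the assay failed or wells are mislabeled.
    """
    pts = [(float(c), float(r)) for c, r in points]
    if any(c < 0 for c, _ in pts):
        raise InputError("calibration concentrations must be >= 0")
    n = len(pts)
    if n < 3:
        raise InsufficientCalibrationError(f"need >= 3 calibration points, got {n}")
    conc = np.array([c for c, _ in pts])
    ratio = np.array([r for _, r in pts])
    if np.unique(conc).size < 2:
        raise InsufficientCalibrationError("all calibration concentrations are equal")

    cbar, rbar = conc.mean(), ratio.mean()
    sxx = float(np.sum((conc - cbar) ** 2))
    beta1 = float(np.sum((conc - cbar) * (ratio - rbar)) / sxx)
    beta0 = float(rbar - beta1 * cbar)
    if beta1 >= 0:
        raise NonMonotoneCalibrationError(
            f"fitted slope {beta1:.4g} is not negative: the green/red ratio must "
            "decrease with cadmium (check well labeling and assay viability)"
        )
    resid = ratio - (beta0 + beta1 * conc)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((ratio - rbar) ** 2))
    r_squared = 1.0 if sst == 0 else 1.0 - sse / sst
    residual_sd = math.sqrt(sse / (n - 2))
    return CalibrationModel(
        beta0=beta0,
        beta1=beta1,
        r_squared=min(max(r_squared, 0.0), 1.0),
        residual_sd=residual_sd,
        n_points=n,
        conc_range=(float(conc.min()), float(conc.max())),
        mean_ratio=float(rbar),
        sxx=sxx,
    )


def predict_concentration(model: CalibrationModel, ratio: float, label: str = "") -> QuantResult:
    """Invert the calibration line for one observed ratio.

    Out-of-range estimates keep their value but carry a ``below_range`` /
    ``above_range`` flag; a non-finite ratio yields ``invalid`` with a NaN
    concentration.
    """
    if not math.isfinite(ratio):
        return QuantResult(float("nan"), float("nan"), "invalid", label)
    c_hat = (ratio - model.beta0) / model.beta1
    se = (model.residual_sd / abs(model.beta1)) * math.sqrt(
        1.0 + 1.0 / model.n_points
        + (ratio - model.mean_ratio) ** 2 / (model.beta1**2 * model.sxx)
    )
    c_min, c_max = model.conc_range
    if c_hat < c_min:
        flag = "below_range"
    elif c_hat > c_max:
        flag = "above_range"
    else:
        flag = "in_range"
    return QuantResult(c_hat, se, flag, label)


def apply_concentration_factor(result: QuantResult, factor: float) -> QuantResult:
    """Back-calculate the original-sample concentration before evaporation.

    Dilute samples are enriched by a known fold-factor (10 to 10,000x by
    evaporation) before assay; dividing the in-well estimate by the factor
    recovers the original concentration, reported in uM.
    """
    if factor <= 0:
        raise InputError(f"concentration factor must be > 0, got {factor}")
    orig_mm = result.concentration / factor
    orig_se = result.std_error / factor
    return QuantResult(
        concentration=result.concentration,
        std_error=result.std_error,
        flag=result.flag,
        well_label=result.well_label,
        orig_conc_uM=orig_mm * 1000.0,
        orig_se_uM=orig_se * 1000.0,
    )


def mm_to_ppm(concentration_mM: float, molar_mass: float = MOLAR_MASS_CDSO4) -> float:
    """Convert molarity (mM) to mass concentration (ppm = mg/L).

    ppm = mM * molar mass (g/mol).  Default basis is CdSO4 (208.47 g/mol),
    the salt the standards are made from; elemental cadmium (112.41 g/mol)
    is available for comparison with regulatory limits.
    """
    if concentration_mM < 0:
        raise InputError("concentration must be >= 0")
    if molar_mass <= 0:
        raise InputError("molar mass must be > 0")
    return concentration_mM * molar_mass
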