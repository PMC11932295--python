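"""Plate-layout model and its JSON serialization.

A layout names every cell of the plate grid: water control, cadmium
standard (with its concentration in mM), unknown sample, or empty.  The
shipped default mirrors the assay convention: the upper row carries the
water control followed by the cadmium sulfate standards, the lower row
carries the unknown samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import ConfigError

#: Cadmium sulfate standard series (mM) used for the calibration row.
STANDARDS_MM = (0.1, 0.25, 0.5, 0.6, 0.8, 1.0, 1.5, 2.0)

VALID_ROLES = {"control", "standard", "sample", "empty"}


@dataclass(frozen=True)
class WellRole:
    """Role of one grid cell.

    ``conc_mM`` is required (finite, >= 0) for standards; ``label`` is a
    free-text sample identifier (defaults to S<n> when parsed).
    """

    role: str
    conc_mM: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ConfigError(f"unknown role {self.role!r}")
        if self.role == "standard":
            if self.conc_mM is None or not math.isfinite(self.conc_mM) or self.conc_mM < 0:
                raise ConfigError(
                    f"standard role requires a finite concentration >= 0, got {self.conc_mM!r}"
                )

    @property
    def is_calibration(self) -> bool:
        return self.role in ("control", "standard")

    @property
    def calibration_conc(self) -> float:
        """Concentration used when this cell enters the calibration fit."""
        return 0.0 if self.role == "control" else float(self.conc_mM)


EMPTY = WellRole("empty")


@dataclass
class PlateLayout:
    """Grid of well roles.

    ``cells[row][col]`` is a :class:`WellRole`.  At least three cells must
    be calibration cells (control or standard) — the minimum for fitting
    the ratio-vs-concentration line.
    """

    n_rows: int
    n_cols: int
    cells: list[list[WellRole]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("layout must have at least one row and column")
        if len(self.cells) != self.n_rows or any(len(r) != self.n_cols for r in self.cells):
            raise ConfigError("cells grid does not match declared n_rows x n_cols")

    # -- queries ---------------------------------------------------------

    def occupied(self) -> list[tuple[int, int, WellRole]]:
        """All non-empty cells in row-major order."""
        return [
            (r, c, cell)
            for r, row in enumerate(self.cells)
            for c, cell in enumerate(row)
            if cell.role != "empty"
        ]

    def n_occupied(self) -> int:
        return len(self.occupied())

    def row_occupancy(self) -> list[int]:
        """Number of non-empty cells per row, top to bottom."""
        return [sum(1 for c in row if c.role != "empty") for row in self.cells]

    def calibration_cells(self) -> list[tuple[int, int, WellRole]]:
        return [(r, c, cell) for r, c, cell in self.occupied() if cell.is_calibration]

    def sample_cells(self) -> list[tuple[int, int, WellRole]]:
        return [(r, c, cell) for r, c, cell in self.occupied() if cell.role == "sample"]

    @property
    def standards_mM(self) -> list[float]:
        return [cell.calibration_conc for _, _, cell in self.calibration_cells()]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        cells = []
        for r, c, cell in self.occupied():
            d: dict = {"row": r, "col": c, "role": cell.role}
            if cell.conc_mM is not None:
                d["conc_mM"] = cell.conc_mM
            if cell.label is not None:
                d["label"] = cell.label
            cells.append(d)
        return {"n_rows": self.n_rows, "n_cols": self.n_cols, "cells": cells}

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def parse_layout(config: Union[str, Path, dict]) -> PlateLayout:
    """Build a validated :class:`PlateLayout` from JSON text, a file path,
    or an already-parsed mapping.

    Raises :class:`ConfigError` naming the offending cell on an unknown
    role tag, a standard without a concentration, or a duplicated cell.
    """
    if isinstance(config, Path) or (isinstance(config, str) and "\n" not in config
                                    and config.strip().endswith(".json")):
        config = json.loads(Path(config).read_text())
    elif isinstance(config, str):
        config = json.loads(config)
    if not isinstance(config, dict):
        raise ConfigError("layout config must be a JSON object")

    try:
        n_rows = int(config["n_rows"])
        n_cols = int(config["n_cols"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"layout config needs integer n_rows/n_cols: {exc}") from exc

    grid = [[EMPTY for _ in range(n_cols)] for _ in range(n_rows)]
    seen: set[tuple[int, int]] = set()
    n_samples = 0
    for entry in config.get("cells", []):
        try:
            r, c = int(entry["row"]), int(entry["col"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"cell entry missing row/col: {entry!r}") from exc
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ConfigError(f"cell ({r}, {c}) outside {n_rows}x{n_cols} grid")
        if (r, c) in seen:
            raise ConfigError(f"cell ({r}, {c}) declared twice")
        seen.add((r, c))
        role = entry.get("role")
        if role not in VALID_ROLES:
            raise ConfigError(f"cell ({r}, {c}): unknown role {role!r}")
        label = entry.get("label")
        if role == "sample":
            n_samples += 1
            if label is None:
                label = f"S{n_samples}"
        conc = entry.get("conc_mM")
        if role == "standard" and conc is None:
            raise ConfigError(f"cell ({r}, {c}): standard role without conc_mM")
        try:
            grid[r][c] = WellRole(role, None if conc is None else float(conc), label)
        except ConfigError as exc:
            raise ConfigError(f"cell ({r}, {c}): {exc}") from exc

    layout = PlateLayout(n_rows, n_cols, grid)
    # a parsed analysis layout must be able to support a calibration fit;
    # bare geometric layouts built in code are exempt (fit errors later anyway)
    if len(layout.calibration_cells()) < 3:
        raise ConfigError("layout needs at least 3 control/standard cells for calibration")
    return layout


def default_layout(n_samples: int = 3) -> PlateLayout:
    """The shipped two-row layout.

    Row 0: water control (0 mM) then the eight cadmium standards
    (0.1-2 mM).  Row 1: ``n_samples`` unknown sample wells, left-aligned,
    labeled S1, S2, ...
    """
    if not 1 <= n_samples <= len(STANDARDS_MM) + 1:
        raise ConfigError("n_samples must be between 1 and 9 for the default layout")
    n_cols = len(STANDARDS_MM) + 1
    top = [WellRole("control", 0.0)] + [WellRole("standard", c) for c in STANDARDS_MM]
    bottom = [WellRole("sample", label=f"S{i + 1}") for i in range(n_samples)]
    bottom += [EMPTY] * (n_cols - n_samples)
    return PlateLayout(2, n_cols, [top, bottom])
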