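"""Haemoglobin extinction-coefficient spectra and wavelength-grid utilities.

The absorption model unmixes an inferred tissue absorption spectrum into
oxygenated (HbO2) and deoxygenated (Hb) haemoglobin contributions; this module
houses the molar extinction coefficients ``eps_hbo2(lambda)`` and
``eps_hb(lambda)`` it needs, on an explicit wavelength grid.

The bundled default table (``data/hb_extinction_synthetic.csv``) is a synthetic
reconstruction of the standard literature compilations of the oxy/deoxy
haemoglobin spectra in water: a monotone interpolation through anchor values
(band peaks, isosbestic crossings, end points) at 1 nm spacing over
500–600 nm. It reproduces the qualitative band structure (HbO2 beta/alpha
bands near 542/577 nm, the single broad Hb band near 555 nm, isosbestic
points near 548/569/586 nm) but is approximate; because StO2 depends only on
the *ratio* of the fitted amplitudes, it is adequate for uncalibrated
saturation work. Users needing calibrated coefficients can point
:func:`load_extinction_table` at their own file in the same CSV dialect
(header ``wavelength_nm,eps_hbo2,eps_hb``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CoverageError,
    GridOrderError,
    GridRangeError,
    MalformedFileError,
)

#: Wavelength range (nm) a grid may span.
ADMISSIBLE_RANGE_NM = (400.0, 1000.0)
#: Wavelength window (nm) used for model fitting.
FIT_WINDOW_NM = (500.0, 600.0)
#: Maximum tabulation spacing (nm) an extinction table may have inside the window.
MAX_TABLE_SPACING_NM = 2.0

DEFAULT_TABLE = "default"
_DEFAULT_RESOURCE = "hb_extinction_synthetic.csv"


def validate_grid(wavelengths) -> np.ndarray:
    """Validate and return a wavelength grid as a float array.

    Raises :class:`GridOrderError` if not strictly increasing and
    :class:`GridRangeError` if any value lies outside 400–1000 nm.
    """
    grid = np.asarray(wavelengths, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise GridOrderError("wavelength grid must be a non-empty 1-D sequence")
    if not np.all(np.diff(grid) > 0):
        raise GridOrderError("wavelengths must be strictly increasing")
    lo, hi = ADMISSIBLE_RANGE_NM
    if grid[0] < lo or grid[-1] > hi:
        raise GridRangeError(
            f"wavelengths must lie within [{lo:g}, {hi:g}] nm, "
            f"got [{grid[0]:g}, {grid[-1]:g}]"
        )
    return grid


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and Hb on a wavelength grid.

    Coefficients are in L mol^-1 cm^-1 and must be strictly positive over the
    fitting window; both coefficient arrays share the grid's length.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    source: str = field(default="unspecified")

    def __post_init__(self):
        grid = validate_grid(self.wavelengths)
        hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        hb = np.asarray(self.eps_hb, dtype=float)
        if hbo2.shape != grid.shape or hb.shape != grid.shape:
            raise MalformedFileError(
                "extinction coefficient columns must match the grid length"
            )
        lo, hi = FIT_WINDOW_NM
        win = (grid >= lo) & (grid <= hi)
        if win.any() and (np.any(hbo2[win] <= 0) or np.any(hb[win] <= 0)):
            raise MalformedFileError(
                "extinction coefficients must be strictly positive over "
                f"[{lo:g}, {hi:g}] nm"
            )
        object.__setattr__(self, "wavelengths", grid)
        object.__setattr__(self, "eps_hbo2", hbo2)
        object.__setattr__(self, "eps_hb", hb)

    def __len__(self) -> int:
        return self.wavelengths.size

    def covers(self, window=FIT_WINDOW_NM) -> bool:
        return self.wavelengths[0] <= window[0] and self.wavelengths[-1] >= window[1]


def _default_table_path() -> Path:
    return Path(importlib.resources.files("oxispec") / "data" / _DEFAULT_RESOURCE)


def load_extinction_table(source: str | Path = DEFAULT_TABLE) -> ExtinctionTable:
    """Load an extinction table from the packaged default or a user CSV.

    ``source`` is either the literal ``"default"`` (the bundled synthetic
    reconstruction of the standard Hb compilations) or a path to a CSV file in
    the dialect ``wavelength_nm,eps_hbo2,eps_hb`` (``#`` comments allowed).

    The loaded table must cover at least 500–600 nm at <= 2 nm spacing.
    """
    if isinstance(source, str) and source == DEFAULT_TABLE:
        path = _default_table_path()
        label = f"packaged:{_DEFAULT_RESOURCE}"
    else:
        path = Path(source)
        label = str(path)
    if not path.exists():
        raise FileNotFoundError(f"extinction table not found: {path}")

    wavelengths, hbo2, hb = [], [], []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line.replace(" ", "") != "wavelength_nm,eps_hbo2,eps_hb":
                    raise MalformedFileError(
                        f"{path}:{lineno}: expected header "
                        "'wavelength_nm,eps_hbo2,eps_hb'"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise MalformedFileError(f"{path}:{lineno}: expected 3 columns")
            try:
                w, a, b = (float(p) for p in parts)
            except ValueError as exc:
                raise MalformedFileError(f"{path}:{lineno}: non-numeric row") from exc
            wavelengths.append(w)
            hbo2.append(a)
            hb.append(b)
    if not header_seen or not wavelengths:
        raise MalformedFileError(f"{path}: no data rows")

    table = ExtinctionTable(
        np.array(wavelengths), np.array(hbo2), np.array(hb), source=label
    )
    lo, hi = FIT_WINDOW_NM
    if not table.covers():
        raise CoverageError(
            f"extinction table must cover [{lo:g}, {hi:g}] nm, "
            f"got [{table.wavelengths[0]:g}, {table.wavelengths[-1]:g}]"
        )
    win = (table.wavelengths >= lo) & (table.wavelengths <= hi)
    spacing = np.diff(table.wavelengths[win])
    if spacing.size and spacing.max() > MAX_TABLE_SPACING_NM:
        raise CoverageError(
            f"extinction table spacing exceeds {MAX_TABLE_SPACING_NM:g} nm "
            f"within [{lo:g}, {hi:g}] nm"
        )
    return table


def resample_extinction(table: ExtinctionTable, target) -> ExtinctionTable:
    """Linearly interpolate an extinction table onto ``target`` wavelengths.

    Linear (not spline) interpolation keeps every interpolated coefficient
    within the bracketing tabulated values, which matters near the sharp
    haemoglobin bands. Extrapolation is refused.
    """
    grid = validate_grid(target)
    if grid[0] < table.wavelengths[0] or grid[-1] > table.wavelengths[-1]:
        raise GridRangeError(
            "target grid "
            f"[{grid[0]:g}, {grid[-1]:g}] nm extends beyond table coverage "
            f"[{table.wavelengths[0]:g}, {table.wavelengths[-1]:g}] nm"
        )
    return ExtinctionTable(
        grid,
        np.interp(grid, table.wavelengths, table.eps_hbo2),
        np.interp(grid, table.wavelengths, table.eps_hb),
        source=table.source,
    )
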