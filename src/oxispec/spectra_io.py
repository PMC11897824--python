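"""Spectrum and time-series containers with their text I/O dialects.

File dialects (all UTF-8, LF, ``.`` decimal separator):

* Spectrum CSV — optional ``# key: value`` comment header (keys ``kind``,
  ``timestamp_s``, ``integration_s``, ``site``, ``notes``), then a
  ``wavelength_nm,value`` table sorted by increasing wavelength.
* StO2 series CSV — ``time_s,sto2,flag``.
* RBFi series CSV — ``time_s,rbfi``.
* Site table CSV — ``time_s,site,sto2`` (long format, one row per probe site).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .chromophores import FIT_WINDOW_NM, validate_grid
from .errors import (
    AlignmentError,
    MalformedFileError,
    SpectrumValidationError,
)

SPECTRUM_KINDS = ("reflectance", "reference", "absorbance")
SITES = ("hilum", "superior", "lateral", "inferior")

#: Per-sample quality flags.
FLAG_OK = "ok"
FLAG_AMBIENT = "ambient-light"
FLAG_SLIP = "probe-slip"
FLAG_FIT_FAILED = "fit-failed"
FLAGS = (FLAG_OK, FLAG_AMBIENT, FLAG_SLIP, FLAG_FIT_FAILED)


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata attached to a spectrum."""

    timestamp_s: float | None = None
    integration_s: float | None = None
    site: str | None = None
    notes: str | None = None

    def __post_init__(self):
        if self.integration_s is not None and not self.integration_s > 0:
            raise SpectrumValidationError("integration time must be > 0 s")
        if self.site is not None and self.site not in SITES:
            raise SpectrumValidationError(
                f"site must be one of {SITES}, got {self.site!r}"
            )


@dataclass(frozen=True)
class Spectrum:
    """A per-wavelength record: raw counts or inferred absorbance.

    ``kind`` is one of ``reflectance`` / ``reference`` / ``absorbance``;
    reflectance and reference values (detector counts) must be non-negative.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self):
        grid = validate_grid(self.wavelengths)
        values = np.asarray(self.values, dtype=float)
        if values.shape != grid.shape:
            raise SpectrumValidationError("values must match the grid length")
        if self.kind not in SPECTRUM_KINDS:
            raise SpectrumValidationError(
                f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}"
            )
        if self.kind in ("reflectance", "reference") and np.any(values < 0):
            raise SpectrumValidationError(f"{self.kind} values must be >= 0")
        if not np.all(np.isfinite(values)):
            raise SpectrumValidationError("values must be finite")
        object.__setattr__(self, "wavelengths", grid)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.wavelengths.size

    def restricted(self, window=FIT_WINDOW_NM) -> "Spectrum":
        """Return the spectrum restricted to a wavelength window."""
        lo, hi = window
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise AlignmentError(f"spectrum has no samples in [{lo:g}, {hi:g}] nm")
        return replace(self, wavelengths=self.wavelengths[mask], values=self.values[mask])


@dataclass(frozen=True)
class StO2Series:
    """Timestamped StO2 estimates with per-sample quality flags.

    Times are seconds from perfusion start (negative allowed for pre-perfusion
    acquisitions). Saturations are fractions in [0, 1] wherever the flag is
    ``ok``; failed fits carry NaN with flag ``fit-failed``.
    """

    times: np.ndarray
    sto2: np.ndarray
    flags: tuple[str, ...]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        sto2 = np.asarray(self.sto2, dtype=float)
        flags = tuple(self.flags)
        if times.ndim != 1 or times.shape != sto2.shape or len(flags) != times.size:
            raise SpectrumValidationError("times, sto2 and flags must align")
        if times.size and not np.all(np.diff(times) > 0):
            raise SpectrumValidationError("times must be strictly increasing")
        bad = [f for f in flags if f not in FLAGS]
        if bad:
            raise SpectrumValidationError(f"unknown flags: {sorted(set(bad))}")
        ok = np.array([f == FLAG_OK for f in flags])
        if ok.any() and (
            np.any(sto2[ok] < 0) or np.any(sto2[ok] > 1) or np.any(~np.isfinite(sto2[ok]))
        ):
            raise SpectrumValidationError("ok-flagged sto2 must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sto2", sto2)
        object.__setattr__(self, "flags", flags)

    def __len__(self) -> int:
        return self.times.size

    def ok_mask(self) -> np.ndarray:
        return np.array([f == FLAG_OK for f in self.flags], dtype=bool)


@dataclass(frozen=True)
class RBFiSeries:
    """Renal blood flow index readings from the perfusion rig (arbitrary units)."""

    times: np.ndarray
    rbfi: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rbfi = np.asarray(self.rbfi, dtype=float)
        if times.ndim != 1 or times.shape != rbfi.shape:
            raise SpectrumValidationError("times and rbfi must align")
        if times.size and not np.all(np.diff(times) > 0):
            raise SpectrumValidationError("times must be strictly increasing")
        if np.any(rbfi < 0):
            raise SpectrumValidationError("rbfi must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rbfi", rbfi)

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# spectrum CSV dialect

_META_KEYS = ("kind", "timestamp_s", "integration_s", "site", "notes")


def read_spectrum(path: str | Path, kind: str | None = None) -> Spectrum:
    """Read a spectrum from the two-column CSV dialect.

    ``kind`` overrides (or supplies, when the header lacks it) the spectrum
    kind; a conflict between the two is an error.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        column_line_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in _META_KEYS:
                        header[key] = value.strip()
                continue
            if not column_line_seen:
                if line.replace(" ", "") != "wavelength_nm,value":
                    raise MalformedFileError(
                        f"{path}:{lineno}: expected column header 'wavelength_nm,value'"
                    )
                column_line_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise MalformedFileError(f"{path}:{lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise MalformedFileError(f"{path}:{lineno}: non-numeric row") from exc
    if not rows:
        raise MalformedFileError(f"{path}: no data rows")

    file_kind = header.get("kind")
    if kind is None:
        kind = file_kind
    elif file_kind is not None and file_kind != kind:
        raise SpectrumValidationError(
            f"{path}: header kind {file_kind!r} conflicts with requested {kind!r}"
        )
    if kind is None:
        raise SpectrumValidationError(f"{path}: spectrum kind not given")

    meta = SpectrumMeta(
        timestamp_s=float(header["timestamp_s"]) if "timestamp_s" in header else None,
        integration_s=float(header["integration_s"]) if "integration_s" in header else None,
        site=header.get("site"),
        notes=header.get("notes"),
    )
    wl, vals = zip(*rows)
    return Spectrum(np.array(wl), np.array(vals), kind=kind, meta=meta)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum in the two-column CSV dialect; inverse of read_spectrum."""
    path = Path(path)
    meta = spectrum.meta
    lines = [f"# kind: {spectrum.kind}"]
    if meta.timestamp_s is not None:
        lines.append(f"# timestamp_s: {meta.timestamp_s:.6g}")
    if meta.integration_s is not None:
        lines.append(f"# integration_s: {meta.integration_s:.6g}")
    if meta.site is not None:
        lines.append(f"# site: {meta.site}")
    if meta.notes is not None:
        lines.append(f"# notes: {meta.notes}")
    lines.append("wavelength_nm,value")
    for w, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{w:.6g},{v:.8g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def align_grids(
    a: Spectrum, b: Spectrum, tolerance_nm: float = 0.5
) -> tuple[Spectrum, Spectrum]:
    """Bring two spectra onto a common grid covering the fitting window.

    If the grids agree pointwise to ``tolerance_nm`` on their overlap they are
    simply cropped; otherwise the coarser spectrum's grid is kept and the
    other is linearly interpolated onto it. Both outputs share one grid.
    """
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    wlo, whi = FIT_WINDOW_NM
    if lo > wlo or hi < whi:
        raise AlignmentError(
            f"spectra overlap [{lo:g}, {hi:g}] nm does not cover "
            f"[{wlo:g}, {whi:g}] nm"
        )

    ga = a.wavelengths[(a.wavelengths >= lo) & (a.wavelengths <= hi)]
    gb = b.wavelengths[(b.wavelengths >= lo) & (b.wavelengths <= hi)]
    if ga.size == gb.size and np.max(np.abs(ga - gb)) <= tolerance_nm:
        # same sampling to within tolerance: keep a's grid, interpolate b if needed
        target = ga
    else:
        # coarser grid = larger mean spacing
        target = ga if np.mean(np.diff(ga)) >= np.mean(np.diff(gb)) else gb

    def onto(s: Spectrum) -> Spectrum:
        if s.wavelengths.size == target.size and np.array_equal(
            s.wavelengths[(s.wavelengths >= lo) & (s.wavelengths <= hi)], target
        ):
            return s.restricted((lo, hi))
        vals = np.interp(target, s.wavelengths, s.values)
        return replace(s, wavelengths=target, values=vals)

    return onto(a), onto(b)


# ---------------------------------------------------------------------------
# series CSV dialects (pandas-backed; simple rectangular tables)


def write_sto2_series(series: StO2Series, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": series.times, "sto2": series.sto2, "flag": list(series.flags)}
    )
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.8g")
    return path


def read_sto2_series(path: str | Path) -> StO2Series:
    df = _read_table(path, ["time_s", "sto2", "flag"])
    return StO2Series(
        df["time_s"].to_numpy(float),
        df["sto2"].to_numpy(float),
        tuple(df["flag"].astype(str)),
    )


def write_rbfi_series(series: RBFiSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": series.times, "rbfi": series.rbfi}).to_csv(
        path, index=False, lineterminator="\n", float_format="%.8g"
    )
    return path


def read_rbfi_series(path: str | Path) -> RBFiSeries:
    df = _read_table(path, ["time_s", "rbfi"])
    return RBFiSeries(df["time_s"].to_numpy(float), df["rbfi"].to_numpy(float))


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format site table CSV into a DataFrame (time_s, site, sto2)."""
    df = _read_table(path, ["time_s", "site", "sto2"])
    bad = set(df["site"]) - set(SITES)
    if bad:
        raise MalformedFileError(f"{path}: unknown sites {sorted(bad)}")
    return df


def _read_table(path: str | Path, columns: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing columns {missing}")
    return df
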