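"""Perfusion time-series analysis of StO2 estimates.

Covers the three analysis shapes used in organ-perfusion monitoring work:

* hand-held site surveys — per-time four-site tables with row averages and
  pre/post-intervention phase averages;
* pump step-down profiles — StO2 versus pump flow level, locating the
  largest adjacent-level drop and the plateau onset;
* continuous monitoring — median smoothing of 15 s-resolution StO2 series
  and detection of abrupt perfusion drops synchronized with the rig's renal
  blood flow index (RBFi).

Wherever a printed-style value is reported (row averages, phase
percentages), rounding is half-away-from-zero on the computed double.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ParameterError,
    PhaseError,
    ProfileError,
    SpectrumValidationError,
)
from .spectra_io import RBFiSeries, SITES, StO2Series


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero on the double value of ``x``."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# site surveys


def aggregate_sites(row: Mapping[str, float]) -> float:
    """Arithmetic mean of the present site StO2 values, rounded to 3 decimals."""
    if not row:
        raise ParameterError("at least one site value is required")
    bad = set(row) - set(SITES)
    if bad:
        raise ParameterError(f"unknown sites: {sorted(bad)}")
    values = np.array([row[s] for s in SITES if s in row], dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise SpectrumValidationError("site StO2 values must lie in [0, 1]")
    return round_half_away(float(np.mean(values)), 3)


@dataclass(frozen=True)
class SiteTable:
    """Per-acquisition-time four-site StO2 records with row averages."""

    data: pd.DataFrame  # long format: time_s, site, sto2

    def __post_init__(self):
        df = self.data
        missing = [c for c in ("time_s", "site", "sto2") if c not in df.columns]
        if missing:
            raise ParameterError(f"site table missing columns {missing}")
        bad = set(df["site"]) - set(SITES)
        if bad:
            raise ParameterError(f"unknown sites: {sorted(bad)}")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.data["time_s"].unique()), dtype=float)

    def row(self, time_s: float) -> dict[str, float]:
        sel = self.data[self.data["time_s"] == time_s]
        return dict(zip(sel["site"], sel["sto2"].astype(float)))

    def averages(self) -> pd.DataFrame:
        """Wide table with one row per time and an ``average`` column."""
        wide = self.data.pivot(index="time_s", columns="site", values="sto2")
        wide = wide.reindex(columns=[s for s in SITES if s in wide.columns])
        wide["average"] = [
            aggregate_sites(self.row(t)) for t in wide.index
        ]
        return wide.reset_index()


def phase_average(table: SiteTable, split_time: float) -> tuple[int, int]:
    """Mean pooled site StO2 before / at-or-after ``split_time``, as percent.

    Pools the individual site values (not row averages) on each side and
    reports integer percentages rounded half away from zero.
    """
    df = table.data
    before = df[df["time_s"] < split_time]["sto2"].astype(float)
    after = df[df["time_s"] >= split_time]["sto2"].astype(float)
    if before.empty or after.empty:
        raise PhaseError("need site values on both sides of the split time")
    return (
        int(round_half_away(float(np.mean(before.to_numpy())) * 100.0)),
        int(round_half_away(float(np.mean(after.to_numpy())) * 100.0)),
    )


# ---------------------------------------------------------------------------
# median smoothing


def median_smooth(series: StO2Series, window: int = 5) -> StO2Series:
    """Sliding median over the ok-flagged samples; timestamps unchanged.

    Each output sample is the median of the up-to-``window`` nearest ok
    samples centred on it, the window shrinking (clipping) at the series
    edges. Flagged-bad samples contribute nothing to any window; their own
    output is the median of the ok samples nearest to them, and their flags
    are preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd count >= 1")
    if window > len(series):
        raise ParameterError("window larger than series")
    ok_idx = np.where(series.ok_mask())[0]
    if ok_idx.size == 0:
        return series
    ok_vals = series.sto2[ok_idx]
    half = window // 2
    out = series.sto2.copy()
    for i in range(len(series)):
        # rank of the ok sample nearest (in index) to position i
        r = int(np.argmin(np.abs(ok_idx - i)))
        lo = max(0, r - half)
        hi = min(ok_idx.size, r + half + 1)
        out[i] = np.median(ok_vals[lo:hi])
    return StO2Series(series.times, out, series.flags)


# ---------------------------------------------------------------------------
# pump step-down


@dataclass(frozen=True)
class PumpStepdownResult:
    """StO2 versus pump flow with the largest drop and plateau onset."""

    flows: np.ndarray  # % of full flow, strictly decreasing
    sto2: np.ndarray
    largest_drop_interval: tuple[float, float]
    plateau_onset: float | None

    def to_dict(self) -> dict:
        return {
            "flows_pct": [float(f) for f in self.flows],
            "sto2": [float(s) for s in self.sto2],
            "largest_drop_interval_pct": list(self.largest_drop_interval),
            "plateau_onset_pct": self.plateau_onset,
        }


def stepdown_profile(
    flows: Sequence[float],
    sto2: Sequence[float],
    plateau_tol: float = 0.02,
) -> PumpStepdownResult:
    """Analyse an StO2-versus-pump-flow step-down profile.

    ``largest_drop_interval`` is the adjacent flow pair with the maximal StO2
    decrease (ties broken toward the higher-flow pair: the earliest
    physiological onset is the conservative report). ``plateau_onset`` is the
    first flow level after which every successive |change| stays within
    ``plateau_tol`` through the end of the profile (None if never).
    """
    flows = np.asarray(flows, dtype=float)
    vals = np.asarray(sto2, dtype=float)
    if flows.size < 3:
        raise ProfileError("need at least 3 flow levels")
    if flows.shape != vals.shape:
        raise ProfileError("flows and sto2 must have equal length")
    if not np.all(np.diff(flows) < 0):
        raise ProfileError("flow levels must be strictly decreasing")
    drops = vals[:-1] - vals[1:]
    i = int(np.argmax(drops))  # argmax takes the first (highest-flow) tie
    steps = np.abs(np.diff(vals))
    plateau: float | None = None
    for k in range(flows.size - 1):
        if np.all(steps[k:] <= plateau_tol):
            plateau = float(flows[k])
            break
    return PumpStepdownResult(
        flows=flows,
        sto2=vals,
        largest_drop_interval=(float(flows[i]), float(flows[i + 1])),
        plateau_onset=plateau,
    )


# ---------------------------------------------------------------------------
# abrupt-drop (decompensation) detection


@dataclass(frozen=True)
class EventConfig:
    """Thresholds for decompensation detection.

    An event requires the median-smoothed StO2 to fall by more than
    ``sto2_drop_abs`` (absolute fraction) within ``span_s`` seconds *and*
    the RBFi to fall by more than ``rbfi_drop_frac`` of its running maximum
    within an overlapping span: the synchronization of the two readouts is
    what distinguishes decompensation from probe artefact.
    """

    sto2_drop_abs: float = 0.02
    span_s: float = 600.0
    rbfi_drop_frac: float = 0.30
    smooth_window: int = 5


@dataclass(frozen=True)
class EventWindow:
    start: float
    end: float
    kind: str  # "decompensation" | "none"

    def __post_init__(self):
        if self.kind not in ("decompensation", "none"):
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if self.kind != "none" and not self.start < self.end:
            raise ParameterError("event window must have start < end")

    def contains(self, t: float) -> bool:
        return self.kind != "none" and self.start <= t <= self.end

    def to_dict(self) -> dict:
        return {"start_s": self.start, "end_s": self.end, "kind": self.kind}


def _trailing_drop(times: np.ndarray, values: np.ndarray, span_s: float) -> np.ndarray:
    """values' running max over the trailing span minus the current value."""
    out = np.empty_like(values)
    j = 0
    running: list[int] = []
    for i in range(times.size):
        while j <= i:
            running.append(j)
            j += 1
        lo = times[i] - span_s
        k = 0
        while running and times[running[0]] < lo:
            running.pop(0)
            k += 1
        window = values[running[0] : i + 1] if running else values[i : i + 1]
        out[i] = window.max() - values[i]
    return out


def detect_abrupt_drop(
    sto2: StO2Series,
    rbfi: RBFiSeries,
    config: EventConfig = EventConfig(),
) -> EventWindow:
    """Locate a synchronized StO2/RBFi collapse; kind="none" when absent."""
    if len(sto2) == 0 or len(rbfi) == 0:
        raise AlignmentError("empty series")
    t0 = max(sto2.times[0], rbfi.times[0])
    t1 = min(sto2.times[-1], rbfi.times[-1])
    if t0 >= t1:
        raise AlignmentError("StO2 and RBFi series do not overlap in time")

    smoothed = median_smooth(sto2, min(config.smooth_window, _odd(len(sto2))))
    ok = smoothed.ok_mask()
    times = smoothed.times[ok]
    vals = smoothed.sto2[ok]
    if times.size < 2:
        return EventWindow(0.0, 0.0, "none")
    rbfi_at = np.interp(times, rbfi.times, rbfi.rbfi)

    sto2_drop = _trailing_drop(times, vals, config.span_s)
    # trailing-span running max for rbfi as well
    tr_max = _trailing_drop(times, rbfi_at, config.span_s) + rbfi_at  # = running max
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tr_max > 0, (tr_max - rbfi_at) / tr_max, 0.0)
    rbfi_drop_ok = rel > config.rbfi_drop_frac

    trigger = (sto2_drop > config.sto2_drop_abs) & rbfi_drop_ok
    if not trigger.any():
        return EventWindow(0.0, 0.0, "none")
    first = int(np.argmax(trigger))
    # extend through the contiguous triggered block
    last = first
    while last + 1 < times.size and trigger[last + 1]:
        last += 1
    start = max(times[0], times[first] - config.span_s)
    return EventWindow(float(start), float(times[last]), "decompensation")


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1
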