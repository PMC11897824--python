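"""Reflectance → absorbance conversion, normalization and quality flagging.

The probe collects light a tungsten-halogen lamp delivered to the organ
surface; under the working assumption that light not reflected back into the
probe was absorbed by the tissue, an absorption spectrum is inferred from the
measured reflectance and the lamp (reference) spectrum. Two rules are
provided:

* ``absolute-difference`` (default): ``A(l) = |s * reference(l) - measured(l)|``
  where ``s`` matches the reference amplitude to the measured spectrum over an
  anchor sub-band (default 590–600 nm, away from the strong Hb bands) so the
  difference captures spectral shape rather than lamp/probe coupling
  efficiency. ``scale_reference=False`` disables the matching (``s = 1``).
* ``log-ratio``: ``A(l) = log10(reference(l) / measured(l))``, the
  Beer–Lambert attenuation form, with the measured spectrum floored at a
  small positive clip to avoid infinities on dark pixels.

Either way the result is restricted to the 500–600 nm fitting window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chromophores import FIT_WINDOW_NM
from .errors import (
    AlignmentError,
    NormalizationError,
    NumericDomainError,
    ParameterError,
)
from .spectra_io import (
    FLAG_AMBIENT,
    FLAG_OK,
    FLAG_SLIP,
    Spectrum,
    SpectrumMeta,
)

ABSORPTION_METHODS = ("absolute-difference", "log-ratio")
DEFAULT_ANCHOR_BAND_NM = (590.0, 600.0)
LOG_RATIO_CLIP_FRAC = 1e-6


@dataclass(frozen=True)
class QualityConfig:
    """Thresholds for the acquisition-quality flags.

    ambient_excess_frac
        A spectrum is flagged ``ambient-light`` when the measured counts
        exceed the reference anywhere by more than this fraction (light
        arrived that the lamp did not supply).
    slip_jump_frac
        Flag ``probe-slip`` when the summed intensity jumps by more than this
        fraction relative to the preceding accepted spectrum (coupling
        change as the probe moves on the organ surface).
    anchor_band_nm
        Sub-band used for reference amplitude matching.
    """

    ambient_excess_frac: float = 0.05
    slip_jump_frac: float = 0.25
    anchor_band_nm: tuple[float, float] = DEFAULT_ANCHOR_BAND_NM


def _window_mask(wavelengths: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise AlignmentError(f"no samples in [{lo:g}, {hi:g}] nm")
    return mask


def _check_aligned(measured: Spectrum, reference: Spectrum) -> None:
    if measured.wavelengths.shape != reference.wavelengths.shape or not np.array_equal(
        measured.wavelengths, reference.wavelengths
    ):
        raise AlignmentError(
            "measured and reference spectra must share a grid (use align_grids)"
        )


class AbsorbanceTransformer(TransformerMixin, BaseEstimator):
    """Map rows of reflectance counts to inferred absorbance rows.

    scikit-learn transformer over a sample matrix ``X`` of shape
    ``(n_spectra, n_wavelengths)``; :meth:`fit` stores the lamp reference and
    the wavelength grid, :meth:`transform` applies the inference rule and
    restricts the output to the fitting window.

    Parameters
    ----------
    method : {"absolute-difference", "log-ratio"}
        Inference rule (see module docstring).
    scale_reference : bool
        Match the reference amplitude to each measured spectrum over
        ``anchor_band_nm`` before differencing (absolute-difference only).
    anchor_band_nm, window_nm : pairs of floats
        Anchor sub-band and output fitting window, nm.
    """

    def __init__(
        self,
        method: str = "absolute-difference",
        scale_reference: bool = True,
        anchor_band_nm: tuple[float, float] = DEFAULT_ANCHOR_BAND_NM,
        window_nm: tuple[float, float] = FIT_WINDOW_NM,
    ):
        self.method = method
        self.scale_reference = scale_reference
        self.anchor_band_nm = anchor_band_nm
        self.window_nm = window_nm

    def fit(self, X=None, y=None, *, wavelengths=None, reference=None):
        if self.method not in ABSORPTION_METHODS:
            raise ParameterError(
                f"method must be one of {ABSORPTION_METHODS}, got {self.method!r}"
            )
        if wavelengths is None or reference is None:
            raise ParameterError("fit requires wavelengths= and reference=")
        wavelengths = np.asarray(wavelengths, dtype=float)
        reference = np.asarray(reference, dtype=float)
        if reference.shape != wavelengths.shape:
            raise AlignmentError("reference must match the wavelength grid")
        self.wavelengths_ = wavelengths
        self.reference_ = reference
        self.window_mask_ = _window_mask(wavelengths, self.window_nm)
        self.anchor_mask_ = _window_mask(wavelengths, self.anchor_band_nm)
        self.wavelengths_out_ = wavelengths[self.window_mask_]
        if self.method == "log-ratio" and np.any(reference[self.window_mask_] <= 0):
            raise NumericDomainError(
                "log-ratio requires a strictly positive reference over the window"
            )
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelengths_.size:
            raise AlignmentError("X columns must match the fitted wavelength grid")
        ref = self.reference_
        if self.method == "absolute-difference":
            if self.scale_reference:
                scale = X[:, self.anchor_mask_].mean(axis=1) / ref[self.anchor_mask_].mean()
            else:
                scale = np.ones(X.shape[0])
            absorb = np.abs(scale[:, None] * ref[None, :] - X)
        else:  # log-ratio
            floor = LOG_RATIO_CLIP_FRAC * ref.max()
            clipped = np.maximum(X, floor)
            if np.any(clipped <= 0):
                raise NumericDomainError("measured counts non-positive after clipping")
            absorb = np.log10(ref[None, :] / clipped)
        return absorb[:, self.window_mask_]


def infer_absorption(
    measured: Spectrum,
    reference: Spectrum,
    method: str = "absolute-difference",
    scale_reference: bool = True,
    anchor_band_nm: tuple[float, float] = DEFAULT_ANCHOR_BAND_NM,
    window_nm: tuple[float, float] = FIT_WINDOW_NM,
) -> Spectrum:
    """Infer an absorbance spectrum from one reflectance/reference pair."""
    _check_aligned(measured, reference)
    tr = AbsorbanceTransformer(
        method=method,
        scale_reference=scale_reference,
        anchor_band_nm=anchor_band_nm,
        window_nm=window_nm,
    ).fit(wavelengths=measured.wavelengths, reference=reference.values)
    values = tr.transform(measured.values[None, :])[0]
    return Spectrum(tr.wavelengths_out_, values, kind="absorbance", meta=measured.meta)


def normalize_spectrum(s: Spectrum, window_nm=FIT_WINDOW_NM) -> Spectrum:
    """Divide by the maximum over the window so the peak is exactly 1."""
    mask = _window_mask(s.wavelengths, window_nm)
    peak = s.values[mask].max()
    if peak <= 0:
        raise NormalizationError("spectrum has no strictly positive value in window")
    return Spectrum(s.wavelengths, s.values / peak, kind=s.kind, meta=s.meta)


def flag_quality(
    s: Spectrum,
    reference: Spectrum,
    config: QualityConfig = QualityConfig(),
    previous: Spectrum | None = None,
) -> str:
    """Return an acquisition-quality flag for one measured spectrum.

    ``previous`` is the last *accepted* (ok-flagged) spectrum in the series;
    probe-slip detection is skipped when it is None. Always returns a flag,
    never raises: ambient-light takes precedence over probe-slip.
    """
    _check_aligned(s, reference)
    excess = s.values > reference.values * (1.0 + config.ambient_excess_frac)
    if excess.any():
        return FLAG_AMBIENT
    if previous is not None:
        _check_aligned(s, previous)
        prev_total = previous.values.sum()
        if prev_total > 0:
            jump = abs(s.values.sum() - prev_total) / prev_total
            if jump > config.slip_jump_frac:
                return FLAG_SLIP
    return FLAG_OK
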