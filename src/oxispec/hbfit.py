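"""Haemoglobin absorption-model fitting and StO2 estimation.

The model for an inferred tissue absorption spectrum is

    A(l) = a_hbo2 * eps_hbo2(l) + a_hb * eps_hb(l) + sum_k b_k * u(l)**k

with ``u(l) = (l - l_c) / 50`` a centred, scaled wavelength coordinate
(``l_c`` = window centre) and the polynomial absorbing lamp-shape and
scattering trends. The physical parameters — mean optical path length <L>
and the two haemoglobin concentrations — enter only as products, so only the
two combined amplitudes ``a = <L> * c * ln10`` are identifiable; they are
reported uncalibrated. Tissue oxygen saturation is their ratio,

    StO2 = a_hbo2 / (a_hb + a_hbo2),

in which the common <L> * ln10 factor cancels, so the ratio of amplitudes
equals the ratio of concentrations.

The model is linear in all parameters, so the least-squares problem with
non-negative amplitudes (and unconstrained background) is convex and is
solved exactly: an unconstrained solve serves as a fast path, with a bounded
solve (scipy ``lsq_linear``) whenever an amplitude bound is active. The
result is deterministic and is the global minimum; amplitude non-negativity
keeps StO2 inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, TransformerMixin

from .chromophores import (
    FIT_WINDOW_NM,
    ExtinctionTable,
    load_extinction_table,
    resample_extinction,
    validate_grid,
)
from .errors import (
    FitPreconditionError,
    ParameterError,
    UndefinedSaturationError,
)
from .spectra_io import Spectrum

#: Scale (nm) of the centred wavelength coordinate used for the background.
BACKGROUND_SCALE_NM = 50.0


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the absorption-model fit."""

    background_order: int = 2
    window_nm: tuple[float, float] = FIT_WINDOW_NM
    max_iterations: int = 200
    convergence_tol: float = 1e-10
    amplitude_lower_bound: float = 0.0

    def __post_init__(self):
        if self.background_order < 0:
            raise ParameterError("background_order must be >= 0")
        if not self.window_nm[0] < self.window_nm[1]:
            raise ParameterError("window_nm must be an increasing pair")


@dataclass(frozen=True)
class HbFitResult:
    """Fitted haemoglobin amplitudes, background, StO2 and diagnostics.

    ``sto2`` is NaN (and the sample is later flagged fit-failed) when both
    amplitudes are zero; it is never clamped.
    """

    a_hbo2: float
    a_hb: float
    background: np.ndarray
    sto2: float
    rss: float
    converged: bool
    n_points: int

    def to_dict(self) -> dict:
        return {
            "a_hbo2": self.a_hbo2,
            "a_hb": self.a_hb,
            "background": [float(b) for b in np.atleast_1d(self.background)],
            "sto2": None if np.isnan(self.sto2) else float(self.sto2),
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def compute_sto2(a_hbo2: float, a_hb: float) -> float:
    """StO2 = a_hbo2 / (a_hb + a_hbo2); undefined when both amplitudes vanish."""
    if a_hbo2 < 0 or a_hb < 0:
        raise ParameterError("amplitudes must be >= 0")
    total = a_hbo2 + a_hb
    if total <= 0:
        raise UndefinedSaturationError("both haemoglobin amplitudes are zero")
    return a_hbo2 / total


def background_design(grid: np.ndarray, order: int, window_nm) -> np.ndarray:
    """Polynomial columns in the centred, scaled wavelength coordinate."""
    center = 0.5 * (window_nm[0] + window_nm[1])
    u = (grid - center) / BACKGROUND_SCALE_NM
    return np.vander(u, N=order + 1, increasing=True)


def evaluate_model(
    a_hbo2: float,
    a_hb: float,
    background,
    extinction: ExtinctionTable,
    grid,
    window_nm=FIT_WINDOW_NM,
) -> Spectrum:
    """Evaluate the absorption model on a wavelength grid."""
    grid = validate_grid(grid)
    ext = resample_extinction(extinction, grid)
    coeffs = np.atleast_1d(np.asarray(background, dtype=float))
    poly = background_design(grid, coeffs.size - 1, window_nm)
    values = a_hbo2 * ext.eps_hbo2 + a_hb * ext.eps_hb + poly @ coeffs
    return Spectrum(grid, values, kind="absorbance")


class HemoglobinUnmixer(TransformerMixin, BaseEstimator):
    """Unmix absorbance rows into HbO2/Hb amplitudes, background and StO2.

    scikit-learn estimator over a sample matrix ``X`` of shape
    ``(n_spectra, n_wavelengths)``. :meth:`fit` resamples the extinction
    table onto the grid and factorises the design matrix; :meth:`transform`
    returns the fitted parameter matrix with columns
    ``[a_hbo2, a_hb, b_0, ..., b_k]`` and :meth:`predict` the StO2 fractions
    (NaN where undefined).

    Parameters
    ----------
    extinction : ExtinctionTable or None
        Extinction table; None loads the packaged default.
    background_order : int
        Degree of the background polynomial (default 2).
    window_nm : pair of floats
        Fit window, nm; points outside are ignored.
    max_iterations, convergence_tol : passed to the bounded solver.
    """

    def __init__(
        self,
        extinction: ExtinctionTable | None = None,
        background_order: int = 2,
        window_nm: tuple[float, float] = FIT_WINDOW_NM,
        max_iterations: int = 200,
        convergence_tol: float = 1e-10,
    ):
        self.extinction = extinction
        self.background_order = background_order
        self.window_nm = window_nm
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    # -- estimator API ------------------------------------------------------

    def fit(self, X=None, y=None, *, wavelengths=None):
        if wavelengths is None:
            raise ParameterError("fit requires wavelengths=")
        config = FitConfig(
            background_order=self.background_order,
            window_nm=self.window_nm,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
        )
        grid = validate_grid(wavelengths)
        lo, hi = config.window_nm
        mask = (grid >= lo) & (grid <= hi)
        n_params = 2 + config.background_order + 1
        if mask.sum() < config.background_order + 3:
            raise FitPreconditionError(
                f"need at least {config.background_order + 3} points in "
                f"[{lo:g}, {hi:g}] nm, got {int(mask.sum())}"
            )
        if grid[mask][0] > lo + 5 or grid[mask][-1] < hi - 5:
            raise FitPreconditionError(
                "absorbance spectrum does not cover the fit window"
            )
        table = self.extinction if self.extinction is not None else load_extinction_table()
        ext = resample_extinction(table, grid[mask])
        design = np.column_stack(
            [
                ext.eps_hbo2,
                ext.eps_hb,
                background_design(grid[mask], config.background_order, config.window_nm),
            ]
        )
        self.config_ = config
        self.wavelengths_ = grid
        self.window_mask_ = mask
        self.extinction_ = ext
        self.design_ = design
        self.n_params_ = n_params
        # column scaling conditions the normal equations (extinction columns
        # are ~1e4, polynomial columns ~1)
        self.col_scale_ = np.linalg.norm(design, axis=0)
        self.pinv_ = np.linalg.pinv(design / self.col_scale_)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.wavelengths_.size:
            Y = X[:, self.window_mask_]
        elif X.shape[1] == int(self.window_mask_.sum()):
            Y = X
        else:
            raise FitPreconditionError("X columns must match the fitted grid")
        params = (self.pinv_ @ Y.T).T / self.col_scale_
        # fast path is the unconstrained optimum; rows with a negative
        # amplitude need the bounded (convex, still exact) solve
        tol = -1e-12 * max(1.0, float(np.abs(params[:, :2]).max(initial=0.0)))
        self.converged_ = np.ones(X.shape[0], dtype=bool)
        bad = np.where((params[:, 0] < tol) | (params[:, 1] < tol))[0]
        lbound = np.full(self.n_params_, -np.inf)
        lbound[:2] = self.config_.amplitude_lower_bound
        for i in bad:
            res = lsq_linear(
                self.design_ / self.col_scale_,
                Y[i],
                bounds=(lbound, np.full(self.n_params_, np.inf)),
                tol=self.config_.convergence_tol,
                max_iter=self.config_.max_iterations,
            )
            params[i] = res.x / self.col_scale_
            self.converged_[i] = res.status > 0
        params[:, :2] = np.maximum(params[:, :2], 0.0)
        return params

    def predict(self, X) -> np.ndarray:
        """StO2 fraction per row; NaN where both amplitudes are zero."""
        params = self.transform(X)
        total = params[:, 0] + params[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            sto2 = np.where(total > 0, params[:, 0] / total, np.nan)
        return sto2

    # -- detailed single/batch results -------------------------------------

    def fit_results(self, X) -> list[HbFitResult]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self.transform(X)
        converged = self.converged_
        Y = X[:, self.window_mask_] if X.shape[1] == self.wavelengths_.size else X
        resid = Y - params @ self.design_.T
        rss = np.einsum("ij,ij->i", resid, resid)
        out = []
        for i in range(params.shape[0]):
            a1, a2 = float(params[i, 0]), float(params[i, 1])
            total = a1 + a2
            sto2 = a1 / total if total > 0 else float("nan")
            out.append(
                HbFitResult(
                    a_hbo2=a1,
                    a_hb=a2,
                    background=params[i, 2:].copy(),
                    sto2=sto2,
                    rss=float(rss[i]),
                    converged=bool(converged[i]),
                    n_points=int(self.window_mask_.sum()),
                )
            )
        return out


def propagated_sto2_sd(
    unmixer: HemoglobinUnmixer,
    sigma_per_point,
    a_hbo2: float,
    a_hb: float,
) -> float:
    """Delta-method standard deviation of the fitted StO2.

    Propagates independent per-wavelength absorbance noise with standard
    deviations ``sigma_per_point`` (one value per point inside the fit
    window) through the unconstrained least-squares solve and the
    StO2 = a_hbo2/(a_hbo2 + a_hb) ratio, linearised at the supplied truth
    amplitudes. Useful as a flatness bound for series fitted at a known
    noise level.
    """
    sigma = np.asarray(sigma_per_point, dtype=float)
    M = unmixer.design_
    if sigma.shape != (M.shape[0],):
        raise ParameterError("sigma_per_point must match the fit window length")
    pinv = np.linalg.inv(M.T @ M) @ M.T
    C = pinv * sigma[None, :]
    cov = (C @ C.T)[:2, :2]
    total = a_hbo2 + a_hb
    if total <= 0:
        raise UndefinedSaturationError("both haemoglobin amplitudes are zero")
    grad = np.array([a_hb, -a_hbo2]) / total ** 2
    return float(np.sqrt(grad @ cov @ grad))


def fit_absorption(
    absorbance: Spectrum,
    extinction: ExtinctionTable | None = None,
    config: FitConfig = FitConfig(),
) -> HbFitResult:
    """Fit the absorption model to one inferred absorbance spectrum."""
    unmixer = HemoglobinUnmixer(
        extinction=extinction,
        background_order=config.background_order,
        window_nm=config.window_nm,
        max_iterations=config.max_iterations,
        convergence_tol=config.convergence_tol,
    ).fit(wavelengths=absorbance.wavelengths)
    return unmixer.fit_results(absorbance.values[None, :])[0]
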