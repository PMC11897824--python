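"""Absorption-model evaluation, least-squares unmixing and StO2."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from oxispec import (
    FitConfig,
    HemoglobinUnmixer,
    Spectrum,
    compute_sto2,
    evaluate_model,
    fit_absorption,
)
from oxispec.errors import (
    FitPreconditionError,
    ParameterError,
    UndefinedSaturationError,
)
from oxispec.hbfit import background_design, propagated_sto2_sd


def synthetic_absorbance(extinction, grid, a_hbo2, a_hb, background=(0.0,)):
    return evaluate_model(a_hbo2, a_hb, background, extinction, grid)


class TestEvaluateModel:
    def test_zero_parameters_zero_spectrum(self, extinction, grid):
        out = evaluate_model(0.0, 0.0, (0.0, 0.0, 0.0), extinction, grid)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_pure_hbo2_proportional_to_extinction(self, extinction, grid):
        out = evaluate_model(1.0, 0.0, (0.0,), extinction, grid)
        np.testing.assert_allclose(out.values, extinction.eps_hbo2)

    def test_spot_wavelengths_match_hand_computation(self, extinction):
        a1, a2 = 0.31, 0.12
        bg = (5.0, -2.0, 1.5)
        for w in (510.0, 555.0, 592.0):
            out = evaluate_model(a1, a2, bg, extinction, [500.0, w, 600.0])
            i = int(np.searchsorted(extinction.wavelengths, w))
            u = (w - 550.0) / 50.0
            expect = (
                a1 * extinction.eps_hbo2[i]
                + a2 * extinction.eps_hb[i]
                + bg[0] + bg[1] * u + bg[2] * u * u
            )
            assert out.values[1] == pytest.approx(expect, rel=1e-12)


class TestComputeSto2:
    def test_pure_oxygenated_boundary(self):
        assert compute_sto2(0.5, 0.0) == 1.0

    @pytest.mark.parametrize("x", [1e-6, 0.3, 7.0])
    def test_equal_amplitudes_give_half(self, x):
        assert compute_sto2(x, x) == pytest.approx(0.5)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedSaturationError):
            compute_sto2(0.0, 0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            compute_sto2(-0.1, 0.2)


class TestFitRecovery:
    @pytest.mark.parametrize("sto2_true", np.round(np.arange(0.0, 1.01, 0.1), 1))
    def test_noiseless_recovery_with_background(self, extinction, grid, sto2_true):
        total = 0.2
        s = synthetic_absorbance(
            extinction, grid, total * sto2_true, total * (1 - sto2_true),
            background=(800.0, -150.0, 60.0),
        )
        r = fit_absorption(s, extinction)
        assert r.converged
        assert r.sto2 == pytest.approx(sto2_true, abs=1e-6)

    def test_pure_hbo2_gives_saturation_one(self, extinction, grid):
        s = synthetic_absorbance(extinction, grid, 0.4, 0.0)
        assert fit_absorption(s, extinction).sto2 == pytest.approx(1.0, abs=1e-6)

    def test_equal_amplitudes_give_half(self, extinction, grid):
        s = synthetic_absorbance(extinction, grid, 0.25, 0.25)
        assert fit_absorption(s, extinction).sto2 == pytest.approx(0.5, abs=1e-6)

    def test_residual_never_exceeds_background_only_fit(self, extinction, grid, rng):
        for _ in range(10):
            y = rng.normal(0.0, 1.0, grid.size)
            s = Spectrum(grid, y, kind="absorbance")
            full = fit_absorption(s, extinction)
            # background-only fit = ordinary polynomial regression
            P = background_design(grid, 2, (500.0, 600.0))
            coef, *_ = np.linalg.lstsq(P, y, rcond=None)
            rss0 = float(np.sum((y - P @ coef) ** 2))
            assert full.rss <= rss0 + 1e-9 * max(rss0, 1.0)

    def test_too_few_points_rejected(self, extinction):
        s = Spectrum([500.0, 550.0, 600.0], [1.0, 2.0, 1.0], kind="absorbance")
        with pytest.raises(FitPreconditionError):
            fit_absorption(s, extinction, FitConfig(background_order=2))

    def test_window_not_covered_rejected(self, extinction):
        g = np.arange(500.0, 551.0, 1.0)
        s = Spectrum(g, np.ones(g.size), kind="absorbance")
        with pytest.raises(FitPreconditionError):
            fit_absorption(s, extinction)


class TestScaleEquivariance:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        sto2=st.floats(min_value=0.05, max_value=0.95),
        noise_seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scaling_absorbance_scales_amplitudes_not_sto2(
        self, k, sto2, noise_seed
    ):
        from oxispec import load_extinction_table

        extinction = load_extinction_table()
        grid = np.arange(500.0, 601.0, 1.0)
        rng = np.random.default_rng(noise_seed)
        total = 0.1
        base = synthetic_absorbance(
            extinction, grid, total * sto2, total * (1 - sto2), (500.0, 80.0, -40.0)
        )
        noisy = base.values * (1.0 + 0.01 * rng.standard_normal(grid.size))
        r1 = fit_absorption(Spectrum(grid, noisy, kind="absorbance"), extinction)
        r2 = fit_absorption(Spectrum(grid, k * noisy, kind="absorbance"), extinction)
        assert r2.sto2 == pytest.approx(r1.sto2, abs=1e-6)
        assert r2.a_hbo2 == pytest.approx(k * r1.a_hbo2, rel=1e-6, abs=1e-12)
        assert r2.a_hb == pytest.approx(k * r1.a_hb, rel=1e-6, abs=1e-12)


class TestGridSearchOracle:
    def test_matches_exhaustive_amplitude_grid(self, extinction, grid, rng):
        """Background-order-0 fits agree with a 201x201 brute-force search."""
        eps = np.column_stack([extinction.eps_hbo2, extinction.eps_hb])
        for _ in range(5):
            a1, a2 = rng.uniform(0.01, 0.3, 2)
            b0 = rng.uniform(-500.0, 500.0)
            y = a1 * eps[:, 0] + a2 * eps[:, 1] + b0
            r = fit_absorption(
                Spectrum(grid, y, kind="absorbance"),
                extinction,
                FitConfig(background_order=0),
            )
            # oracle: exhaustive grid over the amplitude plane, b0 solved
            # analytically per cell (mean of the residual)
            axis = np.linspace(0.0, 0.4, 201)
            A1, A2 = np.meshgrid(axis, axis, indexing="ij")
            pred = A1[..., None] * eps[:, 0] + A2[..., None] * eps[:, 1]
            resid = y[None, None, :] - pred
            resid -= resid.mean(axis=-1, keepdims=True)
            rss = np.einsum("ijk,ijk->ij", resid, resid)
            i, j = np.unravel_index(np.argmin(rss), rss.shape)
            cell = axis[1] - axis[0]
            assert abs(r.a_hbo2 - axis[i]) <= cell
            assert abs(r.a_hb - axis[j]) <= cell


class TestEstimatorApi:
    def test_get_set_params_clone(self):
        um = HemoglobinUnmixer(background_order=3)
        assert um.get_params()["background_order"] == 3
        um2 = clone(um).set_params(background_order=1)
        assert um2.get_params()["background_order"] == 1

    def test_batch_predict_matches_single_fits(self, extinction, grid, rng):
        X = []
        truth = []
        for _ in range(6):
            sto2 = rng.uniform(0.1, 0.9)
            total = rng.uniform(0.05, 0.3)
            s = synthetic_absorbance(
                extinction, grid, total * sto2, total * (1 - sto2), (100.0, 10.0, 0.0)
            )
            X.append(s.values)
            truth.append(sto2)
        um = HemoglobinUnmixer(extinction=extinction).fit(wavelengths=grid)
        np.testing.assert_allclose(um.predict(np.vstack(X)), truth, atol=1e-8)

    def test_propagated_sd_matches_monte_carlo(self, extinction, grid, rng):
        total, sto2 = 0.2, 0.7
        base = synthetic_absorbance(
            extinction, grid, total * sto2, total * (1 - sto2), (300.0, 0.0, 0.0)
        )
        sigma = 0.01 * np.abs(base.values)
        um = HemoglobinUnmixer(extinction=extinction).fit(wavelengths=grid)
        predicted = propagated_sto2_sd(um, sigma, total * sto2, total * (1 - sto2))
        draws = um.predict(
            base.values[None, :] + sigma[None, :] * rng.standard_normal((400, grid.size))
        )
        assert np.std(draws) == pytest.approx(predicted, rel=0.2)
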