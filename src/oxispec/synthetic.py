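"""Synthetic acquisition generator: lamp spectra, reflectance with known
ground-truth StO2, perfusion scenarios and acquisition artifacts.

The forward model is the exact inverse of the package's default absorbance
inference rule: a truth absorption spectrum ``A*`` (haemoglobin amplitudes
plus polynomial background, in detector-count units) is subtracted from the
lamp spectrum, multiplicative Gaussian detector noise is applied, and the
result is clipped at zero. Running the pipeline (absolute-difference
inference with reference scaling disabled, then the model fit) on noiseless
output therefore recovers the truth exactly; this makes the generator an
end-to-end oracle for pipeline correctness rather than a radiative-transfer
simulation.

Scenario time courses emulate the perfusion-compromise experiments the
package analyses:

* ``rejection`` — steady baseline, then an abrupt StO2 fall (default 5 min
  linear ramp) with a synchronized RBFi collapse, as after an anti-HLA
  antibody challenge;
* ``thrombosis`` — pump flow stepped 100/75/50/25/0 % of full flow at equal
  intervals, true StO2 declining linearly with flow down to a perfusion
  threshold (default 25 %) and plateauing below it;
* ``haemorrhage`` — like rejection but with the small-magnitude late drop
  characteristic of an acute bleed;
* ``control`` — constant baseline.

All randomness flows from the single scenario seed through a fixed
``SeedSequence`` spawn order (lamp, detector noise, RBFi noise), so outputs
are bit-reproducible and adding an artifact never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chromophores import ExtinctionTable, load_extinction_table, validate_grid
from .errors import InfeasibleTruthError, ParameterError
from .hbfit import evaluate_model
from .spectra_io import RBFiSeries, Spectrum, SpectrumMeta

SCENARIOS = ("rejection", "thrombosis", "haemorrhage", "control")
ARTIFACTS = ("ambient-light", "probe-slip")

#: Default wavelength grid of the simulated spectrometer (nm).
DEFAULT_GRID_NM = np.arange(500.0, 601.0, 1.0)
#: Peak lamp intensity, detector counts.
LAMP_PEAK_COUNTS = 5.0e4
#: Colour temperature of the simulated tungsten-halogen emitter (K).
LAMP_TEMPERATURE_K = 3000.0
#: Pump flow schedule of the thrombosis scenario (% of full flow).
STEPDOWN_FLOWS_PCT = (100.0, 75.0, 50.0, 25.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation truth for one perfusion scenario.

    ``amplitude_total`` is the summed haemoglobin amplitude in count units;
    the default gives ~50 % reflectance dips at the strongest Hb band,
    typical of a well-perfused organ surface. ``background`` holds the truth
    polynomial coefficients of the count-unit absorption background.
    """

    scenario: str
    duration_s: float = 3600.0
    sample_interval_s: float = 15.0
    baseline_sto2: float = 0.9
    event_time_s: float = 1800.0
    event_magnitude: float = 0.1
    ramp_s: float = 300.0
    plateau_flow_pct: float = 25.0
    rbfi_baseline: float = 1.0
    rbfi_collapse_frac: float = 0.9
    amplitude_total: float = 0.35
    background: tuple[float, ...] = (2000.0, -400.0, 0.0)
    noise_frac: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.baseline_sto2 <= 1.0:
            raise ParameterError("baseline_sto2 must lie in [0, 1]")
        if self.noise_frac < 0:
            raise ParameterError("noise_frac must be >= 0")
        if self.scenario in ("rejection", "haemorrhage") and not (
            0.0 <= self.event_time_s <= self.duration_s
        ):
            raise ParameterError("event_time_s must lie within the duration")
        floor = self.baseline_sto2 - self.event_magnitude
        if self.scenario != "control" and not 0.0 <= floor <= 1.0:
            raise ParameterError("event_magnitude exceeds the baseline StO2")


def default_scenario_config(scenario: str, seed: int = 0) -> ScenarioConfig:
    """Preset configurations matching the study conditions for each scenario."""
    presets = {
        # antibody challenge at t=0; decompensation ~35 min later
        "rejection": dict(
            duration_s=3600.0, event_time_s=2100.0,
            baseline_sto2=0.68, event_magnitude=0.12,
        ),
        # five equal flow steps over the step-down phase
        "thrombosis": dict(
            duration_s=1500.0, baseline_sto2=0.86, event_magnitude=0.27,
        ),
        # late small drop (~95 % -> ~92 %) at ~105 min
        "haemorrhage": dict(
            duration_s=7200.0, event_time_s=6300.0,
            baseline_sto2=0.95, event_magnitude=0.03,
        ),
        "control": dict(duration_s=3600.0, baseline_sto2=0.92),
    }
    if scenario not in presets:
        raise ParameterError(f"scenario must be one of {SCENARIOS}")
    return ScenarioConfig(scenario=scenario, seed=seed, **presets[scenario])


@dataclass(frozen=True)
class ScenarioTruth:
    """Simulated acquisition run together with its generating truth."""

    times: np.ndarray
    true_sto2: np.ndarray
    rbfi: RBFiSeries
    spectra: list[Spectrum]
    reference: Spectrum
    config: ScenarioConfig
    flows: np.ndarray | None = None  # thrombosis only: flow % per sample


def make_lamp_spectrum(
    grid, seed: int = 0, peak_counts: float = LAMP_PEAK_COUNTS
) -> Spectrum:
    """Smooth broadband reference spectrum of a thermal (tungsten) emitter.

    A Planck curve at 3000 K — rising slowly toward long wavelengths over
    500–600 nm — modulated by a gentle seeded quadratic ripple (±2 %)
    standing in for fibre/detector throughput variation. Strictly positive
    and deterministic given the seed.
    """
    grid = validate_grid(grid)
    if grid.size == 0:
        raise ParameterError("empty grid")
    lam_m = grid * 1e-9
    hc_over_k = 1.43877e-2  # m K
    planck = lam_m ** -5 / np.expm1(hc_over_k / (lam_m * LAMP_TEMPERATURE_K))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A3]))
    u = (grid - grid.mean()) / max(grid[-1] - grid[0], 1.0)
    ripple = 1.0 + 0.02 * (rng.uniform(-1, 1) * u + rng.uniform(-1, 1) * (u ** 2 - 1 / 12))
    values = planck * ripple
    values *= peak_counts / values.max()
    return Spectrum(grid, values, kind="reference")


def make_reflectance(
    true_a_hbo2: float,
    true_a_hb: float,
    background,
    lamp: Spectrum,
    noise_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
    extinction: ExtinctionTable | None = None,
    meta: SpectrumMeta = SpectrumMeta(),
) -> Spectrum:
    """Forward-model one reflectance spectrum from truth amplitudes.

    ``measured = (lamp - A*) * (1 + eps)`` with ``eps ~ N(0, noise_frac)``
    i.i.d. per wavelength, clipped at zero. Raises
    :class:`InfeasibleTruthError` when the truth absorbance exceeds the lamp
    anywhere.
    """
    table = extinction if extinction is not None else load_extinction_table()
    truth = evaluate_model(true_a_hbo2, true_a_hb, background, table, lamp.wavelengths)
    clean = lamp.values - truth.values
    if np.any(clean < 0):
        raise InfeasibleTruthError(
            "truth absorbance exceeds the lamp spectrum; reduce amplitudes"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(int(seed)))
    )
    noisy = clean * (1.0 + rng.normal(0.0, noise_frac, clean.size)) if noise_frac > 0 else clean
    return Spectrum(lamp.wavelengths, np.clip(noisy, 0.0, None), kind="reflectance", meta=meta)


def _true_sto2_course(config: ScenarioConfig, times: np.ndarray):
    """Truth StO2 per sample (and flow % per sample for thrombosis)."""
    base = config.baseline_sto2
    flows = None
    if config.scenario == "control":
        sto2 = np.full(times.size, base)
    elif config.scenario in ("rejection", "haemorrhage"):
        frac = np.clip((times - config.event_time_s) / max(config.ramp_s, 1e-9), 0.0, 1.0)
        sto2 = base - config.event_magnitude * frac
    else:  # thrombosis
        n_levels = len(STEPDOWN_FLOWS_PCT)
        level_len = config.duration_s / n_levels
        idx = np.minimum((times / level_len).astype(int), n_levels - 1)
        flows = np.array(STEPDOWN_FLOWS_PCT)[idx]
        floor = base - config.event_magnitude
        thresh = config.plateau_flow_pct
        frac = np.clip((100.0 - flows) / max(100.0 - thresh, 1e-9), 0.0, 1.0)
        sto2 = np.where(flows >= thresh, base - (base - floor) * frac, floor)
    return sto2, flows


def _rbfi_course(config: ScenarioConfig, times: np.ndarray, flows) -> np.ndarray:
    base = config.rbfi_baseline
    if config.scenario == "control":
        rbfi = np.full(times.size, base)
    elif config.scenario == "thrombosis":
        rbfi = base * flows / 100.0
    else:
        frac = np.clip((times - config.event_time_s) / max(config.ramp_s, 1e-9), 0.0, 1.0)
        rbfi = base * (1.0 - config.rbfi_collapse_frac * frac)
    return rbfi


def make_scenario(
    config: ScenarioConfig,
    grid=None,
    extinction: ExtinctionTable | None = None,
) -> ScenarioTruth:
    """Generate a full scenario: reference, per-sample spectra, truth, RBFi."""
    grid = DEFAULT_GRID_NM if grid is None else validate_grid(grid)
    table = extinction if extinction is not None else load_extinction_table()
    times = np.arange(0.0, config.duration_s, config.sample_interval_s)
    if times.size == 0:
        raise ParameterError("duration shorter than one sample interval")
    sto2, flows = _true_sto2_course(config, times)
    rbfi_clean = _rbfi_course(config, times, flows)

    ss = np.random.SeedSequence(int(config.seed)).spawn(3)
    lamp_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    rng_noise = np.random.default_rng(ss[1])
    rng_rbfi = np.random.default_rng(ss[2])

    lamp = make_lamp_spectrum(grid, seed=lamp_seed)
    spectra = []
    for t, s in zip(times, sto2):
        spectra.append(
            make_reflectance(
                config.amplitude_total * s,
                config.amplitude_total * (1.0 - s),
                config.background,
                lamp,
                noise_frac=config.noise_frac,
                seed=rng_noise,
                extinction=table,
                meta=SpectrumMeta(
                    timestamp_s=float(t), integration_s=config.sample_interval_s
                ),
            )
        )
    rbfi_noisy = np.clip(
        rbfi_clean * (1.0 + rng_rbfi.normal(0.0, config.noise_frac, times.size)),
        0.0,
        None,
    )
    return ScenarioTruth(
        times=times,
        true_sto2=sto2,
        rbfi=RBFiSeries(times, rbfi_noisy),
        spectra=spectra,
        reference=lamp,
        config=config,
        flows=flows,
    )


def inject_artifact(
    truth: ScenarioTruth,
    artifact: str,
    at: float,
    magnitude: float,
    seed: int = 0,
) -> ScenarioTruth:
    """Corrupt the measured spectra from time ``at`` onward; truth unchanged.

    ``ambient-light`` adds a broadband positive offset of
    ``magnitude * max(reference)`` counts; ``probe-slip`` multiplies the
    probe coupling by ``(1 - magnitude)``. ``seed`` is accepted for interface
    stability (reserved for randomized artifact shapes); the current
    artifacts are deterministic.
    """
    if artifact not in ARTIFACTS:
        raise ParameterError(f"artifact must be one of {ARTIFACTS}")
    if not truth.times[0] <= at <= truth.times[-1]:
        raise ParameterError("artifact time lies outside the scenario duration")
    if magnitude < 0:
        raise ParameterError("magnitude must be >= 0")
    offset = magnitude * truth.reference.values.max()
    spectra = []
    for t, s in zip(truth.times, truth.spectra):
        if t < at or magnitude == 0:
            spectra.append(s)
        elif artifact == "ambient-light":
            spectra.append(replace(s, values=s.values + offset))
        else:
            spectra.append(replace(s, values=s.values * (1.0 - magnitude)))
    return replace(truth, spectra=spectra)
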