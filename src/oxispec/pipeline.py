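"""End-to-end orchestration: config, batch fitting and step-down runs.

`fit_series` is the in-memory pipeline (preprocess -> quality flag -> fit)
used by the CLI, the simulator round-trip tests and the acceptance checks;
`run_fit` / `run_stepdown` are its file-based counterparts driven by a
:class:`RunConfig`. Individual bad spectra are flagged, never abort a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chromophores import ExtinctionTable, load_extinction_table
from .errors import ConfigError, DataError, ProfileError
from .hbfit import FitConfig, HbFitResult, HemoglobinUnmixer
from .preprocess import (
    AbsorbanceTransformer,
    QualityConfig,
    flag_quality,
)
from .spectra_io import (
    FLAG_FIT_FAILED,
    FLAG_OK,
    Spectrum,
    StO2Series,
    align_grids,
    read_spectrum,
    write_sto2_series,
)
from .timeseries import EventConfig, PumpStepdownResult, stepdown_profile

logger = logging.getLogger("oxispec")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one analysis run."""

    reference: str = ""
    spectra_dir: str | None = None
    manifest: str | None = None
    extinction: str = "default"
    method: str = "absolute-difference"
    scale_reference: bool = True
    outdir: str = "oxispec-out"
    smooth_window: int = 5
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    event: EventConfig = field(default_factory=EventConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quality"]["anchor_band_nm"] = list(self.quality.anchor_band_nm)
        d["fit"]["window_nm"] = list(self.fit.window_nm)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        try:
            fit = FitConfig(**_tupled(raw.pop("fit", {}), "window_nm"))
            quality = QualityConfig(**_tupled(raw.pop("quality", {}), "anchor_band_nm"))
            event = EventConfig(**raw.pop("event", {}))
            return cls(fit=fit, quality=quality, event=event, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad run config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tupled(d: dict, key: str) -> dict:
    if key in d:
        d = dict(d)
        d[key] = tuple(d[key])
    return d


# ---------------------------------------------------------------------------


def fit_series(
    spectra: list[Spectrum],
    reference: Spectrum,
    extinction: ExtinctionTable | None = None,
    method: str = "absolute-difference",
    scale_reference: bool = True,
    fit_config: FitConfig = FitConfig(),
    quality: QualityConfig = QualityConfig(),
) -> tuple[StO2Series, list[HbFitResult]]:
    """Preprocess, quality-flag and fit an ordered sequence of spectra.

    Timestamps come from the spectra's metadata when all are present (and
    strictly increasing); otherwise the sample index is used. Samples whose
    fit leaves both amplitudes at zero are flagged ``fit-failed`` with NaN
    StO2.
    """
    if not spectra:
        raise ConfigError("no spectra to fit")
    if extinction is None:
        extinction = load_extinction_table()

    stamps = [s.meta.timestamp_s for s in spectra]
    if all(t is not None for t in stamps) and np.all(np.diff(stamps) > 0):
        times = np.asarray(stamps, dtype=float)
    else:
        times = np.arange(len(spectra), dtype=float)

    # bring every spectrum onto the reference grid; a shared grid takes the
    # vectorized path below
    aligned: list[Spectrum] = []
    ref_aligned: Spectrum | None = None
    for s in spectra:
        sa, ra = align_grids(s, reference)
        if ref_aligned is None:
            ref_aligned = ra
        elif not np.array_equal(ra.wavelengths, ref_aligned.wavelengths):
            raise DataError("spectra do not share a common grid with the reference")
        aligned.append(sa)
    assert ref_aligned is not None

    flags = []
    previous: Spectrum | None = None
    for sa in aligned:
        flag = flag_quality(sa, ref_aligned, quality, previous=previous)
        flags.append(flag)
        if flag == FLAG_OK:
            previous = sa

    transformer = AbsorbanceTransformer(
        method=method,
        scale_reference=scale_reference,
        anchor_band_nm=quality.anchor_band_nm,
        window_nm=fit_config.window_nm,
    ).fit(wavelengths=ref_aligned.wavelengths, reference=ref_aligned.values)
    X = np.vstack([sa.values for sa in aligned])
    absorbance = transformer.transform(X)

    unmixer = HemoglobinUnmixer(
        extinction=extinction,
        background_order=fit_config.background_order,
        window_nm=fit_config.window_nm,
        max_iterations=fit_config.max_iterations,
        convergence_tol=fit_config.convergence_tol,
    ).fit(wavelengths=transformer.wavelengths_out_)
    results = unmixer.fit_results(absorbance)

    sto2 = np.array([r.sto2 for r in results])
    final_flags = tuple(
        FLAG_FIT_FAILED if (np.isnan(s) or not r.converged) else f
        for s, r, f in zip(sto2, results, flags)
    )
    return StO2Series(times, sto2, final_flags), results


# ---------------------------------------------------------------------------


def _load_inputs(config: RunConfig) -> tuple[Spectrum, list[Spectrum]]:
    if not config.reference:
        raise ConfigError("run config needs a reference spectrum path")
    ref_path = Path(config.reference)
    if not ref_path.exists():
        raise ConfigError(f"reference spectrum not found: {ref_path}")
    reference = read_spectrum(ref_path, kind="reference")

    paths: list[Path]
    if config.manifest:
        mpath = Path(config.manifest)
        if not mpath.exists():
            raise ConfigError(f"manifest not found: {mpath}")
        paths = [
            Path(line.strip())
            for line in mpath.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        ]
    elif config.spectra_dir:
        d = Path(config.spectra_dir)
        if not d.is_dir():
            raise ConfigError(f"spectra directory not found: {d}")
        # companion outputs a simulator/run writes next to the spectra
        companions = {ref_path.name, "rbfi.csv", "sto2.csv", "stepdown.csv"}
        paths = sorted(p for p in d.glob("*.csv") if p.name not in companions)
    else:
        raise ConfigError("run config needs spectra_dir or manifest")
    if not paths:
        raise ConfigError("no spectra found")
    return reference, [read_spectrum(p, kind="reflectance") for p in paths]


def run_fit(config: RunConfig) -> StO2Series:
    """File-based batch fit: read inputs, fit, write series/reports/run log."""
    reference, spectra = _load_inputs(config)
    extinction = (
        load_extinction_table()
        if config.extinction == "default"
        else load_extinction_table(config.extinction)
    )
    series, results = fit_series(
        spectra,
        reference,
        extinction=extinction,
        method=config.method,
        scale_reference=config.scale_reference,
        fit_config=config.fit,
        quality=config.quality,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sto2_series(series, outdir / "sto2.csv")
    reports = [
        {"time_s": float(t), "flag": f, **r.to_dict()}
        for t, f, r in zip(series.times, series.flags, results)
    ]
    (outdir / "fits.json").write_text(
        json.dumps(reports, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    flag_counts: dict[str, int] = {}
    for f in series.flags:
        flag_counts[f] = flag_counts.get(f, 0) + 1
    log = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "version": __version__,
        "n_spectra": len(spectra),
        "flag_counts": flag_counts,
    }
    (outdir / "runlog.json").write_text(
        json.dumps(log, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("fitted %d spectra (%s)", len(spectra), flag_counts)
    return series


def run_stepdown(
    config: RunConfig, manifest: list[tuple[float, str | Path]]
) -> PumpStepdownResult:
    """Fit one spectrum per pump flow level and analyse the profile."""
    if len(manifest) < 3:
        raise ProfileError("need at least 3 flow levels")
    flows = [float(f) for f, _ in manifest]
    if len(set(flows)) != len(flows):
        raise DataError("duplicate flow level in manifest")
    if not config.reference:
        raise ConfigError("run config needs a reference spectrum path")
    ref_path = Path(config.reference)
    if not ref_path.exists():
        raise ConfigError(f"reference spectrum not found: {ref_path}")
    reference = read_spectrum(ref_path, kind="reference")
    order = np.argsort(flows)[::-1]
    spectra = [read_spectrum(Path(manifest[i][1]), kind="reflectance") for i in order]
    flows_sorted = [flows[i] for i in order]
    series, results = fit_series(
        spectra,
        reference,
        method=config.method,
        scale_reference=config.scale_reference,
        fit_config=config.fit,
        quality=config.quality,
    )
    profile = stepdown_profile(flows_sorted, [r.sto2 for r in results])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["flow_pct,sto2"] + [
        f"{f:g},{s:.6g}" for f, s in zip(profile.flows, profile.sto2)
    ]
    (outdir / "stepdown.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    (outdir / "stepdown.json").write_text(
        json.dumps(profile.to_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return profile
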