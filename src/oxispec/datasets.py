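"""Packaged example datasets.

Small StO2 site surveys and a pump step-down profile from an ex vivo
normothermic human-kidney perfusion feasibility experiment, shipped so the
table-arithmetic analyses (row averages, phase averages, step-down profile)
can be exercised without external data.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .spectra_io import read_site_table
from .timeseries import SiteTable

#: Split times (s) separating the experimental phases of the example surveys.
REJECTION_SPLIT_S = 6750.0  # between survey rounds 2 and 3 (intervention)
CONTROL_SPLIT_S = 6450.0  # between survey rounds 2 and 3 (placebo)
THROMBOSIS_SPLIT_S = 0.0  # benching (pre-perfusion) vs perfusion


def _example_path(name: str) -> Path:
    return Path(importlib.resources.files("oxispec") / "data" / "examples" / name)


def load_rejection_sites() -> SiteTable:
    """Four-round site survey of the simulated-rejection kidney."""
    return SiteTable(read_site_table(_example_path("rejection_sites.csv")))


def load_control_sites() -> SiteTable:
    """Four-round site survey of the matched control kidney."""
    return SiteTable(read_site_table(_example_path("control_sites.csv")))


def load_thrombosis_sites() -> SiteTable:
    """Six-round site survey (incl. pre-perfusion benching) of the
    step-down kidney."""
    return SiteTable(read_site_table(_example_path("thrombosis_sites.csv")))


def load_stepdown_profile() -> pd.DataFrame:
    """Pump step-down StO2 profile (flow_pct, sto2), flows decreasing."""
    df = pd.read_csv(_example_path("stepdown_profile.csv"), comment="#")
    return df
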