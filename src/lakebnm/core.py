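"""Core data model for multi-lake annual panels.

The analysis works on long-format annual panels: one row per lake-year with
the ten model variables

======  =======================================================  ==========
column  meaning                                                  units
======  =======================================================  ==========
AT      annual air temperature over the catchment                °C
PRE     annual precipitation over the catchment                  m
PE      annual potential evaporation over the catchment          m
LUag    agricultural land use                                    % of catchment area
WT      lake water temperature                                   °C
WL      lake water level                                         m
CHL     chlorophyll-a concentration (primary productivity)       µg/l
CATCH   total annual fish catch per lake area                    kg/ha
ST      fish stocked per hectare                                 number/ha
EFF     fishing-effort index                                     dimensionless
======  =======================================================  ==========

Any variable may be missing in any year (empty CSV cell, ``NaN`` in memory);
missingness is per-variable, so a year can contribute to one submodel's fit
and not another's.  The annual water-level change ``dWL`` is derived from WL
by first differences over consecutive observed years and is never stored in
input files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The ten model variables, in canonical column order.
VARIABLES = ("AT", "PRE", "PE", "LUag", "WT", "WL", "CHL", "CATCH", "ST", "EFF")

#: Variables entering the model through a log transform: must be > 0.
LOG_VARIABLES = ("CHL", "CATCH", "EFF")

#: Minimum number of observed years required per variable per lake.
MIN_YEARS = 9

PANEL_COLUMNS = ("lake_id", "year") + VARIABLES

CHARACTERISTIC_COLUMNS = (
    "lake_id",
    "access_clean_water",
    "shoreline_pop_density",
    "avg_depth",
    "shoreline_length_km",
    "lake_area_km2",
)


def delta_wl(wl: pd.Series) -> pd.Series:
    """Year-over-year water-level change from a WL series indexed by year.

    ``dWL(t) = WL(t) - WL(t-1)`` when both years are observed and consecutive;
    missing otherwise.  The first year is always missing and gaps in the year
    index or in WL propagate as missing — no gap filling is attempted.
    """
    years = wl.index.to_numpy()
    values = wl.to_numpy(dtype=float)
    out = np.full(len(wl), np.nan)
    for k in range(1, len(wl)):
        if years[k] - years[k - 1] == 1:
            out[k] = values[k] - values[k - 1]
    return pd.Series(out, index=wl.index, name="dWL")


class LakePanel:
    """Annual time series of the ten model variables for one lake.

    Wraps a DataFrame indexed by year (sorted ascending, unique) with columns
    ``VARIABLES`` plus the derived ``dWL``.  Missing values are ``NaN``.
    """

    def __init__(self, lake_id: str, df: pd.DataFrame):
        self.lake_id = str(lake_id)
        df = df.copy()
        if "year" in df.columns:
            df = df.set_index("year")
        df.index = df.index.astype(int)
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ValueError(
                f"duplicate lake-year keys for lake {lake_id!r}: years {dups}"
            )
        df = df.sort_index()
        for var in VARIABLES:
            if var not in df.columns:
                df[var] = np.nan
        df = df[list(VARIABLES)].astype(float)
        df["dWL"] = delta_wl(df["WL"])
        self.df = df

    @property
    def years(self) -> np.ndarray:
        return self.df.index.to_numpy()

    @property
    def n_years(self) -> int:
        return len(self.df)

    def observed_counts(self) -> dict[str, int]:
        """Number of observed (non-missing) years per model variable."""
        return {var: int(self.df[var].notna().sum()) for var in VARIABLES}

    def window(self, start: int | None = None, end: int | None = None) -> "LakePanel":
        """Restrict to a study window [start, end] (inclusive, years)."""
        df = self.df
        if start is not None:
            df = df[df.index >= start]
        if end is not None:
            df = df[df.index <= end]
        return LakePanel(self.lake_id, df.drop(columns="dWL").reset_index())

    def __repr__(self) -> str:  # pragma: no cover
        return f"LakePanel({self.lake_id!r}, years {self.years.min()}–{self.years.max()})"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel` for one lake."""

    lake_id: str
    observed_counts: dict[str, int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_panel(panel: LakePanel, min_years: int = MIN_YEARS) -> ValidationReport:
    """Check a lake panel against the model's data requirements.

    Flags any variable observed in fewer than ``min_years`` years, nonpositive
    values of the log-transformed variables (CHL, CATCH, EFF), and LUag
    outside [0, 100].  Duplicate lake-year keys raise at panel construction.
    """
    counts = panel.observed_counts()
    violations: list[str] = []
    for var, n in counts.items():
        if n < min_years:
            violations.append(
                f"{var}: only {n} observed years (minimum {min_years})"
            )
    for var in LOG_VARIABLES:
        bad = panel.df[var] <= 0
        if bad.any():
            years = panel.df.index[bad.fillna(False)].tolist()
            violations.append(f"{var}: nonpositive values in years {years}")
    lu = panel.df["LUag"]
    bad_lu = (lu < 0) | (lu > 100)
    if bad_lu.any():
        years = panel.df.index[bad_lu.fillna(False)].tolist()
        violations.append(f"LUag: values outside [0, 100] in years {years}")
    return ValidationReport(panel.lake_id, counts, violations)


def compute_medians(
    panel: LakePanel,
    window: tuple[int, int] | None = None,
    variables: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-variable medians of observed values over the study window.

    The study window defaults to the full panel.  Medians use the standard
    convention: for an even count, the mean of the two central order
    statistics.  A variable with zero observations raises ``ValueError``.
    """
    df = panel.df
    if window is not None:
        df = df[(df.index >= window[0]) & (df.index <= window[1])]
    if variables is None:
        variables = list(VARIABLES) + ["dWL"]
    medians: dict[str, float] = {}
    for var in variables:
        vals = df[var].dropna()
        if len(vals) == 0:
            raise ValueError(
                f"lake {panel.lake_id!r}: no observed values for {var} in window"
            )
        medians[var] = float(vals.median())
    return medians


@dataclass
class LakeCharacteristics:
    """Socio-economic and hydrogeomorphological characteristics of lakes.

    One row per lake: access to clean water (proportion of catchment
    population using drinking-water and sanitation services, in [0, 1]),
    shoreline population density (persons/km² within 10 km of the shore),
    average depth (m), shoreline length SL (km) and lake area Alake (km²).
    The shoreline development index SDI = 0.5·SL/√(π·Alake) is derived on
    construction (1 for a circular lake, larger for more convoluted shores).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in CHARACTERISTIC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"characteristics table missing columns: {missing}")
        if (df["shoreline_length_km"] <= 0).any() or (df["lake_area_km2"] <= 0).any():
            raise ValueError("shoreline length and lake area must be positive")
        df["SDI"] = 0.5 * df["shoreline_length_km"] / np.sqrt(
            math.pi * df["lake_area_km2"]
        )
        if (df["SDI"] < 1 - 1e-9).any():
            raise ValueError("SDI below 1: inconsistent shoreline length and area")
        self.table = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path) -> dict[str, LakePanel]:
    """Read a long-format panel CSV into one :class:`LakePanel` per lake.

    Expected columns: ``lake_id, year, AT, PRE, PE, LUag, WT, WL, CHL, CATCH,
    ST, EFF`` (UTF-8, header required; empty cells are missing values).
    """
    df = pd.read_csv(path, dtype={"lake_id": str}, float_precision="round_trip")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    return {
        str(lake_id): LakePanel(str(lake_id), sub.drop(columns="lake_id"))
        for lake_id, sub in df.groupby("lake_id", sort=True)
    }


def write_panel_csv(panels: Mapping[str, LakePanel] | Iterable[LakePanel],
                    path: str | Path) -> None:
    """Write lake panels to a long-format CSV (derived dWL is not written)."""
    if isinstance(panels, Mapping):
        panels = panels.values()
    frames = []
    for panel in panels:
        out = panel.df.drop(columns="dWL").reset_index()
        out.insert(0, "lake_id", panel.lake_id)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_characteristics_csv(path: str | Path) -> LakeCharacteristics:
    df = pd.read_csv(path, dtype={"lake_id": str})
    return LakeCharacteristics(df)


def write_characteristics_csv(chars: LakeCharacteristics, path: str | Path) -> None:
    chars.table.drop(columns=["SDI"], errors="ignore").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Settings shared by the estimation and Monte-Carlo stages.

    ``chains``/``burn_in``/``retained`` default to the scaled-down testing
    configuration (3 × 2,000 + 5,000); :meth:`full_scale` switches to the
    full 3 × 20,000 + 50,000 production run.  ``classification_level`` is the credible
    level of the one-tailed interval used to call an effect positive or
    negative (0.75).  ``ratio_window`` is the closed predicted-catch-ratio
    acceptance window defining a "25% catch decrease" scenario, and
    ``mc_target`` the number of accepted samples per lake × driver.
    """

    chains: int = 3
    burn_in: int = 2_000
    retained: int = 5_000
    thinning: int = 1
    seed: int = 0
    submodels: tuple[str, ...] = ("WT", "dWL", "CHL", "CATCH")
    classification_level: float = 0.75
    mc_target: int = 10_000
    ratio_window: tuple[float, float] = (0.74, 0.76)
    # fixed values for validation runs; None = sampled
    fixed_sigma: Mapping[str, float] | None = None
    fixed_g: Mapping[str, float] | None = None
    # hyperprior shapes: inverse-gamma(a, b) on sigma^2 and on g
    sigma_hyper: tuple[float, float] = (0.001, 0.001)
    g_hyper: tuple[float, float] = (0.001, 0.001)

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for Gelman–Rubin")
        if not self.ratio_window[0] < self.ratio_window[1]:
            raise ValueError("ratio window lower bound must be below upper bound")
        unknown = set(self.submodels) - {"WT", "dWL", "CHL", "CATCH"}
        if unknown:
            raise ValueError(f"unknown submodels: {sorted(unknown)}")
        # downstream submodels consume upstream predicted means
        if "CHL" in self.submodels and not {"WT", "dWL"} <= set(self.submodels):
            raise ValueError("CHL submodel requires WT and dWL")
        if "CATCH" in self.submodels and not {"WT", "dWL", "CHL"} <= set(self.submodels):
            raise ValueError("CATCH submodel requires WT, dWL and CHL")

    @classmethod
    def full_scale(cls, **kwargs) -> "ModelConfig":
        kwargs.setdefault("burn_in", 20_000)
        kwargs.setdefault("retained", 50_000)
        return cls(**kwargs)
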