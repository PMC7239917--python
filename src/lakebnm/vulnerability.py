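"""Vulnerability of lake catches and its correlates.

A lake's vulnerability to a 25% catch decrease under one driver is indexed
by the median *absolute* driver change over the accepted Monte-Carlo
scenarios: a smaller required change means a more vulnerable catch.  These
magnitudes are correlated, driver by driver, against four lake
characteristics — access to clean water, shoreline population density,
average depth and the shoreline development index
SDI = 0.5·SL/√(π·Alake) — with a two-sided t-test on the Pearson r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assessment import DriverAssessment

CHARACTERISTICS = ("access_clean_water", "shoreline_pop_density",
                   "avg_depth", "SDI")


def sdi(shoreline_length: float, lake_area: float) -> float:
    """Shoreline development index, 0.5·SL/√(π·Alake).

    SL in km, Alake in km².  Equals 1 for a circular lake — the circle
    minimizes shoreline for a given area — and grows with shoreline
    complexity (relatively more littoral area).
    """
    if shoreline_length <= 0 or lake_area <= 0:
        raise ValueError("shoreline length and lake area must be positive")
    return 0.5 * shoreline_length / math.sqrt(math.pi * lake_area)


def magnitude_of_change(assessment: DriverAssessment) -> float:
    """Median absolute driver change over the accepted scenario samples."""
    if assessment.n_accepted == 0:
        raise ValueError("empty assessment")
    return float(assessment.samples["delta_driver"].abs().median())


@dataclass
class CorrelationResult:
    r: float
    t: float
    p: float
    n: int
    significant: bool
    # least-squares line (returned when significant, plotting convention)
    slope: float | None = None
    intercept: float | None = None


def correlation_pvalue(r: float, n: int) -> tuple[float, float]:
    """(t, two-sided p) for a Pearson correlation r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return math.inf if r > 0 else -math.inf, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return t, float(p)


def correlation_test(x: Sequence[float], y: Sequence[float],
                     alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test.

    ``t = r·√(n−2)/√(1−r²)`` on n−2 degrees of freedom.  When significant at
    ``alpha`` the least-squares line of y on x is also returned.
    Symmetric in r and p under exchange of x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    t, p = correlation_pvalue(r, n)
    significant = p <= alpha
    slope = intercept = None
    if significant:
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    return CorrelationResult(r, t, p, n, significant, slope, intercept)


def vulnerability_table(
    assessments: Mapping[str, Mapping[str, DriverAssessment]],
    characteristics: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-lake magnitudes of change with the lake characteristics.

    ``assessments[lake_id][driver]`` → one row per lake × driver with the
    magnitude and the characteristic columns (including derived SDI).
    """
    chars = characteristics.copy()
    if "SDI" not in chars.columns:
        chars["SDI"] = [
            sdi(sl, a) for sl, a in
            zip(chars["shoreline_length_km"], chars["lake_area_km2"])
        ]
    chars = chars.set_index("lake_id")
    rows = []
    for lake_id, per_driver in assessments.items():
        for driver, assessment in per_driver.items():
            row = {"lake_id": lake_id, "driver": driver,
                   "magnitude": magnitude_of_change(assessment)}
            for c in CHARACTERISTICS:
                row[c] = float(chars.loc[lake_id, c])
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_summary(vuln: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All characteristic × driver correlations (within driver only).

    Magnitudes mix units across drivers (°C, %, percentage points), so each
    driver is correlated separately.  No multiple-testing correction is
    applied; each test is reported at its own p-value.
    """
    rows = []
    for driver, sub in vuln.groupby("driver"):
        for c in CHARACTERISTICS:
            if len(sub) < 3:
                rows.append({"driver": driver, "characteristic": c,
                             "n": len(sub), "r": np.nan, "t": np.nan,
                             "p": np.nan, "significant": False})
                continue
            res = correlation_test(sub[c].to_numpy(),
                                   sub["magnitude"].to_numpy(), alpha)
            rows.append({
                "driver": driver, "characteristic": c, "n": res.n,
                "r": res.r, "t": res.t, "p": res.p,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)
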