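"""Monte-Carlo assessment of driver changes behind a 25% catch decrease.

For each lake × driver (AT, PRE or LUag) the sampler repeats three steps:

1. draw a coefficient set from the empirical posterior and compute the
   baseline predictions μ₀ at the lake's study-window median inputs;
2. draw the assessed driver from a normal distribution fitted to the lake's
   observed series (the other drivers stay at their medians; for the AT
   assessment PE co-moves with the sampled AT through the lake's fitted
   PE–AT line, anchored so the median AT maps to the median PE);
3. recompute the predictions μ and keep the sample iff the predicted catch
   ratio exp(μ^CATCH − μ₀^CATCH) falls inside the closed window
   [0.74, 0.76] — a "25% catch decrease" scenario —

until the target number of accepted samples (default 10,000) is reached.
Each accepted sample records the driver change in its reporting metric, the
mediator changes (ΔWT, ΔWL as actual differences; CHL as a percent
difference) and the mediator → catch effects
``{exp[β·(μ − μ₀)] − 1} × 100%``, which multiply exactly to the catch ratio
because the catch mean is additive in the mediator means.

Because the WT pathway is only hypothesized for air temperature, the PRE and
LUag assessments track two mediators (WL, CHL) and use the 13.4% importance
cutoff; the AT assessment tracks three and uses 9.1%, where the cutoff for k
equal contributors is (1 − 0.75^(1/k)) × 100%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import LakePanel, ModelConfig, compute_medians
from .inference import PosteriorDraws

DRIVERS = ("AT", "PRE", "LUag")

#: mediators tracked per assessed driver (WT is AT-only)
ACTIVE_MEDIATORS = {
    "AT": ("WT", "WL", "CHL"),
    "PRE": ("WL", "CHL"),
    "LUag": ("WL", "CHL"),
}


def importance_cutoff(k: int) -> float:
    """Percent catch decrease attributed to each of k equal contributors.

    ``(1 − 0.75^(1/k)) × 100``: the per-mediator share of a 25% total
    decrease if k mediators contribute equally on the multiplicative scale.
    k = 3 gives 9.1%, k = 2 gives 13.4%, k = 1 the whole 25%.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError("k must be an integer >= 1")
    return (1.0 - 0.75 ** (1.0 / k)) * 100.0


def fit_driver_distribution(panel: LakePanel, driver: str) -> tuple[float, float]:
    """Normal proposal parameters: mean and SD of the observed driver series."""
    vals = panel.df[driver].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError(f"lake {panel.lake_id!r}: not enough {driver} data")
    return float(vals.mean()), float(vals.std(ddof=1))


def fit_pe_at_map(panel: LakePanel) -> tuple[float, float]:
    """Least-squares line PE = a + b·AT from the observed (AT, PE) pairs.

    Stands in for recomputing potential evaporation under a uniform monthly
    temperature shift, which needs monthly data.
    """
    df = panel.df[["AT", "PE"]].dropna()
    if len(df) < 3:
        raise ValueError(f"lake {panel.lake_id!r}: not enough (AT, PE) pairs")
    at = df["AT"].to_numpy()
    pe = df["PE"].to_numpy()
    b, a = np.polyfit(at, pe, 1)
    return float(a), float(b)


def _batch_mu(beta: Mapping[str, np.ndarray], eligible: bool,
              inputs: Mapping[str, float | np.ndarray]) -> dict[str, np.ndarray]:
    """Vectorized predicted means: one row of each beta array per sample."""
    b_wt, b_wl = beta["WT"], beta["dWL"]
    b_chl, bc = beta["CHL"], beta["CATCH"]
    at, pre = inputs["AT"], inputs["PRE"]
    pe, lu = inputs["PE"], inputs["LUag"]
    mu_wt = b_wt[:, 0] + b_wt[:, 1] * at
    mu_dwl = (b_wl[:, 0] + b_wl[:, 1] * pre + b_wl[:, 2] * pe
              + b_wl[:, 3] * pe * lu)
    mu_chl = (b_chl[:, 0] + b_chl[:, 1] * np.log(pre)
              + b_chl[:, 2] * np.log(lu)
              + b_chl[:, 3] * mu_dwl + b_chl[:, 4] * mu_wt)
    mu_catch = (bc[:, 0] + bc[:, 1] * mu_wt + bc[:, 2] * mu_dwl
                + bc[:, 3] * mu_chl)
    if eligible:
        mu_catch = mu_catch + bc[:, 4] * np.log(inputs["ST"])
    mu_catch = mu_catch + bc[:, -1] * np.log(inputs["EFF"])
    return {"WT": mu_wt, "dWL": mu_dwl, "CHL": mu_chl, "CATCH": mu_catch}


def baseline_prediction(beta: Mapping[str, np.ndarray], eligible: bool,
                        medians: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Predicted means μ₀ at the lake's median inputs, per coefficient draw."""
    return _batch_mu(beta, eligible, medians)


def propose_driver(driver: str, mean: float, sd: float,
                   rng: np.random.Generator, size: int) -> np.ndarray:
    """Sample the assessed driver; out-of-domain PRE/LUag are resampled."""
    x = rng.normal(mean, sd, size)
    if driver == "PRE":
        bad = x <= 0
    elif driver == "LUag":
        bad = (x <= 0) | (x >= 100)
    else:
        return x
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        if driver == "PRE":
            bad = x <= 0
        else:
            bad = (x <= 0) | (x >= 100)
    return x


def accept_sample(mu_catch, mu0_catch,
                  window: tuple[float, float] = (0.74, 0.76)):
    """True where exp(μ^CATCH − μ₀^CATCH) lies inside the closed window."""
    ratio = np.exp(np.asarray(mu_catch) - np.asarray(mu0_catch))
    return (ratio >= window[0]) & (ratio <= window[1])


def change_metric(variable: str, value, median):
    """A predicted change in the variable's reporting convention.

    Actual difference for AT, WT, WL and LUag (the latter in percentage
    points of catchment area); percent difference from the median for PRE.
    For CHL, modeled on the log scale, ``value`` and ``median`` are log-scale
    quantities and the metric is the implied percent difference
    ``(exp(value − median) − 1) × 100``.
    """
    value = np.asarray(value, dtype=float)
    if variable in ("AT", "WT", "WL", "dWL", "LUag"):
        return value - median
    if variable == "PRE":
        if median == 0:
            raise ValueError("percent change undefined for zero median PRE")
        return (value / median - 1.0) * 100.0
    if variable == "CHL":
        return (np.exp(value - median) - 1.0) * 100.0
    raise ValueError(f"no change metric for {variable!r}")


def mediator_catch_effect(beta, mu, mu0):
    """Percent catch change attributed to one mediator: {exp[β(μ−μ₀)]−1}·100."""
    return (np.exp(np.asarray(beta) * (np.asarray(mu) - np.asarray(mu0))) - 1.0) * 100.0


@dataclass
class DriverAssessment:
    """Accepted Monte-Carlo samples for one lake × driver."""

    lake_id: str
    driver: str
    samples: pd.DataFrame
    n_proposed: int
    window: tuple[float, float]
    medians: dict[str, float]

    @property
    def n_accepted(self) -> int:
        return len(self.samples)

    @property
    def active_mediators(self) -> tuple[str, ...]:
        return ACTIVE_MEDIATORS[self.driver]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


def run_driver_assessment(
    panel: LakePanel,
    driver: str,
    posterior: PosteriorDraws | Mapping[str, np.ndarray],
    lake_id: str | None = None,
    stocking_eligible: bool = False,
    n_accepted: int = 10_000,
    seed: int = 0,
    window: tuple[float, float] = (0.74, 0.76),
    batch_size: int = 50_000,
    min_rate: float = 1e-5,
) -> DriverAssessment:
    """Accumulate ``n_accepted`` accepted 25%-catch-decrease scenarios.

    ``posterior`` is a :class:`PosteriorDraws` (its chains are flattened) or
    a pre-flattened mapping submodel → (n_draws, n_terms).  Aborts with
    guidance if, after a substantial number of proposals, the acceptance rate
    falls below ``min_rate`` — the driver's plausible range then cannot
    produce a 25% catch decrease for this lake.
    """
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {DRIVERS}")
    lake_id = lake_id or panel.lake_id
    if isinstance(posterior, PosteriorDraws):
        beta = posterior.coefficient_sets(lake_id)
    else:
        beta = {sm: np.asarray(v) for sm, v in posterior.items()}
    eligible = stocking_eligible or beta["CATCH"].shape[1] == 6
    n_draws = beta["WT"].shape[0]

    medians = compute_medians(panel)
    mean, sd = fit_driver_distribution(panel, driver)
    if driver == "AT":
        _, pe_slope = fit_pe_at_map(panel)

    rng = np.random.default_rng(seed)
    mu0 = baseline_prediction(beta, eligible, medians)

    chunks: list[pd.DataFrame] = []
    got = 0
    proposed = 0
    while got < n_accepted:
        size = min(batch_size, max(10 * (n_accepted - got), 1000))
        idx = rng.integers(0, n_draws, size)
        value = propose_driver(driver, mean, sd, rng, size)
        inputs = {v: medians[v] for v in ("AT", "PRE", "PE", "LUag", "ST", "EFF")}
        inputs[driver] = value
        if driver == "AT":
            # PE co-moves with AT through the lake's PE–AT line, anchored at
            # the medians so the median AT reproduces the median PE
            inputs["PE"] = medians["PE"] + pe_slope * (value - medians["AT"])
        sub = {sm: arr[idx] for sm, arr in beta.items()}
        mu = _batch_mu(sub, eligible, inputs)
        mu0_idx = {k: v[idx] for k, v in mu0.items()}
        keep = accept_sample(mu["CATCH"], mu0_idx["CATCH"], window)
        proposed += size
        if keep.any():
            k = np.flatnonzero(keep)
            bK = sub["CATCH"][k]
            rec = pd.DataFrame({
                "draw_index": idx[k],
                "driver_value": value[k],
                "delta_driver": change_metric(driver, value[k], medians[driver]),
                "d_WT": mu["WT"][k] - mu0_idx["WT"][k],
                "d_WL": mu["dWL"][k] - mu0_idx["dWL"][k],
                "d_CHL": change_metric("CHL", mu["CHL"][k], mu0_idx["CHL"][k]),
                "e_WT": mediator_catch_effect(bK[:, 1], mu["WT"][k], mu0_idx["WT"][k]),
                "e_WL": mediator_catch_effect(bK[:, 2], mu["dWL"][k], mu0_idx["dWL"][k]),
                "e_CHL": mediator_catch_effect(bK[:, 3], mu["CHL"][k], mu0_idx["CHL"][k]),
                "ratio": np.exp(mu["CATCH"][k] - mu0_idx["CATCH"][k]),
            })
            got += len(rec)
            chunks.append(rec)
        if proposed >= 20 * max(n_accepted, 10_000) and got / proposed < min_rate:
            raise RuntimeError(
                f"lake {lake_id!r}, driver {driver}: acceptance rate "
                f"{got / proposed:.2e} after {proposed} proposals is below "
                f"{min_rate:.0e}. The sampled {driver} range cannot produce a "
                "25% catch decrease here; widen the proposal SD or check the "
                "fitted coefficients."
            )
    samples = pd.concat(chunks, ignore_index=True).iloc[:n_accepted].copy()
    observed = panel.df[driver].dropna()
    n_outside = int(((samples["driver_value"] < observed.min())
                     | (samples["driver_value"] > observed.max())).sum())
    if n_outside:
        warnings.warn(
            f"lake {lake_id!r}, driver {driver}: {n_outside} of {n_accepted} "
            "accepted samples lie outside the observed driver range — the "
            "scenario extrapolates beyond the data",
            RuntimeWarning, stacklevel=2)
    return DriverAssessment(lake_id, driver, samples, proposed, window,
                            {k: float(v) for k, v in medians.items()})


def classify_association(delta_driver: np.ndarray) -> str:
    """Direction of the driver change associated with the catch decrease.

    ``positive`` (catch decrease goes with a driver *decrease*) if the third
    quartile of the accepted Δdriver is below 0, ``negative`` if the first
    quartile is above 0, ``mixed`` otherwise.
    """
    arr = np.asarray(delta_driver, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValueError("empty accepted samples")
    q25, q75 = np.quantile(arr, [0.25, 0.75])
    if q75 < 0:
        return "positive"
    if q25 > 0:
        return "negative"
    return "mixed"


def flag_importance(effects_pct: np.ndarray, k: int) -> bool:
    """Whether a mediator's catch effect exceeds its equal-share cutoff.

    True iff at least 75% of the accepted samples show a decrease larger
    than ``importance_cutoff(k)``, i.e. the 0.75 quantile of the percent
    effects is ≤ −cutoff.
    """
    arr = np.asarray(effects_pct, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValueError("empty effect draws")
    return bool(np.quantile(arr, 0.75) <= -importance_cutoff(k))


def summarize_assessment(assessment: DriverAssessment) -> dict:
    """Medians, quartiles, association call and importance flags."""
    s = assessment.samples
    k = len(assessment.active_mediators)
    med_cols = {"WT": ("d_WT", "e_WT"), "WL": ("d_WL", "e_WL"),
                "CHL": ("d_CHL", "e_CHL")}
    out = {
        "lake_id": assessment.lake_id,
        "driver": assessment.driver,
        "n_accepted": assessment.n_accepted,
        "n_proposed": assessment.n_proposed,
        "acceptance_rate": assessment.acceptance_rate,
        "association": classify_association(s["delta_driver"].to_numpy()),
        "delta_driver": {
            "median": float(s["delta_driver"].median()),
            "q25": float(s["delta_driver"].quantile(0.25)),
            "q75": float(s["delta_driver"].quantile(0.75)),
            "median_abs": float(s["delta_driver"].abs().median()),
        },
        "mediators": {},
    }
    for med in assessment.active_mediators:
        d_col, e_col = med_cols[med]
        out["mediators"][med] = {
            "change_median": float(s[d_col].median()),
            "effect_median_pct": float(s[e_col].median()),
            "effect_q25_pct": float(s[e_col].quantile(0.25)),
            "effect_q75_pct": float(s[e_col].quantile(0.75)),
            "important": flag_importance(s[e_col].to_numpy(), k),
        }
    return out


def save_assessment(assessment: DriverAssessment, outdir: str | Path) -> None:
    """Write the accepted samples (CSV) and summary (JSON) for one lake × driver."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"assessment_{assessment.lake_id}_{assessment.driver}"
    assessment.samples.to_csv(outdir / f"{stem}.csv", index=False)
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(summarize_assessment(assessment), fh, indent=2)
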