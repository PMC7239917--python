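"""Synthetic multi-lake panels with known ground truth.

Every downstream stage (priors, MCMC, effect classification, Monte-Carlo
driver assessment, vulnerability correlations) is exercised on panels drawn
from the same conditional-Gaussian network the estimator assumes:

* ``WT ~ N(β0 + β1·AT, σ_WT)``
* ``dWL ~ N(β0 + β1·PRE + β2·PE + β3·PE·LUag, σ_dWL)``
* ``log CHL ~ N(β0 + β1·log PRE + β2·log LUag + β3·μ_dWL + β4·μ_WT, σ_CHL)``
* ``log CATCH ~ N(β0 + β1·μ_WT + β2·μ_dWL + β3·μ_CHL + β4·log ST + β5·log EFF,
  σ_CATCH)``

where the downstream means consume the upstream *predicted* means μ (not the
noisy realizations), exactly as the estimation equations are written.  Water
level WL is integrated from the realized dWL draws on top of a lake-specific
initial level, so differencing the panel recovers the simulated dWL.

Defaults emulate the study conditions: 31 lakes × 45 years (1970–2014
analog); drivers independent across years; a universally positive AT→WT link
with mixed signs on the other links; coefficient and driver scales chosen so
that a 25% catch swing lies within roughly two to three standard deviations
of each driver's interannual variability (the regime in which conditional
scenario sampling is meaningful); noise standard deviations set to a fixed
fraction (default 10%) of each deterministic response signal's spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import LakePanel, MIN_YEARS

START_YEAR = 1970

#: per-link sign plan: probability that the coefficient is positive, and the
#: magnitude range it is drawn from (uniform).  Magnitudes are bounded away
#: from zero so every lake has a usable driver → catch pathway.
_SIGN_PLAN = {
    # (submodel, term): (P(positive), lo, hi)
    ("WT", "AT"): (1.0, 0.5, 1.0),
    ("dWL", "PRE"): (0.95, 0.6, 2.0),
    ("dWL", "PE"): (0.10, 0.3, 1.0),
    ("dWL", "PExLUag"): (0.40, 0.002, 0.012),
    ("CHL", "log_PRE"): (0.70, 0.2, 0.8),
    ("CHL", "log_LUag"): (0.65, 0.3, 1.0),
    ("CHL", "mu_dWL"): (0.60, 0.2, 0.8),
    ("CHL", "mu_WT"): (0.35, 0.03, 0.12),
    ("CATCH", "mu_WT"): (0.50, 0.10, 0.35),
    ("CATCH", "mu_dWL"): (0.55, 0.5, 1.5),
    ("CATCH", "mu_CHL"): (0.55, 0.2, 0.6),
    ("CATCH", "log_ST"): (0.80, 0.05, 0.25),
    ("CATCH", "log_EFF"): (0.95, 0.4, 1.0),
}

#: minimum |d log CATCH / d driver| × driver SD required of every lake: a
#: 25% catch decrease (|Δlog| ≈ 0.29) must lie within ~2.5 SD of driver
#: variability, the regime where conditional scenario sampling is meaningful
_MIN_PATH_STRENGTH = 0.12

NOISE_LEVELS = {"none": 0.0, "moderate": 0.10, "high": 0.30}

#: fraction of lakes where stocking contributes enough to estimate its effect
STOCKING_RATE = 8 / 31


@dataclass
class LakeTruth:
    """Ground-truth coefficients and generating parameters for one lake."""

    lake_id: str
    beta: dict[str, list[float]]           # submodel -> coefficient vector
    sigma: dict[str, float]                # submodel -> noise SD
    stocking_eligible: bool
    # driver-generating parameters
    at_mean: float
    at_sd: float
    pre_logmean: float
    pre_logsd: float
    luag_mean: float
    luag_sd: float
    pe_a: float                            # PE = pe_a + pe_b * AT
    pe_b: float
    wl0: float                             # initial water level
    st_logmean: float
    st_logsd: float
    eff_logmean: float
    eff_logsd: float

    def at_catch_sensitivity(self) -> float:
        """|d log CATCH / d AT| through all mediated pathways.

        AT moves catch through WT (directly and via WT→CHL) and, because PE
        co-varies with AT, through the water-level change and its CHL effect.
        Used as the lake's true driver sensitivity when planting correlations
        with lake characteristics.
        """
        b_wt = self.beta["WT"][1]
        b_wl = self.beta["dWL"]
        b_chl = self.beta["CHL"]
        bc = self.beta["CATCH"]
        wt_path = b_wt * (bc[1] + bc[3] * b_chl[4])
        dwl_dat = self.pe_b * (b_wl[2] + b_wl[3] * self.luag_mean)
        wl_path = dwl_dat * (bc[2] + bc[3] * b_chl[3])
        return abs(wt_path + wl_path)

    def path_strengths(self) -> dict[str, float]:
        """|d log CATCH / d driver| × driver SD per driver, at driver means.

        The catch response to one driver-SD of change, combining every
        mediated pathway (dWL and CHL for all three drivers; WT additionally
        for AT).  Log-scale drivers use the chain rule at the mean.
        """
        b_wl = self.beta["dWL"]
        b_chl = self.beta["CHL"]
        bc = self.beta["CATCH"]
        wl_to_catch = bc[2] + bc[3] * b_chl[3]
        pre_mean = math.exp(self.pre_logmean)
        pre_sd = pre_mean * math.sqrt(math.expm1(self.pre_logsd ** 2))
        d_pre = (b_wl[1] * wl_to_catch + b_chl[1] * bc[3] / pre_mean)
        pe_mean = self.pe_a + self.pe_b * self.at_mean
        d_lu = (b_wl[3] * pe_mean * wl_to_catch
                + b_chl[2] * bc[3] / self.luag_mean)
        return {
            "AT": self.at_catch_sensitivity() * self.at_sd,
            "PRE": abs(d_pre) * pre_sd,
            "LUag": abs(d_lu) * self.luag_sd,
        }


@dataclass
class TruthScenario:
    """A full synthetic study: per-lake truths plus generated driver series."""

    n_lakes: int
    n_years: int
    seed: int
    noise: str
    sign_plan: str
    lakes: list[LakeTruth]
    drivers: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return np.arange(START_YEAR, START_YEAR + self.n_years)

    def lake(self, lake_id: str) -> LakeTruth:
        for lt in self.lakes:
            if lt.lake_id == lake_id:
                return lt
        raise KeyError(lake_id)

    def stocking_flags(self) -> dict[str, bool]:
        return {lt.lake_id: lt.stocking_eligible for lt in self.lakes}

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_lakes": self.n_lakes,
            "n_years": self.n_years,
            "seed": self.seed,
            "noise": self.noise,
            "sign_plan": self.sign_plan,
            "lakes": [asdict(lt) for lt in self.lakes],
            "drivers": {
                lake_id: df.reset_index().to_dict(orient="list")
                for lake_id, df in self.drivers.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TruthScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        lakes = [LakeTruth(**d) for d in doc["lakes"]]
        drivers = {
            lake_id: pd.DataFrame(rec).set_index("year")
            for lake_id, rec in doc["drivers"].items()
        }
        return cls(doc["n_lakes"], doc["n_years"], doc["seed"], doc["noise"],
                   doc["sign_plan"], lakes, drivers)


def _draw_coefficient(rng: np.random.Generator, submodel: str, term: str,
                      sign_plan: str) -> float:
    p_pos, lo, hi = _SIGN_PLAN[(submodel, term)]
    if sign_plan == "mixed" and (submodel, term) == ("WT", "AT"):
        p_pos = 0.6
    sign = 1.0 if rng.random() < p_pos else -1.0
    return float(sign * rng.uniform(lo, hi))


def _deterministic_means(truth: LakeTruth, drv: pd.DataFrame) -> dict[str, np.ndarray]:
    """Predicted means of the four responses given the driver series."""
    b_wt = truth.beta["WT"]
    b_wl = truth.beta["dWL"]
    b_chl = truth.beta["CHL"]
    bc = truth.beta["CATCH"]
    at = drv["AT"].to_numpy()
    pre = drv["PRE"].to_numpy()
    pe = drv["PE"].to_numpy()
    lu = drv["LUag"].to_numpy()
    mu_wt = b_wt[0] + b_wt[1] * at
    mu_dwl = b_wl[0] + b_wl[1] * pre + b_wl[2] * pe + b_wl[3] * pe * lu
    mu_chl = (b_chl[0] + b_chl[1] * np.log(pre) + b_chl[2] * np.log(lu)
              + b_chl[3] * mu_dwl + b_chl[4] * mu_wt)
    mu_catch = (bc[0] + bc[1] * mu_wt + bc[2] * mu_dwl + bc[3] * mu_chl
                + bc[5] * np.log(drv["EFF"].to_numpy()))
    if truth.stocking_eligible:
        mu_catch = mu_catch + bc[4] * np.log(drv["ST"].to_numpy())
    return {"WT": mu_wt, "dWL": mu_dwl, "CHL": mu_chl, "CATCH": mu_catch}


def generate_scenario(
    n_lakes: int = 31,
    n_years: int = 45,
    seed: int = 0,
    noise: str = "moderate",
    sign_plan: str = "all_positive_WT",
) -> TruthScenario:
    """Draw a ground-truth scenario and its driver series.

    Reproducible given ``seed``.  ``sign_plan="all_positive_WT"`` (default)
    makes every lake's AT→WT slope positive, the direction this link takes
    universally in real lakes; ``"mixed"`` allows negative slopes too.
    ``noise`` sets each submodel's σ as a fraction of its deterministic
    signal spread (see ``NOISE_LEVELS``).
    """
    if n_lakes < 1:
        raise ValueError("n_lakes must be >= 1")
    if n_years < 10:
        raise ValueError("n_years must be >= 10")
    if noise not in NOISE_LEVELS:
        raise ValueError(f"noise must be one of {sorted(NOISE_LEVELS)}")
    if sign_plan not in ("all_positive_WT", "mixed"):
        raise ValueError("sign_plan must be 'all_positive_WT' or 'mixed'")
    rng = np.random.default_rng(seed)
    noise_frac = NOISE_LEVELS[noise]
    years = np.arange(START_YEAR, START_YEAR + n_years)

    lakes: list[LakeTruth] = []
    drivers: dict[str, pd.DataFrame] = {}
    width = len(str(n_lakes))
    for i in range(n_lakes):
        lake_id = f"L{i + 1:0{width}d}"
        at_mean = rng.uniform(5.0, 25.0)
        pre_logmean = math.log(rng.uniform(0.5, 2.0))
        luag_mean = rng.uniform(15.0, 60.0)
        pe_b = rng.uniform(0.02, 0.06)
        pe_a = rng.uniform(0.6, 1.4) - pe_b * at_mean
        wl0 = rng.uniform(50.0, 300.0)
        st_logmean = math.log(rng.uniform(50.0, 200.0))
        eff_logmean = math.log(rng.uniform(0.5, 2.0))
        eligible = bool(rng.random() < STOCKING_RATE)

        # redraw coefficients (and driver variability) until every driver's
        # pathway is strong enough that a 25% catch swing is reachable within
        # the driver's plausible range (the lakes the analysis targets)
        for _ in range(2000):
            at_sd = rng.uniform(0.7, 1.3)
            pre_logsd = rng.uniform(0.18, 0.32)
            luag_sd = rng.uniform(5.0, 12.0)
            beta: dict[str, list[float]] = {}
            beta["WT"] = [rng.uniform(1.0, 6.0),
                          _draw_coefficient(rng, "WT", "AT", sign_plan)]
            beta["dWL"] = [rng.normal(0.0, 0.05)] + [
                _draw_coefficient(rng, "dWL", t, sign_plan)
                for t in ("PRE", "PE", "PExLUag")]
            beta["CHL"] = [0.0] + [
                _draw_coefficient(rng, "CHL", t, sign_plan)
                for t in ("log_PRE", "log_LUag", "mu_dWL", "mu_WT")]
            beta["CATCH"] = [0.0] + [
                _draw_coefficient(rng, "CATCH", t, sign_plan)
                for t in ("mu_WT", "mu_dWL", "mu_CHL", "log_ST", "log_EFF")]
            probe = LakeTruth(
                lake_id, beta, {}, eligible,
                float(at_mean), float(at_sd), float(pre_logmean),
                float(pre_logsd), float(luag_mean), float(luag_sd),
                float(pe_a), float(pe_b), float(wl0),
                float(st_logmean), 0.3, float(eff_logmean), 0.25,
            )
            if min(probe.path_strengths().values()) >= _MIN_PATH_STRENGTH:
                break
        else:  # pragma: no cover - bounds make this unreachable in practice
            raise RuntimeError(f"could not draw a feasible coefficient set "
                               f"for lake {lake_id}")

        # driver series: independent across years
        at = rng.normal(at_mean, at_sd, n_years)
        pre = np.exp(rng.normal(pre_logmean, pre_logsd, n_years))
        lu = np.clip(rng.normal(luag_mean, luag_sd, n_years), 0.5, 99.5)
        pe = pe_a + pe_b * at
        st = np.exp(rng.normal(st_logmean, 0.3, n_years))
        eff = np.exp(rng.normal(eff_logmean, 0.25, n_years))
        drv = pd.DataFrame(
            {"AT": at, "PRE": pre, "PE": pe, "LUag": lu, "ST": st, "EFF": eff},
            index=pd.Index(years, name="year"),
        )

        truth = probe
        # center CHL at ~15 µg/l and CATCH at ~50 kg/ha, then set σ from the
        # deterministic signal spread
        mus = _deterministic_means(truth, drv)
        beta["CHL"][0] = float(rng.normal(math.log(15.0), 0.4)
                               - np.mean(mus["CHL"]))
        mus_chl_shift = float(beta["CHL"][0])
        beta["CATCH"][0] = float(
            rng.normal(math.log(50.0), 0.4)
            - np.mean(mus["CATCH"]) - beta["CATCH"][3] * mus_chl_shift
        )
        mus = _deterministic_means(truth, drv)
        for sm in ("WT", "dWL", "CHL", "CATCH"):
            spread = float(np.std(mus[sm]))
            truth.sigma[sm] = (
                0.0 if noise_frac == 0 else max(noise_frac * spread, 1e-6)
            )
        lakes.append(truth)
        drivers[lake_id] = drv

    return TruthScenario(n_lakes, n_years, int(seed), noise, sign_plan,
                         lakes, drivers)


def forward_simulate(scenario: TruthScenario, seed: int = 0) -> dict[str, LakePanel]:
    """Simulate complete (gap-free) panels from a scenario.

    Responses are drawn from the conditional normals around the deterministic
    predicted means; WL is integrated from the realized dWL draws starting at
    the lake's initial level.  CHL, CATCH, ST and EFF are strictly positive
    by construction (log-normal).
    """
    rng = np.random.default_rng(seed)
    panels: dict[str, LakePanel] = {}
    for truth in scenario.lakes:
        drv = scenario.drivers[truth.lake_id]
        n = len(drv)
        mus = _deterministic_means(truth, drv)
        wt = mus["WT"] + truth.sigma["WT"] * rng.standard_normal(n)
        dwl = mus["dWL"] + truth.sigma["dWL"] * rng.standard_normal(n)
        wl = truth.wl0 + np.concatenate([[0.0], np.cumsum(dwl[1:])])
        log_chl = mus["CHL"] + truth.sigma["CHL"] * rng.standard_normal(n)
        log_catch = mus["CATCH"] + truth.sigma["CATCH"] * rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "year": drv.index.to_numpy(),
                "AT": drv["AT"].to_numpy(),
                "PRE": drv["PRE"].to_numpy(),
                "PE": drv["PE"].to_numpy(),
                "LUag": drv["LUag"].to_numpy(),
                "WT": wt,
                "WL": wl,
                "CHL": np.exp(log_chl),
                "CATCH": np.exp(log_catch),
                "ST": drv["ST"].to_numpy(),
                "EFF": drv["EFF"].to_numpy(),
            }
        )
        panels[truth.lake_id] = LakePanel(truth.lake_id, df)
    return panels


def apply_missingness(
    panels: Mapping[str, LakePanel],
    fractions: Mapping[str, float],
    seed: int = 0,
    min_years: int = MIN_YEARS,
) -> dict[str, LakePanel]:
    """Blank out a per-variable fraction of years in every lake panel.

    Years to blank are chosen uniformly at random per lake × variable.
    Raises if a requested fraction would leave fewer than ``min_years``
    observed years for any variable (the estimation floor).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, LakePanel] = {}
    for lake_id, panel in panels.items():
        df = panel.df.drop(columns="dWL").copy()
        n = len(df)
        for var, frac in fractions.items():
            if not 0 <= frac < 1:
                raise ValueError(f"missing fraction for {var} must be in [0, 1)")
            n_obs = int(df[var].notna().sum())
            n_missing = int(round(frac * n_obs))
            if n_obs - n_missing < min_years:
                raise ValueError(
                    f"lake {lake_id!r}: removing {n_missing} of {n_obs} {var} "
                    f"years would leave fewer than {min_years}"
                )
            if n_missing:
                observed_pos = np.flatnonzero(df[var].notna().to_numpy())
                drop = rng.choice(observed_pos, size=n_missing, replace=False)
                df.iloc[drop, df.columns.get_loc(var)] = np.nan
        out[lake_id] = LakePanel(lake_id, df.reset_index())
    return out


def generate_characteristics(
    scenario: TruthScenario,
    planted_r: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Lake-characteristics table with a plantable vulnerability correlation.

    ``access_clean_water`` is generated so that its expected Pearson
    correlation with the lakes' *inverse* AT→catch sensitivity (a proxy for
    the vulnerability magnitude: less sensitive lakes need larger driver
    changes for the same catch decrease) equals ``planted_r``.  Shoreline
    length and lake area are drawn so the shoreline development index spans
    roughly 1–8.
    """
    if not -1.0 <= planted_r <= 1.0:
        raise ValueError("planted correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = scenario.n_lakes
    inv_sens = np.array([1.0 / lt.at_catch_sensitivity() for lt in scenario.lakes])
    z = (inv_sens - inv_sens.mean()) / inv_sens.std() if n > 1 and inv_sens.std() > 0 \
        else np.zeros(n)
    acw_z = planted_r * z + math.sqrt(max(0.0, 1 - planted_r ** 2)) * rng.standard_normal(n)
    acw = np.clip(0.5 + 0.15 * acw_z, 0.02, 0.98)
    area = np.exp(rng.normal(math.log(200.0), 1.2, n))
    sdi = 1.0 + np.exp(rng.normal(math.log(0.6), 0.8, n))
    sl = sdi * 2.0 * np.sqrt(math.pi * area)
    return pd.DataFrame(
        {
            "lake_id": [lt.lake_id for lt in scenario.lakes],
            "access_clean_water": acw,
            "shoreline_pop_density": np.exp(rng.normal(math.log(100.0), 1.0, n)),
            "avg_depth": np.exp(rng.normal(math.log(8.0), 0.8, n)),
            "shoreline_length_km": sl,
            "lake_area_km2": area,
        }
    )
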