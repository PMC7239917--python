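"""Conditional-Gaussian network estimation by block Gibbs sampling.

The model is a recursive system of four conditional Gaussian regressions per
lake *i* (year index suppressed; all years are treated as independent):

.. math::

    WT &\\sim N(\\mu^{WT}, \\sigma^{WT}_i), \\qquad
       \\mu^{WT} = \\beta^{WT}_{0,i} + \\beta^{WT}_{1,i}\\,AT \\\\
    dWL &\\sim N(\\mu^{dWL}, \\sigma^{dWL}_i), \\qquad
       \\mu^{dWL} = \\beta^{dWL}_{0,i} + \\beta_1 PRE + \\beta_2 PE
                    + \\beta_3 PE\\cdot LUag \\\\
    \\log CHL &\\sim N(\\mu^{CHL}, \\sigma^{CHL}_i), \\qquad
       \\mu^{CHL} = \\beta^{CHL}_{0,i} + \\beta_1\\log PRE + \\beta_2\\log LUag
                    + \\beta_3\\mu^{dWL} + \\beta_4\\mu^{WT} \\\\
    \\log CATCH &\\sim N(\\mu^{CATCH}, \\sigma^{CATCH}_i), \\qquad
       \\mu^{CATCH} = \\beta^{CATCH}_{0,i} + \\beta_1\\mu^{WT}
                    + \\beta_2\\mu^{dWL} + \\beta_3\\mu^{CHL}
                    + \\beta_4\\log ST + \\beta_5\\log EFF

Downstream means consume upstream *predicted* means μ, so information flows
both ways: catch data inform the water-temperature coefficients and vice
versa.  Because every μ is linear in each coefficient block separately, each
block's full conditional given the other blocks is Gaussian and can be drawn
exactly; σ² and the prior-scale hyperparameter g have conjugate
inverse-gamma full conditionals under the default priors.  The stocking term
β₄·log ST is present only for stocking-eligible lakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import norm

from .core import LakePanel, ModelConfig
from .priors import PriorSpec, SUBMODELS, submodel_terms

__all__ = [
    "CoefficientSet",
    "PosteriorDraws",
    "predicted_means",
    "log_joint",
    "run_mcmc",
    "gelman_rubin",
    "classify_coefficient",
    "effects_table",
    "stocking_eligible",
    "EFFECT_PAIRS",
]


@dataclass
class CoefficientSet:
    """One lake's coefficient vectors and noise SDs for the four submodels."""

    lake_id: str
    beta: dict[str, np.ndarray]
    sigma: dict[str, float]
    stocking_eligible: bool = True

    def __post_init__(self) -> None:
        for sm, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma[{sm}] must be nonnegative")
        if "CATCH" in self.beta:
            expected = 6 if self.stocking_eligible else 5
            if len(self.beta["CATCH"]) != expected:
                raise ValueError(
                    f"CATCH coefficient vector has {len(self.beta['CATCH'])} "
                    f"entries, expected {expected} for "
                    f"stocking_eligible={self.stocking_eligible}"
                )


def _aslog(name: str, x) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"log of nonpositive {name}")
    return np.log(x)


def predicted_means(
    coeffs: CoefficientSet | Mapping[str, Sequence[float]],
    inputs: Mapping[str, float | np.ndarray],
    stocking_eligible: bool | None = None,
) -> dict[str, float | np.ndarray]:
    """Evaluate the four predicted means at given driver inputs.

    ``inputs`` must provide AT, PRE, PE, LUag and, for the CATCH mean, EFF
    (plus ST for stocking-eligible lakes).  Values may be scalars or arrays.
    Returns ``{"WT": μ^WT, "dWL": μ^dWL, "CHL": μ^CHL, "CATCH": μ^CATCH}``.
    """
    if isinstance(coeffs, CoefficientSet):
        beta = coeffs.beta
        if stocking_eligible is None:
            stocking_eligible = coeffs.stocking_eligible
    else:
        beta = coeffs
    b_wt = np.asarray(beta["WT"], dtype=float)
    b_wl = np.asarray(beta["dWL"], dtype=float)
    b_chl = np.asarray(beta["CHL"], dtype=float)
    bc = np.asarray(beta["CATCH"], dtype=float)
    if stocking_eligible is None:
        stocking_eligible = len(bc) == 6

    at = np.asarray(inputs["AT"], dtype=float)
    pre = np.asarray(inputs["PRE"], dtype=float)
    pe = np.asarray(inputs["PE"], dtype=float)
    lu = np.asarray(inputs["LUag"], dtype=float)

    mu_wt = b_wt[0] + b_wt[1] * at
    mu_dwl = b_wl[0] + b_wl[1] * pre + b_wl[2] * pe + b_wl[3] * pe * lu
    mu_chl = (b_chl[0] + b_chl[1] * _aslog("PRE", pre)
              + b_chl[2] * _aslog("LUag", lu)
              + b_chl[3] * mu_dwl + b_chl[4] * mu_wt)
    mu_catch = bc[0] + bc[1] * mu_wt + bc[2] * mu_dwl + bc[3] * mu_chl
    if stocking_eligible:
        mu_catch = mu_catch + bc[4] * _aslog("ST", inputs["ST"])
        mu_catch = mu_catch + bc[5] * _aslog("EFF", inputs["EFF"])
    else:
        mu_catch = mu_catch + bc[-1] * _aslog("EFF", inputs["EFF"])
    return {"WT": mu_wt, "dWL": mu_dwl, "CHL": mu_chl, "CATCH": mu_catch}


# ---------------------------------------------------------------------------
# Per-lake static design data
# ---------------------------------------------------------------------------

class _LakeData:
    """Masked design pieces for one lake, precomputed once per run.

    Each submodel contributes likelihood terms only in the years where its
    response and every required raw input are observed (and positive where a
    log is taken); years with a missing response simply drop out.
    """

    def __init__(self, panel: LakePanel, eligible: bool,
                 submodels: Sequence[str]):
        self.lake_id = panel.lake_id
        self.eligible = eligible
        self.active = tuple(sm for sm in SUBMODELS if sm in submodels)
        df = panel.df

        def col(name, mask):
            return df.loc[mask, name].to_numpy()

        if "WT" in self.active:
            m = df[["WT", "AT"]].notna().all(axis=1)
            self.y_wt = col("WT", m)
            self.X_wt = np.column_stack([np.ones(m.sum()), col("AT", m)])
            self.XtX_wt = self.X_wt.T @ self.X_wt
            self.Xty_wt = self.X_wt.T @ self.y_wt
            self.n_wt = int(m.sum())

        if "dWL" in self.active:
            m = df[["dWL", "PRE", "PE", "LUag"]].notna().all(axis=1)
            self.y_wl = col("dWL", m)
            self.X_wl = np.column_stack([
                np.ones(m.sum()), col("PRE", m), col("PE", m),
                col("PE", m) * col("LUag", m)])
            self.XtX_wl = self.X_wl.T @ self.X_wl
            self.Xty_wl = self.X_wl.T @ self.y_wl
            self.n_wl = int(m.sum())

        if "CHL" in self.active:
            m = (df[["CHL", "AT", "PRE", "PE", "LUag"]].notna().all(axis=1)
                 & (df["CHL"] > 0) & (df["PRE"] > 0) & (df["LUag"] > 0))
            self.y_chl = np.log(col("CHL", m))
            self.Z_chl = np.column_stack([
                np.ones(m.sum()), np.log(col("PRE", m)), np.log(col("LUag", m))])
            self.Awt_chl = np.column_stack([np.ones(m.sum()), col("AT", m)])
            self.Awl_chl = np.column_stack([
                np.ones(m.sum()), col("PRE", m), col("PE", m),
                col("PE", m) * col("LUag", m)])
            self.G_wt_chl = self.Awt_chl.T @ self.Awt_chl
            self.G_wl_chl = self.Awl_chl.T @ self.Awl_chl
            self.n_chl = int(m.sum())

        if "CATCH" in self.active:
            need = ["CATCH", "AT", "PRE", "PE", "LUag", "EFF"]
            m = (df[need].notna().all(axis=1)
                 & (df["CATCH"] > 0) & (df["PRE"] > 0) & (df["LUag"] > 0)
                 & (df["EFF"] > 0))
            if eligible:
                m &= df["ST"].notna() & (df["ST"] > 0)
            self.y_c = np.log(col("CATCH", m))
            self.Awt_c = np.column_stack([np.ones(m.sum()), col("AT", m)])
            self.Awl_c = np.column_stack([
                np.ones(m.sum()), col("PRE", m), col("PE", m),
                col("PE", m) * col("LUag", m)])
            self.Z_chl_c = np.column_stack([
                np.ones(m.sum()), np.log(col("PRE", m)), np.log(col("LUag", m))])
            self.log_st = np.log(col("ST", m)) if eligible else None
            self.log_eff = np.log(col("EFF", m))
            self.G_wt_c = self.Awt_c.T @ self.Awt_c
            self.G_wl_c = self.Awl_c.T @ self.Awl_c
            self.n_c = int(m.sum())

    # helper: the fixed (non-CHL-mediated) part of mu_CATCH for given blocks
    def _catch_offsets(self, bK: np.ndarray) -> np.ndarray:
        off = np.full(len(self.y_c), bK[0])
        if self.eligible:
            off = off + bK[4] * self.log_st + bK[5] * self.log_eff
        else:
            off = off + bK[4] * self.log_eff
        return off


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC draws indexed (chain, iteration) per parameter.

    ``beta[submodel][lake_id]`` has shape (chains, iterations, n_terms);
    ``sigma[submodel][lake_id]`` and ``g[submodel]`` have shape
    (chains, iterations).  ``terms[submodel][lake_id]`` names the columns.
    """

    beta: dict[str, dict[str, np.ndarray]]
    sigma: dict[str, dict[str, np.ndarray]]
    g: dict[str, np.ndarray]
    terms: dict[str, dict[str, tuple[str, ...]]]
    lake_ids: tuple[str, ...]
    config: ModelConfig
    seed: int

    @property
    def n_chains(self) -> int:
        sm = next(iter(self.beta))
        lake = next(iter(self.beta[sm]))
        return self.beta[sm][lake].shape[0]

    def coefficient(self, submodel: str, lake_id: str, term: str) -> np.ndarray:
        """Draws for one coefficient, shape (chains, iterations)."""
        idx = self.terms[submodel][lake_id].index(term)
        return self.beta[submodel][lake_id][:, :, idx]

    def param_dict(self, include_nuisance: bool = False) -> dict[str, np.ndarray]:
        """Registry name → (chains, iterations) array for all coefficients."""
        out: dict[str, np.ndarray] = {}
        for sm, lakes in self.beta.items():
            for lake_id, arr in lakes.items():
                for j, term in enumerate(self.terms[sm][lake_id]):
                    out[f"beta_{sm}[{lake_id}][{term}]"] = arr[:, :, j]
        if include_nuisance:
            for sm, lakes in self.sigma.items():
                for lake_id, arr in lakes.items():
                    out[f"sigma_{sm}[{lake_id}]"] = arr
            for sm, arr in self.g.items():
                out[f"g_{sm}"] = arr
        return out

    def coefficient_sets(self, lake_id: str) -> list[CoefficientSet]:
        """Flatten the chains into a list-like of per-draw coefficient sets.

        Returns a lightweight view used by the Monte-Carlo stage: a dict of
        (n_draws, n_terms) arrays per submodel, chains concatenated.
        """
        flat_beta = {
            sm: self.beta[sm][lake_id].reshape(-1, self.beta[sm][lake_id].shape[-1])
            for sm in self.beta
        }
        return flat_beta  # type: ignore[return-value]

    def save(self, directory) -> None:
        """Persist draws as a columnar container plus a registry sidecar.

        Writes ``draws.npz`` (one array per parameter group) and
        ``registry.json`` naming every coefficient column and the sampler
        settings.
        """
        from pathlib import Path
        import json
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for sm in self.beta:
            for lid, arr in self.beta[sm].items():
                arrays[f"beta/{sm}/{lid}"] = arr
                arrays[f"sigma/{sm}/{lid}"] = self.sigma[sm][lid]
            arrays[f"g/{sm}"] = self.g[sm]
        np.savez_compressed(directory / "draws.npz", **arrays)
        registry = {
            "lake_ids": list(self.lake_ids),
            "terms": {sm: {lid: list(t) for lid, t in lakes.items()}
                      for sm, lakes in self.terms.items()},
            "seed": self.seed,
            "chains": self.config.chains,
            "burn_in": self.config.burn_in,
            "retained": self.config.retained,
            "thinning": self.config.thinning,
        }
        with open(directory / "registry.json", "w") as fh:
            json.dump(registry, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        """Load draws written by :meth:`save`."""
        from pathlib import Path
        import json
        directory = Path(directory)
        with open(directory / "registry.json") as fh:
            registry = json.load(fh)
        data = np.load(directory / "draws.npz")
        terms = {sm: {lid: tuple(t) for lid, t in lakes.items()}
                 for sm, lakes in registry["terms"].items()}
        beta = {sm: {lid: data[f"beta/{sm}/{lid}"] for lid in lakes}
                for sm, lakes in terms.items()}
        sigma = {sm: {lid: data[f"sigma/{sm}/{lid}"] for lid in lakes}
                 for sm, lakes in terms.items()}
        g = {sm: data[f"g/{sm}"] for sm in terms}
        config = ModelConfig(
            chains=registry["chains"], burn_in=registry["burn_in"],
            retained=registry["retained"], thinning=registry["thinning"],
            seed=registry["seed"], submodels=tuple(terms))
        return cls(beta, sigma, g, terms, tuple(registry["lake_ids"]),
                   config, registry["seed"])

    def summary(self) -> pd.DataFrame:
        """Posterior median and central 50% interval per coefficient."""
        rows = []
        for name, arr in self.param_dict().items():
            flat = arr.reshape(-1)
            q25, q50, q75 = np.quantile(flat, [0.25, 0.5, 0.75])
            rows.append({"parameter": name, "median": q50,
                         "q25": q25, "q75": q75})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Log joint density (validation / testing aid)
# ---------------------------------------------------------------------------

def log_joint(
    coeffs: Mapping[str, CoefficientSet],
    priors: PriorSpec | None,
    panels: Mapping[str, LakePanel],
    g: Mapping[str, float] | None = None,
    submodels: Sequence[str] = SUBMODELS,
    sigma_hyper: tuple[float, float] = (0.001, 0.001),
    g_hyper: tuple[float, float] = (0.001, 0.001),
) -> float:
    """Joint log density: Gaussian likelihood + MVN priors + hyperpriors.

    With ``priors=None`` only the likelihood portion is returned (flat-prior
    limit).  Non-finite (−inf) on any σ ≤ 0.
    """
    total = 0.0
    for lake_id, panel in panels.items():
        cs = coeffs[lake_id]
        if any(cs.sigma[sm] <= 0 for sm in submodels):
            return -np.inf
        data = _LakeData(panel, cs.stocking_eligible, submodels)
        if "WT" in submodels:
            r = data.y_wt - data.X_wt @ np.asarray(cs.beta["WT"])
            total += norm.logpdf(r, scale=cs.sigma["WT"]).sum()
        if "dWL" in submodels:
            r = data.y_wl - data.X_wl @ np.asarray(cs.beta["dWL"])
            total += norm.logpdf(r, scale=cs.sigma["dWL"]).sum()
        if "CHL" in submodels:
            bC = np.asarray(cs.beta["CHL"])
            mu_wt = data.Awt_chl @ np.asarray(cs.beta["WT"])
            mu_dwl = data.Awl_chl @ np.asarray(cs.beta["dWL"])
            mu = data.Z_chl @ bC[:3] + bC[3] * mu_dwl + bC[4] * mu_wt
            total += norm.logpdf(data.y_chl - mu, scale=cs.sigma["CHL"]).sum()
        if "CATCH" in submodels:
            bC = np.asarray(cs.beta["CHL"])
            bK = np.asarray(cs.beta["CATCH"])
            mu_wt = data.Awt_c @ np.asarray(cs.beta["WT"])
            mu_dwl = data.Awl_c @ np.asarray(cs.beta["dWL"])
            mu_chl = data.Z_chl_c @ bC[:3] + bC[3] * mu_dwl + bC[4] * mu_wt
            mu = (bK[1] * mu_wt + bK[2] * mu_dwl + bK[3] * mu_chl
                  + data._catch_offsets(bK))
            total += norm.logpdf(data.y_c - mu, scale=cs.sigma["CATCH"]).sum()
    if priors is None:
        return float(total)
    if g is None:
        raise ValueError("g values required when priors are given")
    from scipy.stats import invgamma, multivariate_normal
    a_s, b_s = sigma_hyper
    a_g, b_g = g_hyper
    for sm in submodels:
        sp = priors.submodels[sm]
        gv = g[sm]
        if gv <= 0:
            return -np.inf
        for lake_id in panels:
            cs = coeffs[lake_id]
            total += multivariate_normal.logpdf(
                np.asarray(cs.beta[sm]), mean=sp.means[lake_id],
                cov=gv * sp.covs_unscaled[lake_id])
            total += invgamma.logpdf(cs.sigma[sm] ** 2, a_s, scale=b_s)
        total += invgamma.logpdf(gv, a_g, scale=b_g)
    return float(total)


# ---------------------------------------------------------------------------
# Block Gibbs sampler
# ---------------------------------------------------------------------------

def _draw_mvn_canonical(P: np.ndarray, h: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P⁻¹h, P⁻¹) given precision P and linear term h."""
    try:
        L = cholesky(P, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical safety
        P = P + 1e-10 * np.eye(len(P)) * max(1.0, np.trace(P) / len(P))
        L = cholesky(P, lower=True)
    u = solve_triangular(L, h, lower=True)
    z = rng.standard_normal(len(h))
    return solve_triangular(L.T, u + z, lower=False)


def _invgamma_draw(a: float, b: float, rng: np.random.Generator) -> float:
    return b / rng.gamma(a)


class _LakeState:
    """Mutable per-lake sampler state (current coefficient blocks and σ)."""

    __slots__ = ("beta", "sigma")

    def __init__(self, beta: dict[str, np.ndarray], sigma: dict[str, float]):
        self.beta = beta
        self.sigma = sigma


def run_mcmc(
    panels: Mapping[str, LakePanel],
    priors: PriorSpec,
    config: ModelConfig | None = None,
    seed: int | None = None,
    stocking: Mapping[str, bool] | None = None,
) -> PosteriorDraws:
    """Sample the posterior by block Gibbs.

    Per iteration and lake each submodel's coefficient block is drawn from
    its exact Gaussian full conditional (the network is linear in every block
    given the others), then each σ² from its conjugate inverse-gamma, and
    finally each submodel's shared prior scale g from its conjugate
    inverse-gamma given all lakes' coefficient deviations from the prior
    means.  Chains start at the prior means plus Normal(0, 0.1 × prior SD)
    perturbations.  Fully reproducible given ``seed``.
    """
    config = config or ModelConfig()
    if seed is None:
        seed = config.seed
    stocking = stocking or {}
    submodels = config.submodels
    lake_ids = tuple(sorted(panels))
    data = {
        lid: _LakeData(panels[lid], stocking.get(lid, False), submodels)
        for lid in lake_ids
    }
    # prior precision pieces
    Vinv: dict[str, dict[str, np.ndarray]] = {}
    Vinv_m: dict[str, dict[str, np.ndarray]] = {}
    for sm in submodels:
        sp = priors.submodels[sm]
        Vinv[sm] = {lid: np.linalg.inv(sp.covs_unscaled[lid]) for lid in lake_ids}
        Vinv_m[sm] = {lid: Vinv[sm][lid] @ sp.means[lid] for lid in lake_ids}

    a_s, b_s = config.sigma_hyper
    a_g, b_g = config.g_hyper
    n_keep = config.retained
    thin = max(1, config.thinning)

    # output containers
    beta_out = {sm: {lid: np.empty((config.chains, n_keep,
                                    len(priors.submodels[sm].means[lid])))
                     for lid in lake_ids} for sm in submodels}
    sigma_out = {sm: {lid: np.empty((config.chains, n_keep))
                      for lid in lake_ids} for sm in submodels}
    g_out = {sm: np.empty((config.chains, n_keep)) for sm in submodels}

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.chains)

    for chain in range(config.chains):
        rng = np.random.default_rng(chain_seeds[chain])
        # --- initialize ---
        g_cur = {sm: (config.fixed_g[sm] if config.fixed_g else 1.0)
                 for sm in submodels}
        states: dict[str, _LakeState] = {}
        for lid in lake_ids:
            beta0 = {}
            sigma0 = {}
            for sm in submodels:
                sp = priors.submodels[sm]
                mean = sp.means[lid]
                # correlated perturbation 0.1 × the prior shape: shifts the
                # coefficients without displacing the fitted values much
                # (independent per-coordinate noise can start a chain on a
                # bad regression line and trap it in a degenerate mode)
                L = cholesky(g_cur[sm] * sp.covs_unscaled[lid], lower=True)
                beta0[sm] = mean + 0.1 * (L @ rng.standard_normal(len(mean)))
            states[lid] = _LakeState(beta0, sigma0)
        for lid in lake_ids:
            st = states[lid]
            for sm in submodels:
                if config.fixed_sigma:
                    st.sigma[sm] = float(config.fixed_sigma[sm])
                else:
                    # start σ at the lake's LS residual SD: chains whose σ
                    # starts inflated can wander into a weak-likelihood mode
                    rv = priors.submodels[sm].resid_var.get(lid)
                    if rv is None:
                        ssr, n = _submodel_ssr(data[lid], st, sm)
                        rv = ssr / max(n, 1)
                    st.sigma[sm] = max(float(np.sqrt(rv)), 1e-3)

        total_iter = config.burn_in + n_keep * thin
        kept = 0
        for it in range(total_iter):
            for lid in lake_ids:
                _update_lake(data[lid], states[lid], Vinv, Vinv_m,
                             g_cur, submodels, rng)
                if not config.fixed_sigma:
                    _update_sigmas(data[lid], states[lid], submodels,
                                   a_s, b_s, rng)
            if not config.fixed_g:
                for sm in submodels:
                    quad = 0.0
                    p_tot = 0
                    for lid in lake_ids:
                        d = states[lid].beta[sm] - priors.submodels[sm].means[lid]
                        quad += float(d @ Vinv[sm][lid] @ d)
                        p_tot += len(d)
                    g_cur[sm] = _invgamma_draw(a_g + p_tot / 2,
                                               b_g + quad / 2, rng)
            if it >= config.burn_in and (it - config.burn_in) % thin == 0:
                for lid in lake_ids:
                    st = states[lid]
                    for sm in submodels:
                        beta_out[sm][lid][chain, kept] = st.beta[sm]
                        sigma_out[sm][lid][chain, kept] = st.sigma[sm]
                for sm in submodels:
                    g_out[sm][chain, kept] = g_cur[sm]
                kept += 1
        if kept != n_keep:  # pragma: no cover - consistency guard
            raise RuntimeError("retained-draw bookkeeping error")
        # divergence check once per chain (values are exchanged every
        # iteration, so a non-finite state would propagate and be caught here)
        for sm in submodels:
            for lid in lake_ids:
                if not np.isfinite(beta_out[sm][lid][chain]).all():
                    raise FloatingPointError(
                        f"chain {chain}: non-finite draws for {sm} in lake "
                        f"{lid}; check data scaling and priors"
                    )

    terms = {sm: {lid: priors.submodels[sm].terms[lid] for lid in lake_ids}
             for sm in submodels}
    return PosteriorDraws(beta_out, sigma_out, g_out, terms, lake_ids,
                          config, seed)


def _submodel_ssr(d: _LakeData, st: _LakeState, sm: str) -> tuple[float, int]:
    """Sum of squared residuals and row count for one submodel."""
    if sm == "WT":
        r = d.y_wt - d.X_wt @ st.beta["WT"]
        return float(r @ r), d.n_wt
    if sm == "dWL":
        r = d.y_wl - d.X_wl @ st.beta["dWL"]
        return float(r @ r), d.n_wl
    if sm == "CHL":
        bC = st.beta["CHL"]
        mu = (d.Z_chl @ bC[:3] + bC[3] * (d.Awl_chl @ st.beta["dWL"])
              + bC[4] * (d.Awt_chl @ st.beta["WT"]))
        r = d.y_chl - mu
        return float(r @ r), d.n_chl
    if sm == "CATCH":
        bC = st.beta["CHL"]
        bK = st.beta["CATCH"]
        mu_wt = d.Awt_c @ st.beta["WT"]
        mu_dwl = d.Awl_c @ st.beta["dWL"]
        mu_chl = d.Z_chl_c @ bC[:3] + bC[3] * mu_dwl + bC[4] * mu_wt
        mu = bK[1] * mu_wt + bK[2] * mu_dwl + bK[3] * mu_chl + d._catch_offsets(bK)
        r = d.y_c - mu
        return float(r @ r), d.n_c
    raise ValueError(sm)


def _update_sigmas(d: _LakeData, st: _LakeState, submodels: Sequence[str],
                   a_s: float, b_s: float, rng: np.random.Generator) -> None:
    for sm in submodels:
        ssr, n = _submodel_ssr(d, st, sm)
        var = _invgamma_draw(a_s + n / 2, b_s + ssr / 2, rng)
        st.sigma[sm] = float(np.sqrt(var))


def _update_lake(d: _LakeData, st: _LakeState,
                 Vinv: Mapping[str, Mapping[str, np.ndarray]],
                 Vinv_m: Mapping[str, Mapping[str, np.ndarray]],
                 g: Mapping[str, float], submodels: Sequence[str],
                 rng: np.random.Generator) -> None:
    """One Gibbs sweep over this lake's coefficient blocks."""
    has_chl = "CHL" in submodels
    has_catch = "CATCH" in submodels
    lid = d.lake_id

    # --- beta_WT block ----------------------------------------------------
    if "WT" in submodels:
        w = 1.0 / st.sigma["WT"] ** 2
        P = w * d.XtX_wt + Vinv["WT"][lid] / g["WT"]
        h = w * d.Xty_wt + Vinv_m["WT"][lid] / g["WT"]
        if has_chl and d.n_chl:
            bC = st.beta["CHL"]
            wc = 1.0 / st.sigma["CHL"] ** 2
            r = (d.y_chl - d.Z_chl @ bC[:3]
                 - bC[3] * (d.Awl_chl @ st.beta["dWL"]))
            P += wc * bC[4] ** 2 * d.G_wt_chl
            h += wc * bC[4] * (d.Awt_chl.T @ r)
        if has_catch and d.n_c:
            bC = st.beta["CHL"]
            bK = st.beta["CATCH"]
            wk = 1.0 / st.sigma["CATCH"] ** 2
            a = bK[1] + bK[3] * bC[4]
            mu_dwl = d.Awl_c @ st.beta["dWL"]
            r = (d.y_c - d._catch_offsets(bK) - bK[2] * mu_dwl
                 - bK[3] * (d.Z_chl_c @ bC[:3] + bC[3] * mu_dwl))
            P += wk * a ** 2 * d.G_wt_c
            h += wk * a * (d.Awt_c.T @ r)
        st.beta["WT"] = _draw_mvn_canonical(P, h, rng)

    # --- beta_dWL block ---------------------------------------------------
    if "dWL" in submodels:
        w = 1.0 / st.sigma["dWL"] ** 2
        P = w * d.XtX_wl + Vinv["dWL"][lid] / g["dWL"]
        h = w * d.Xty_wl + Vinv_m["dWL"][lid] / g["dWL"]
        if has_chl and d.n_chl:
            bC = st.beta["CHL"]
            wc = 1.0 / st.sigma["CHL"] ** 2
            r = (d.y_chl - d.Z_chl @ bC[:3]
                 - bC[4] * (d.Awt_chl @ st.beta["WT"]))
            P += wc * bC[3] ** 2 * d.G_wl_chl
            h += wc * bC[3] * (d.Awl_chl.T @ r)
        if has_catch and d.n_c:
            bC = st.beta["CHL"]
            bK = st.beta["CATCH"]
            wk = 1.0 / st.sigma["CATCH"] ** 2
            a = bK[2] + bK[3] * bC[3]
            mu_wt = d.Awt_c @ st.beta["WT"]
            r = (d.y_c - d._catch_offsets(bK) - bK[1] * mu_wt
                 - bK[3] * (d.Z_chl_c @ bC[:3] + bC[4] * mu_wt))
            P += wk * a ** 2 * d.G_wl_c
            h += wk * a * (d.Awl_c.T @ r)
        st.beta["dWL"] = _draw_mvn_canonical(P, h, rng)

    # --- beta_CHL block ---------------------------------------------------
    if has_chl:
        wc = 1.0 / st.sigma["CHL"] ** 2
        mu_wt_chl = d.Awt_chl @ st.beta["WT"]
        mu_dwl_chl = d.Awl_chl @ st.beta["dWL"]
        X = np.column_stack([d.Z_chl, mu_dwl_chl, mu_wt_chl])
        P = wc * (X.T @ X) + Vinv["CHL"][lid] / g["CHL"]
        h = wc * (X.T @ d.y_chl) + Vinv_m["CHL"][lid] / g["CHL"]
        if has_catch and d.n_c:
            bK = st.beta["CATCH"]
            wk = 1.0 / st.sigma["CATCH"] ** 2
            mu_wt_c = d.Awt_c @ st.beta["WT"]
            mu_dwl_c = d.Awl_c @ st.beta["dWL"]
            Xc = np.column_stack([d.Z_chl_c, mu_dwl_c, mu_wt_c])
            r = (d.y_c - d._catch_offsets(bK)
                 - bK[1] * mu_wt_c - bK[2] * mu_dwl_c)
            P += wk * bK[3] ** 2 * (Xc.T @ Xc)
            h += wk * bK[3] * (Xc.T @ r)
        st.beta["CHL"] = _draw_mvn_canonical(P, h, rng)

    # --- beta_CATCH block ---------------------------------------------------
    if has_catch:
        bC = st.beta["CHL"]
        wk = 1.0 / st.sigma["CATCH"] ** 2
        mu_wt_c = d.Awt_c @ st.beta["WT"]
        mu_dwl_c = d.Awl_c @ st.beta["dWL"]
        mu_chl_c = d.Z_chl_c @ bC[:3] + bC[3] * mu_dwl_c + bC[4] * mu_wt_c
        cols = [np.ones(d.n_c), mu_wt_c, mu_dwl_c, mu_chl_c]
        if d.eligible:
            cols.append(d.log_st)
        cols.append(d.log_eff)
        X = np.column_stack(cols)
        P = wk * (X.T @ X) + Vinv["CATCH"][lid] / g["CATCH"]
        h = wk * (X.T @ d.y_c) + Vinv_m["CATCH"][lid] / g["CATCH"]
        st.beta["CATCH"] = _draw_mvn_canonical(P, h, rng)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for one parameter.

    ``x`` has shape (chains, iterations); each chain is halved, so m chains
    of length n become 2m of length n//2.  Returns ``NaN`` when the
    within-chain variance is zero (degenerate chains are flagged upstream,
    not silently reported as converged).
    """
    m, n = x.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 iterations per chain")
    halves = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        return float("nan")
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * W + B_over_n
    # var_hat can undershoot W by sampling noise; 1 is the diagnostic's floor
    return float(max(1.0, np.sqrt(var_hat / W)))


def lag_autocorr(x: np.ndarray, lag: int = 1) -> float:
    """Mean lag-k autocorrelation across chains for one parameter."""
    m, n = x.shape
    vals = []
    for c in range(m):
        a = x[c] - x[c].mean()
        denom = float(a @ a)
        if denom == 0:
            vals.append(np.nan)
        else:
            vals.append(float(a[:-lag] @ a[lag:]) / denom)
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def gelman_rubin(
    draws: PosteriorDraws | Mapping[str, np.ndarray],
    include_nuisance: bool = False,
) -> pd.DataFrame:
    """Split-R̂ and lag-1 autocorrelation per parameter.

    Accepts a :class:`PosteriorDraws` or a mapping name → (chains,
    iterations).  Parameters with zero within-chain variance get
    ``rhat = NaN`` and ``undefined = True``.
    """
    params = (draws.param_dict(include_nuisance)
              if isinstance(draws, PosteriorDraws) else dict(draws))
    rows = []
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need >=2 chains of draws")
        if arr.shape[1] < 10:
            raise ValueError(f"{name}: need >=10 retained iterations")
        r = split_rhat(arr)
        rows.append({
            "parameter": name,
            "rhat": r,
            "undefined": bool(np.isnan(r)),
            "lag1_autocorr": lag_autocorr(arr),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def classify_coefficient(draws: np.ndarray, level: float = 0.75) -> str:
    """Directional call from the one-tailed credible intervals of a coefficient.

    ``positive`` if the lower one-tailed interval [q₁₋L, ∞) excludes 0 (i.e.
    the 1−level quantile is above 0), ``negative`` if (−∞, q_L] excludes 0,
    ``mixed`` otherwise — equivalently, mixed iff 0 lies inside the central
    2·level−1 interval.
    """
    flat = np.asarray(draws, dtype=float).reshape(-1)
    if flat.size == 0:
        raise ValueError("empty draws")
    lo, hi = np.quantile(flat, [1 - level, level])
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "mixed"


#: The 13 predictor → response pairs of the network, in presentation order.
EFFECT_PAIRS = (
    ("AT", "WT"), ("AT", "WL"),
    ("PRE", "WL"), ("PRE", "CHL"),
    ("LUag", "WL"), ("LUag", "CHL"),
    ("WT", "CHL"), ("WT", "CATCH"),
    ("WL", "CHL"), ("WL", "CATCH"),
    ("CHL", "CATCH"),
    ("ST", "CATCH"), ("EFF", "CATCH"),
)

_DIRECT_PAIR_COEF = {
    ("AT", "WT"): ("WT", "AT"),
    ("PRE", "WL"): ("dWL", "PRE"),
    ("PRE", "CHL"): ("CHL", "log_PRE"),
    ("LUag", "CHL"): ("CHL", "log_LUag"),
    ("WT", "CHL"): ("CHL", "mu_WT"),
    ("WT", "CATCH"): ("CATCH", "mu_WT"),
    ("WL", "CHL"): ("CHL", "mu_dWL"),
    ("WL", "CATCH"): ("CATCH", "mu_dWL"),
    ("CHL", "CATCH"): ("CATCH", "mu_CHL"),
    ("ST", "CATCH"): ("CATCH", "log_ST"),
    ("EFF", "CATCH"): ("CATCH", "log_EFF"),
}


def pair_effect_draws(
    posterior: PosteriorDraws,
    lake_id: str,
    pair: tuple[str, str],
    medians: Mapping[str, float] | None = None,
    pe_at_slope: float | None = None,
) -> np.ndarray:
    """Per-draw effect strength for one variable pair in one lake.

    Eleven of the thirteen pairs map to a single coefficient.  The two
    composite pairs go through PE: AT→WL is (β₂ + β₃·LUag_med)·(dPE/dAT)
    — air temperature moves the water balance only through potential
    evaporation — and LUag→WL is β₃·PE_med.
    """
    if pair in _DIRECT_PAIR_COEF:
        sm, term = _DIRECT_PAIR_COEF[pair]
        return posterior.coefficient(sm, lake_id, term)
    if pair == ("AT", "WL"):
        if medians is None or pe_at_slope is None:
            raise ValueError("AT→WL needs LUag median and the PE–AT slope")
        b2 = posterior.coefficient("dWL", lake_id, "PE")
        b3 = posterior.coefficient("dWL", lake_id, "PExLUag")
        return (b2 + b3 * medians["LUag"]) * pe_at_slope
    if pair == ("LUag", "WL"):
        if medians is None:
            raise ValueError("LUag→WL needs the PE median")
        b3 = posterior.coefficient("dWL", lake_id, "PExLUag")
        return b3 * medians["PE"]
    raise KeyError(pair)


def effects_table(
    posterior: PosteriorDraws,
    medians: Mapping[str, Mapping[str, float]],
    pe_at_slopes: Mapping[str, float],
    stocking: Mapping[str, bool] | None = None,
    level: float = 0.75,
) -> pd.DataFrame:
    """Counts of positive / negative / mixed effects per variable pair.

    One row per pair; the counts sum to the number of lakes, except the
    ST→CATCH row, which counts only the stocking-eligible lakes.
    """
    stocking = stocking or {}
    rows = []
    for pair in EFFECT_PAIRS:
        counts = {"positive": 0, "negative": 0, "mixed": 0}
        for lake_id in posterior.lake_ids:
            if pair == ("ST", "CATCH") and not stocking.get(lake_id, False):
                continue
            draws = pair_effect_draws(posterior, lake_id, pair,
                                      medians[lake_id], pe_at_slopes[lake_id])
            counts[classify_coefficient(draws, level)] += 1
        rows.append({"predictor": pair[0], "response": pair[1], **counts})
    return pd.DataFrame(rows)


def stocking_eligible(contributions: Sequence[float],
                      threshold: float = 0.20,
                      min_years: int = 10) -> bool:
    """Whether stocking matters enough to estimate its catch effect.

    True iff stocked species contributed strictly more than ``threshold``
    (20%) of the catch in strictly more than ``min_years`` (10) years.
    """
    arr = np.asarray(contributions, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("contribution fractions must lie in [0, 1]")
    return int((arr > threshold).sum()) > min_years
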