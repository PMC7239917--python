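"""Lake-wise least-squares anchors and multivariate-normal priors.

Each of the four conditional submodels (WT, dWL, CHL, CATCH) is first fitted
lake by lake as an ordinary linear model on the years where its response and
all predictors are observed.  The per-lake prior for that submodel's
coefficient vector is then multivariate normal with

* mean = the lake's least-squares estimates, and
* covariance = g × (XᵀX)⁻¹, the *unscaled* least-squares covariance (no
  residual-variance multiplier), with a single positive scale hyperparameter
  g per submodel shared across lakes and given a noninformative hyperprior.

The shared g is the pooling channel: lakes with more observed years have a
larger XᵀX, hence a tighter prior relative to lakes with sparse records, so
the relative weight of lake-specific information grows with its sample size.

For the CHL and CATCH designs, the upstream predicted means that appear in
the estimation equations are replaced by their *observed* counterparts here
(observed WT, dWL and log CHL): the plug-in means do not exist before
estimation, and this substitution affects only the prior, not the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import LakePanel

SUBMODELS = ("WT", "dWL", "CHL", "CATCH")

#: Design-term names per submodel (intercept first).  ``log_ST`` appears in
#: the CATCH design only for stocking-eligible lakes.
TERMS = {
    "WT": ("intercept", "AT"),
    "dWL": ("intercept", "PRE", "PE", "PExLUag"),
    "CHL": ("intercept", "log_PRE", "log_LUag", "mu_dWL", "mu_WT"),
    "CATCH": ("intercept", "mu_WT", "mu_dWL", "mu_CHL", "log_ST", "log_EFF"),
}


def submodel_terms(submodel: str, stocking_eligible: bool = True) -> tuple[str, ...]:
    terms = TERMS[submodel]
    if submodel == "CATCH" and not stocking_eligible:
        terms = tuple(t for t in terms if t != "log_ST")
    return terms


def build_ls_design(
    panel: LakePanel, submodel: str, stocking_eligible: bool = True
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Response vector and design matrix for one lake's least-squares fit.

    Rows are the years where the response and every predictor are observed
    (and positive where a log is taken).  Returns ``(y, X, term_names)``.
    """
    df = panel.df
    if submodel == "WT":
        need = df[["WT", "AT"]].notna().all(axis=1)
        sub = df[need]
        y = sub["WT"].to_numpy()
        X = np.column_stack([np.ones(len(sub)), sub["AT"].to_numpy()])
    elif submodel == "dWL":
        need = df[["dWL", "PRE", "PE", "LUag"]].notna().all(axis=1)
        sub = df[need]
        y = sub["dWL"].to_numpy()
        X = np.column_stack([
            np.ones(len(sub)),
            sub["PRE"].to_numpy(),
            sub["PE"].to_numpy(),
            (sub["PE"] * sub["LUag"]).to_numpy(),
        ])
    elif submodel == "CHL":
        need = (
            df[["CHL", "PRE", "LUag", "dWL", "WT"]].notna().all(axis=1)
            & (df["CHL"] > 0) & (df["PRE"] > 0) & (df["LUag"] > 0)
        )
        sub = df[need]
        y = np.log(sub["CHL"].to_numpy())
        X = np.column_stack([
            np.ones(len(sub)),
            np.log(sub["PRE"].to_numpy()),
            np.log(sub["LUag"].to_numpy()),
            sub["dWL"].to_numpy(),
            sub["WT"].to_numpy(),
        ])
    elif submodel == "CATCH":
        cols = ["CATCH", "WT", "dWL", "CHL", "EFF"]
        if stocking_eligible:
            cols.append("ST")
        need = df[cols].notna().all(axis=1) & (df["CATCH"] > 0) & (df["CHL"] > 0) & (df["EFF"] > 0)
        if stocking_eligible:
            need &= df["ST"] > 0
        sub = df[need]
        columns = [
            np.ones(len(sub)),
            sub["WT"].to_numpy(),
            sub["dWL"].to_numpy(),
            np.log(sub["CHL"].to_numpy()),
        ]
        if stocking_eligible:
            columns.append(np.log(sub["ST"].to_numpy()))
        columns.append(np.log(sub["EFF"].to_numpy()))
        y = np.log(sub["CATCH"].to_numpy())
        X = np.column_stack(columns)
    else:
        raise ValueError(f"unknown submodel {submodel!r}")
    return y, X, submodel_terms(submodel, stocking_eligible)


@dataclass
class LeastSquaresResult:
    """OLS estimates and unscaled covariance for one lake × submodel."""

    lake_id: str
    submodel: str
    terms: tuple[str, ...]
    beta: np.ndarray
    cov_unscaled: np.ndarray  # (XᵀX)⁻¹, no residual-variance scaling
    resid_var: float
    n_used: int


def _collinear_columns(X: np.ndarray, terms: tuple[str, ...]) -> list[str]:
    """Names of columns implicated in a rank deficiency (via SVD null space)."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if len(s) else 0.0
    null = vt[s <= tol] if len(s) else vt
    if null.size == 0:
        return []
    weight = np.abs(null).max(axis=0)
    return [t for t, w in zip(terms, weight) if w > 1e-8]


def least_squares_fit(
    panel: LakePanel, submodel: str, stocking_eligible: bool = True
) -> LeastSquaresResult:
    """Ordinary least squares for one lake's submodel.

    Raises ``ValueError`` on a rank-deficient design (naming the collinear
    columns) or when fewer than p + 1 usable years are available.
    """
    y, X, terms = build_ls_design(panel, submodel, stocking_eligible)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(
            f"lake {panel.lake_id!r} submodel {submodel}: {n} usable years "
            f"for {p} coefficients (need at least {p + 1})"
        )
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        cols = _collinear_columns(X, terms)
        raise ValueError(
            f"lake {panel.lake_id!r} submodel {submodel}: rank-deficient design "
            f"(rank {rank} < {p}); collinear columns: {cols}"
        )
    cov = np.linalg.inv(xtx)
    beta = cov @ (X.T @ y)
    resid = y - X @ beta
    resid_var = float(resid @ resid / (n - p)) if n > p else 0.0
    return LeastSquaresResult(panel.lake_id, submodel, terms, beta, cov, resid_var, n)


@dataclass
class SubmodelPrior:
    """Per-lake MVN priors for one submodel plus the shared g hyperprior.

    ``resid_var`` keeps each lake's least-squares residual variance: it is
    not part of the prior itself but initializes the σ chains at the
    empirical noise scale, which keeps early Gibbs sweeps anchored to the
    data-supported region.
    """

    submodel: str
    means: dict[str, np.ndarray]
    covs_unscaled: dict[str, np.ndarray]
    terms: dict[str, tuple[str, ...]]
    n_used: dict[str, int]
    g_hyper: tuple[float, float] = (0.001, 0.001)
    resid_var: dict[str, float] = field(default_factory=dict)

    def cov(self, lake_id: str, g: float) -> np.ndarray:
        """Prior covariance for one lake at hyperparameter value g."""
        if g <= 0:
            raise ValueError("g must be positive")
        return g * self.covs_unscaled[lake_id]


@dataclass
class PriorSpec:
    """Full prior specification: one :class:`SubmodelPrior` per submodel."""

    submodels: dict[str, SubmodelPrior] = field(default_factory=dict)
    sigma_hyper: tuple[float, float] = (0.001, 0.001)

    def to_text(self) -> str:
        """Human-readable audit dump of all prior means and covariances."""
        lines = []
        for name, sp in self.submodels.items():
            lines.append(f"[{name}] g ~ inv-gamma{sp.g_hyper}")
            for lake in sorted(sp.means):
                mean = np.array2string(sp.means[lake], precision=6)
                lines.append(f"  lake {lake}: mean {mean} "
                             f"(n={sp.n_used[lake]}, terms={sp.terms[lake]})")
        lines.append(f"sigma^2 ~ inv-gamma{self.sigma_hyper} (all submodels)")
        return "\n".join(lines)


def build_prior(
    ls_results: Mapping[str, LeastSquaresResult],
    submodel: str,
    g_hyper: tuple[float, float] = (0.001, 0.001),
) -> SubmodelPrior:
    """Assemble per-lake MVN priors for one submodel from the OLS fits.

    Prior mean is each lake's least-squares estimate; the prior covariance is
    g × (XᵀX)⁻¹ with one g shared across lakes, inverse-gamma hyperprior by
    default.  Raises if any unscaled covariance is not positive definite.
    """
    means, covs, terms, n_used, resid_var = {}, {}, {}, {}, {}
    for lake_id, res in ls_results.items():
        if res.submodel != submodel:
            raise ValueError(f"result for {res.submodel} passed to {submodel} prior")
        eig = np.linalg.eigvalsh(res.cov_unscaled)
        if eig.min() <= 0:
            raise ValueError(
                f"lake {lake_id!r} submodel {submodel}: covariance not positive definite"
            )
        means[lake_id] = res.beta.copy()
        covs[lake_id] = res.cov_unscaled.copy()
        terms[lake_id] = res.terms
        n_used[lake_id] = res.n_used
        resid_var[lake_id] = res.resid_var
    return SubmodelPrior(submodel, means, covs, terms, n_used, g_hyper,
                         resid_var)


def build_priors(
    panels: Mapping[str, LakePanel],
    stocking: Mapping[str, bool] | None = None,
    g_hyper: tuple[float, float] = (0.001, 0.001),
    sigma_hyper: tuple[float, float] = (0.001, 0.001),
) -> PriorSpec:
    """Fit all lakes × submodels by OLS and assemble the full prior spec."""
    stocking = stocking or {}
    spec = PriorSpec(sigma_hyper=sigma_hyper)
    for submodel in SUBMODELS:
        results = {
            lake_id: least_squares_fit(
                panel, submodel, stocking.get(lake_id, False)
            )
            for lake_id, panel in panels.items()
        }
        spec.submodels[submodel] = build_prior(results, submodel, g_hyper)
    return spec
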