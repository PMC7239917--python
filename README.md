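# lakebnm

Bayesian networks modelling of how climate and land-use change propagate to
lake fish catches, for quantitative ecologists and fisheries scientists
working with heterogeneous multi-lake monitoring panels.

Annual catches respond to climate (air temperature AT, precipitation PRE)
and land use (agricultural share of the catchment, LUag) only indirectly,
through the lake environment: water temperature (WT), water-level change
(ΔWL) and primary productivity (chlorophyll-a, CHL). `lakebnm` estimates
that causal chain as a recursive system of conditional Gaussian regressions,
fitted jointly per lake *i* and year:

```
WT         ~ N(μ_WT,    σ_WT),     μ_WT    = β₀ + β₁·AT
ΔWL        ~ N(μ_ΔWL,   σ_ΔWL),    μ_ΔWL   = β₀ + β₁·PRE + β₂·PE + β₃·PE·LUag
log CHL    ~ N(μ_CHL,   σ_CHL),    μ_CHL   = β₀ + β₁·log PRE + β₂·log LUag
                                             + β₃·μ_ΔWL + β₄·μ_WT
log CATCH  ~ N(μ_CATCH, σ_CATCH),  μ_CATCH = β₀ + β₁·μ_WT + β₂·μ_ΔWL + β₃·μ_CHL
                                             + β₄·log ST + β₅·log EFF
```

where PE is potential evaporation, ST fish stocked per hectare (included
only for lakes where stocked species contributed >20% of catches in >10
years) and EFF a fishing-effort index. Downstream means consume upstream
*predicted* means μ, so every observation informs every coefficient — the
property that makes the model usable on panels where, say, chlorophyll was
measured in only 9 of 45 years.

The package covers the full analysis:

* **Synthetic studies** (`lakebnm.synth`) — multi-lake panels with known
  coefficients, per-variable missingness and plantable correlations between
  lake characteristics and driver sensitivity, so every stage is testable
  without restricted monitoring data.
* **Priors** (`lakebnm.priors`) — per-lake least-squares fits; MVN priors
  centered there with covariance g·(XᵀX)⁻¹ and a shared noninformative
  scale hyperparameter g per submodel.
* **Estimation** (`lakebnm.inference`) — block-Gibbs MCMC (each coefficient
  block has an exact Gaussian full conditional), split Gelman–Rubin
  diagnostics, and classification of all 13 variable-pair effects as
  positive / negative / mixed from one-tailed 75% credible intervals.
* **Scenario sampling** (`lakebnm.assessment`) — Monte-Carlo acceptance
  sampling of driver changes associated with a 25% catch decrease
  (predicted catch ratio in [0.74, 0.76]), mediator effect decomposition
  {exp[β(μ−μ₀)]−1}×100%, and importance cutoffs (1−0.75^(1/k))×100%.
* **Vulnerability** (`lakebnm.vulnerability`) — median absolute driver
  change per lake, shoreline development index SDI = 0.5·SL/√(π·Alake), and
  Pearson correlations with lake characteristics (two-sided t-test).

## Worked example

```python
from lakebnm import (ModelConfig, apply_missingness, build_priors,
                     forward_simulate, gelman_rubin, generate_scenario,
                     run_driver_assessment, run_mcmc, summarize_assessment)

scenario = generate_scenario(n_lakes=4, n_years=45, seed=11)
panels = apply_missingness(forward_simulate(scenario, seed=12),
                           {"CHL": 0.3, "WT": 0.2}, seed=13)
stocking = scenario.stocking_flags()
priors = build_priors(panels, stocking)
config = ModelConfig(chains=3, burn_in=500, retained=1500, seed=5)
posterior = run_mcmc(panels, priors, config, stocking=stocking)
print("max split R-hat:", round(gelman_rubin(posterior)["rhat"].max(), 4))

assessment = run_driver_assessment(panels["L1"], "AT", posterior,
                                   stocking_eligible=stocking["L1"],
                                   n_accepted=2000, seed=7)
s = summarize_assessment(assessment)
print("association:", s["association"])
print("median AT change (deg C):", round(s["delta_driver"]["median"], 2))
for m in ("WT", "WL", "CHL"):
    info = s["mediators"][m]
    print(f"{m}: median catch effect {info['effect_median_pct']:.1f}% "
          f"important={info['important']}")
```

prints

```
max split R-hat: 1.0014
association: negative
median AT change (deg C): 1.17
WT: median catch effect -23.3% important=True
WL: median catch effect 1.5% important=False
CHL: median catch effect -3.6% important=False
```

The chains agree (R-hat well under the 1.005 bar). For lake L1 a 25% catch
decrease is associated with *warmer* air temperature (a "negative"
association in the reporting convention: catch falls as the driver rises),
typically +1.17 °C; the decomposition attributes essentially the whole
decrease to the water-temperature pathway (−23.3%, beyond the 9.1%
three-mediator cutoff), with water level and chlorophyll contributing little.

A YAML-configured command line wraps the same stages end to end and writes
CSV outputs, line-delimited JSON logs and a hash manifest:

```bash
lakebnm run-all --config demo.yaml --outdir out/
```

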