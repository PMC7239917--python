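# Methods

## Model

`lakebnm` treats each lake as a small causal network observed annually.
Four response variables get conditional Gaussian distributions whose means
are linear in their parents:

* water temperature: `WT ~ N(β₀ + β₁·AT, σ_WT)`;
* water-level change: `ΔWL ~ N(β₀ + β₁·PRE + β₂·PE + β₃·PE·LUag, σ_ΔWL)` —
  the PE and PE×LUag terms come from writing the annual water balance as
  precipitation minus evapotranspiration over agricultural and undeveloped
  area and absorbing the empirical constants into the β's (the undeveloped
  share is collinear with LUag when their sum is nearly constant, so only
  LUag appears);
* log chlorophyll-a: `log CHL ~ N(β₀ + β₁·log PRE + β₂·log LUag + β₃·μ_ΔWL +
  β₄·μ_WT, σ_CHL)`, a log–log nutrient/productivity relationship with
  water-balance and temperature modifiers;
* log catch: `log CATCH ~ N(β₀ + β₁·μ_WT + β₂·μ_ΔWL + β₃·μ_CHL + β₄·log ST +
  β₅·log EFF, σ_CATCH)`, from catch = catchability × effort × biomass with
  log-linear biomass drivers. The stocking term β₄ is estimated only for
  lakes where stocked species contributed >20% of the catch in >10 years.

Two assumptions matter. First, years are independent: each year's mean
depends only on that year's inputs. An AR(1) option for the synthetic
drivers exists but defaults off, matching this assumption. Second, the
downstream means consume the upstream *predicted* means μ (not the noisy
observations), so the system is a network rather than a chain of separate
regressions: catch data inform β^WT and vice versa, and a year missing one
response still contributes its other responses. ΔWL is constructed as the
first difference of observed water level over consecutive years; gaps are
not filled, and the first year is always undefined.

## Priors and estimation

Each submodel is first fitted per lake by ordinary least squares on the
years where its response and all predictors are observed (the CHL and CATCH
designs use *observed* upstream values here, since predicted means do not
exist before estimation; this affects only the prior). The prior for a
lake's coefficient block is MVN centered at the OLS estimate with
covariance g·(XᵀX)⁻¹ — the unscaled least-squares covariance, no
residual-variance multiplier — where one scale g per submodel is shared by
all lakes and carries an inverse-gamma(0.001, 0.001) hyperprior. The shared
g is the pooling channel: (XᵀX) grows with a lake's record length, so
data-rich lakes get tighter priors in relative terms. Noise SDs are
per-lake, with inverse-gamma(0.001, 0.001) priors on σ². Requiring at
least 9 observed years per variable per lake (enforced by
`validate_panel`) keeps every OLS anchor estimable.

Sampling is by block Gibbs: given the other blocks, every coefficient
block enters all four likelihood terms linearly, so its full conditional is
Gaussian and is drawn exactly (canonical form, Cholesky solve); σ² and g
have conjugate inverse-gamma full conditionals. Chains start at the prior
means plus a draw from 0.1² × the prior covariance — a *correlated*
perturbation that moves the coefficients without displacing the fitted
values much — and each σ starts at the lake's least-squares residual SD.
Both choices matter: the joint posterior has a secondary, weak-likelihood
mode in which a submodel's σ inflates and its coefficients decouple from
the data (the plug-in-μ products make such ridges possible), and a chain
started on a broken regression line or with an inflated σ can fall into it
and never leave. Anchored starts keep all random-start chains in the
data-supported basin. Defaults are 3 chains ×
(2,000 burn-in + 5,000 retained), a scaled-down configuration whose maximum
split Gelman–Rubin statistic on the bundled synthetic studies stays under
the 1.005 convergence bar; `ModelConfig.full_scale()` switches to 20,000 +
50,000 for production runs. The split-R̂ diagnostic floors at 1.0, reports
lag-1 autocorrelation, and flags zero-within-variance parameters as
undefined rather than converged. Thinning defaults to 1.

Effects between the 13 variable pairs are classified per lake from
one-tailed 75% credible intervals of the associated coefficient: positive
if the 0.25 posterior quantile exceeds 0, negative if the 0.75 quantile is
below 0, mixed otherwise (equivalently, 0 inside the central 50% interval).
Two pairs are composites through PE: the AT→WL effect is
(β₂ + β₃·LUag_med)·(dPE/dAT) and the LUag→WL effect is β₃·PE_med.

## Scenario sampling: the 25% catch decrease

For each lake × driver (AT, PRE, LUag) the Monte-Carlo sampler repeatedly
(1) draws a coefficient set from the pooled posterior draws and computes
baseline predictions μ₀ at the lake's median inputs, (2) draws the assessed
driver from a normal fitted to its observed series (other drivers held at
medians; out-of-domain PRE/LUag proposals are resampled), and (3) accepts
the sample iff the predicted catch ratio exp(μ^CATCH − μ₀^CATCH) lies in
the closed window [0.74, 0.76], until 10,000 accepted samples are collected
(closed endpoints chosen since the window is stated without strictness).
For the AT assessment, PE co-moves with the sampled AT through a per-lake
OLS line anchored so the median AT maps to the median PE — a stand-in for
recomputing evaporation under a uniform monthly temperature shift, which
would need monthly data. Driver changes are reported in IPCC-style metrics:
actual differences for AT, WT, WL and LUag (percentage points of catchment
area), percent differences for PRE and CHL.

Mediator effects on catch are {exp[β·(μ − μ₀)] − 1} × 100%. Because the
catch mean is additive in the mediator means and ST/EFF sit at their
medians, the factors (1 + effect/100) multiply exactly to the catch ratio —
an identity the tests verify to 1e-10. A mediator is flagged important when
the 0.75 quantile of its effect distribution is at or below
−(1 − 0.75^(1/k))×100%, the equal-share cutoff for k active mediators
(9.1% for the three AT mediators; 13.4% for the two PRE/LUag mediators,
since no WT pathway is hypothesized for those drivers). Whether the
importance rule should read the 0.25 or 0.75 quantile of the effect
distribution is genuinely open; the 0.75 quantile is the conservative
mirror of the direction rule and is the default here. Sampler guards: the
run aborts with guidance if the acceptance rate stays below 1e-5 after a
substantial number of proposals, and warns when accepted driver values fall
outside the observed range (extrapolation).

Vulnerability is the median absolute driver change over accepted samples —
smaller means more vulnerable. It is correlated, within driver only (the
metrics mix units), against access to clean water, shoreline population
density, average depth and the shoreline development index
SDI = 0.5·SL/√(π·Alake), using Pearson r with a two-sided t-test
(t = r√(n−2)/√(1−r²)); two-sided matches the convention of reporting
p ≈ 0.03 for r = −0.39 at n = 31. No multiple-testing correction is applied
across the 12 characteristic × driver tests.

## Synthetic-data generator

The generator emulates a 31-lake × 45-year monitoring panel (1970–2014
analog): per-lake coefficient heterogeneity with mixed link directions
(AT→WT positive everywhere by default, as that link is physically
one-signed); drivers independent across years (AT normal, PRE log-normal,
LUag normal clipped to (0, 100), PE a linear function of AT with positive
slope); ST and EFF log-normal; WL integrated from realized ΔWL draws over a
lake-specific initial level; noise σ set per submodel to 10% ("moderate")
or 30% ("high") of the deterministic signal spread. Stocking eligibility is
drawn at rate 8/31. Missingness blanks a per-variable fraction of years at
random, never below 9 observed years. Lake characteristics include a
plantable Pearson correlation between access to clean water and the lakes'
inverse AT→catch sensitivity, for power checks of the vulnerability stage;
shoreline length and area are drawn so SDI spans roughly 1–8.

Coefficient magnitudes are drawn uniformly within per-link ranges bounded
away from zero, and a candidate lake is redrawn until every driver's
pathway strength — |d log CATCH/d driver| × driver SD, through all mediated
paths — is at least 0.12. This encodes the study conditions the analysis
targets: lakes where a 25% catch decrease (|Δlog| ≈ 0.29) lies within
roughly 2–3 SD of each driver's interannual variability, so conditional
scenario sampling is meaningful for every lake × driver. Scaled-down test
studies use 4–6 lakes; the acceptance script uses 6 lakes × 45 years.

What the generator does not emulate: serial correlation and trends in
drivers or responses, observation error distinct from process noise,
non-Gaussian tails, structurally missing variables (e.g., a lake with no
stocking records at all), and real lakes' magnitudes. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Calibration behavior and limitations

Because each lake's prior is centered on the least-squares estimate from
the *same* panel the likelihood uses, the posterior concentrates around
that estimate more tightly than the estimate's own sampling error, and the
learned scale g equilibrates near the cross-submodel discrepancy scale
rather than the residual variance. The test suite quantifies this: with a
fixed, data-independent prior the sampler's 50% intervals cover
prior-drawn truths at the nominal rate (≈0.54 over 640 draws in the
calibration check used during development), but under the full
empirical-prior procedure the 50% intervals cover the generating
coefficients only ≈0.22 of the time across 20 replicate studies (the
recovery test reports the exact figure on its conditions). Point estimates
are unaffected — posterior medians correlate with the generating
coefficients at r ≈ 0.99 — so directional effect classification is
reliable, but the credible intervals understate uncertainty and the
mixed/positive/negative splits should be read with that in mind. Other
limitations: no model comparison or alternative links; no imputation
(years with a missing response simply drop out of that submodel); the
PE–AT line is a coarse stand-in for an energy-balance recomputation; and
the Monte-Carlo assessment inherits any extrapolation in the fitted driver
normals (it warns, but does not truncate beyond the PRE/LUag domains).

## Degenerate inputs and numerical notes

Rank-deficient OLS designs raise with the collinear columns named (SVD
null-space attribution); fits require at least p + 1 usable years.
Cholesky factorizations add a trace-scaled jitter only on failure. Medians
use the even-count mean-of-central-pair convention. `delta_wl` of a
constant series is 0 (not missing) wherever defined. Empty draw vectors,
nonpositive SDI inputs, zero-variance correlation inputs and fractions
outside [0, 1] raise immediately rather than propagating NaNs. All
randomness flows from explicit integer seeds through `numpy` generators;
identical seeds reproduce panels, chains, accepted samples and the CLI's
output hashes bit for bit.
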