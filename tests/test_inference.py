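"""Model evaluation, Gibbs sampler, diagnostics and effect classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lakebnm import synth
from lakebnm.core import LakePanel, ModelConfig, VARIABLES
from lakebnm.inference import (
    CoefficientSet, PosteriorDraws, classify_coefficient, effects_table,
    gelman_rubin, lag_autocorr, log_joint, pair_effect_draws, predicted_means,
    run_mcmc, split_rhat, stocking_eligible,
)
from lakebnm.priors import build_priors, least_squares_fit, submodel_terms


class TestPredictedMeans:
    BETA = {
        "WT": [2.0, 0.6],
        "dWL": [0.1, 2.0, -1.5, -0.01],
        "CHL": [0.0, 0.0, 0.0, 0.0, 0.0],
        "CATCH": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    }
    INPUTS = {"AT": 10.0, "PRE": 1.2, "PE": 0.8, "LUag": 30.0,
              "ST": 100.0, "EFF": 1.0}

    def test_wt_mean_arithmetic(self):
        mu = predicted_means(self.BETA, self.INPUTS)
        assert mu["WT"] == pytest.approx(8.0)

    def test_dwl_mean_arithmetic(self):
        mu = predicted_means(self.BETA, self.INPUTS)
        assert mu["dWL"] == pytest.approx(0.1 + 2.4 - 1.2 - 0.24)

    def test_all_zero_coefficients_give_zero_means(self):
        beta = {sm: np.zeros(len(v)) for sm, v in self.BETA.items()}
        mu = predicted_means(beta, self.INPUTS)
        assert all(v == 0 for v in mu.values())

    def test_log_of_nonpositive_input_raises(self):
        bad = dict(self.INPUTS, PRE=-0.1)
        with pytest.raises(ValueError, match="PRE"):
            predicted_means(self.BETA, bad)

    def test_stocking_term_only_for_eligible_lakes(self):
        beta = {k: list(v) for k, v in self.BETA.items()}
        beta["CATCH"] = [0.0, 0, 0, 0, 0.5, 0.0]
        mu_elig = predicted_means(beta, self.INPUTS, stocking_eligible=True)
        beta5 = dict(beta, CATCH=[0.0, 0, 0, 0, 0.0])
        mu_not = predicted_means(beta5, self.INPUTS, stocking_eligible=False)
        assert mu_elig["CATCH"] == pytest.approx(0.5 * np.log(100.0))
        assert mu_not["CATCH"] == pytest.approx(0.0)


def _coeff_sets_at_prior_means(prior_spec, stocking, sigma=0.5):
    out = {}
    lakes = prior_spec.submodels["WT"].means.keys()
    for lid in lakes:
        beta = {sm: prior_spec.submodels[sm].means[lid].copy()
                for sm in prior_spec.submodels}
        out[lid] = CoefficientSet(
            lid, beta, {sm: sigma for sm in prior_spec.submodels},
            stocking.get(lid, False))
    return out


class TestLogJoint:
    def test_duplicating_a_lake_doubles_the_likelihood(self, panels,
                                                       prior_spec, stocking):
        lid = sorted(panels)[0]
        coeffs = _coeff_sets_at_prior_means(prior_spec, stocking)
        one = log_joint({lid: coeffs[lid]}, None, {lid: panels[lid]})
        # a second lake with identical data and coefficients
        df = panels[lid].df.drop(columns="dWL").reset_index()
        twin = LakePanel("twin", df)
        cs = coeffs[lid]
        coeffs2 = {lid: cs, "twin": CoefficientSet(
            "twin", cs.beta, cs.sigma, cs.stocking_eligible)}
        two = log_joint(coeffs2, None, {lid: panels[lid], "twin": twin})
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nonpositive_sigma_is_minus_infinity(self, panels, prior_spec,
                                                 stocking):
        coeffs = _coeff_sets_at_prior_means(prior_spec, stocking)
        lid = sorted(panels)[0]
        coeffs[lid].sigma["WT"] = 0.0
        assert log_joint(coeffs, None, panels) == -np.inf

    def test_flat_prior_argmax_is_least_squares(self, toy_panel):
        """With flat priors and one submodel the optimum is the OLS solution."""
        from scipy.optimize import minimize
        ls = least_squares_fit(toy_panel, "WT")

        def neg(beta):
            cs = CoefficientSet("toy", {"WT": np.asarray(beta)}, {"WT": 1.0})
            return -log_joint({"toy": cs}, None, {"toy": toy_panel},
                              submodels=("WT",))

        res = minimize(neg, x0=ls.beta + 1.0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(res.x, ls.beta, atol=1e-5)

    def test_year_with_only_missing_chl_contributes_nothing_to_chl_term(
            self, toy_panel, prior_spec):
        # blank CHL in one year: the CHL likelihood must ignore that year,
        # so blanking the *other* variables there too changes nothing further
        df = toy_panel.df.drop(columns="dWL").reset_index()
        df.loc[4, "CHL"] = np.nan
        panel_a = LakePanel("toy", df)
        cs = CoefficientSet("toy", {
            "WT": np.array([2.0, 0.5]),
            "dWL": np.array([0.0, 0.5, -0.5, 0.0]),
            "CHL": np.array([1.0, 0.2, 0.3, 0.1, 0.05]),
            "CATCH": np.array([1.0, 0.1, 0.2, 0.3, 0.1, 0.5]),
        }, {sm: 0.7 for sm in ("WT", "dWL", "CHL", "CATCH")})
        lj_chl_only_a = log_joint({"toy": cs}, None, {"toy": panel_a},
                                  submodels=("WT", "dWL", "CHL"))
        lj_wt_dwl = log_joint({"toy": cs}, None, {"toy": panel_a},
                              submodels=("WT", "dWL"))
        # recompute CHL portion from a panel without year 4 at all
        df_b = df.drop(index=4)
        panel_b = LakePanel("toy", df_b)
        lj_chl_only_b = log_joint({"toy": cs}, None, {"toy": panel_b},
                                  submodels=("WT", "dWL", "CHL"))
        lj_wt_dwl_b = log_joint({"toy": cs}, None, {"toy": panel_b},
                                submodels=("WT", "dWL"))
        assert (lj_chl_only_a - lj_wt_dwl) == pytest.approx(
            lj_chl_only_b - lj_wt_dwl_b, rel=1e-12)


class TestRunMCMC:
    def test_same_seed_identical_draws(self, panels, prior_spec, stocking):
        cfg = ModelConfig(chains=2, burn_in=50, retained=100, seed=9)
        a = run_mcmc(panels, prior_spec, cfg, stocking=stocking)
        b = run_mcmc(panels, prior_spec, cfg, stocking=stocking)
        lid = a.lake_ids[0]
        for sm in ("WT", "CATCH"):
            np.testing.assert_array_equal(a.beta[sm][lid], b.beta[sm][lid])
        np.testing.assert_array_equal(a.g["CHL"], b.g["CHL"])

    def test_conjugate_closed_form_single_lake_wt_only(self, toy_panel):
        """σ and g fixed: the β^WT posterior is exactly Gaussian."""
        sigma, g = 0.8, 0.05
        spec = build_priors({"toy": toy_panel})
        cfg = ModelConfig(chains=2, burn_in=200, retained=4000, seed=17,
                          submodels=("WT",),
                          fixed_sigma={"WT": sigma}, fixed_g={"WT": g})
        post = run_mcmc({"toy": toy_panel}, spec, cfg)
        ls = least_squares_fit(toy_panel, "WT")
        y, X = toy_panel.df["WT"].to_numpy(), np.column_stack(
            [np.ones(toy_panel.n_years), toy_panel.df["AT"].to_numpy()])
        prior_prec = np.linalg.inv(g * ls.cov_unscaled)
        P = X.T @ X / sigma**2 + prior_prec
        mean = np.linalg.solve(P, X.T @ y / sigma**2 + prior_prec @ ls.beta)
        cov = np.linalg.inv(P)
        draws = post.beta["WT"]["toy"].reshape(-1, 2)
        mc_se = draws.std(axis=0) / np.sqrt(len(draws))  # draws are iid here
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * mc_se)
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.15)

    def test_flat_prior_limit_recovers_least_squares(self, toy_panel):
        spec = build_priors({"toy": toy_panel})
        cfg = ModelConfig(chains=2, burn_in=200, retained=2000, seed=19,
                          submodels=("WT",), fixed_g={"WT": 1e8})
        post = run_mcmc({"toy": toy_panel}, spec, cfg)
        ls = least_squares_fit(toy_panel, "WT")
        draws = post.beta["WT"]["toy"].reshape(-1, 2)
        sd = draws.std(axis=0)
        assert np.all(np.abs(draws.mean(axis=0) - ls.beta) < 2 * sd)

    def test_posterior_contraction_with_more_years(self):
        """Doubling the record length shrinks the average posterior SD."""
        sds = []
        for n_years in (16, 64):
            sc = synth.generate_scenario(n_lakes=2, n_years=n_years, seed=23)
            panels = synth.forward_simulate(sc, seed=24)
            spec = build_priors(panels, sc.stocking_flags())
            cfg = ModelConfig(chains=2, burn_in=200, retained=600, seed=25)
            post = run_mcmc(panels, spec, cfg, stocking=sc.stocking_flags())
            all_sd = [arr.reshape(-1, arr.shape[-1]).std(axis=0).mean()
                      for sm in post.beta for arr in post.beta[sm].values()]
            sds.append(np.mean(all_sd))
        assert sds[1] < sds[0]


def test_posterior_save_load_round_trip(tmp_path, posterior):
    posterior.save(tmp_path / "post")
    back = PosteriorDraws.load(tmp_path / "post")
    assert back.lake_ids == posterior.lake_ids
    assert back.terms == posterior.terms
    lid = posterior.lake_ids[0]
    for sm in posterior.beta:
        np.testing.assert_array_equal(back.beta[sm][lid],
                                      posterior.beta[sm][lid])
        np.testing.assert_array_equal(back.sigma[sm][lid],
                                      posterior.sigma[sm][lid])
    assert (tmp_path / "post" / "registry.json").exists()


class TestGelmanRubin:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        draws = {"x": rng.normal(0, 1, size=(3, 4000))}
        table = gelman_rubin(draws)
        assert 1.0 <= table.loc[0, "rhat"] <= 1.01

    def test_separated_chains_far_above_one(self):
        rng = np.random.default_rng(2)
        arr = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert split_rhat(arr) > 1.1 * 3

    def test_constant_chains_flagged_undefined(self):
        table = gelman_rubin({"c": np.ones((2, 100))})
        assert table.loc[0, "undefined"]
        assert np.isnan(table.loc[0, "rhat"])

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 1, size=(3, 800)) + np.linspace(0, 0.3, 800)
        ours = split_rhat(arr)
        theirs = float(az.rhat(arr[None].transpose(1, 2, 0)[..., 0],
                               method="split"))
        assert ours == pytest.approx(max(1.0, theirs), rel=1e-6)

    def test_autocorrelation_of_iid_draws_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(lag_autocorr(rng.normal(size=(2, 5000)))) < 0.05

    def test_requires_enough_chains_and_draws(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin({"x": np.ones((1, 100))})
        with pytest.raises(ValueError, match="iterations"):
            gelman_rubin({"x": np.ones((2, 5))})


class TestClassifyCoefficient:
    def test_all_positive_draws(self):
        assert classify_coefficient(np.ones(100)) == "positive"

    def test_zero_inside_central_fifty_percent_interval(self):
        draws = np.concatenate([np.full(500, -0.1), np.full(500, 0.2)])
        assert classify_coefficient(draws) == "mixed"

    def test_narrow_negative_normal(self):
        rng = np.random.default_rng(5)
        assert classify_coefficient(rng.normal(-1, 0.1, 10_000)) == "negative"

    def test_empty_draws_raise(self):
        with pytest.raises(ValueError):
            classify_coefficient(np.array([]))

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.normal(rng.normal(), rng.uniform(0.1, 2), 400)
        a, b = classify_coefficient(draws), classify_coefficient(-draws)
        flipped = {"positive": "negative", "negative": "positive",
                   "mixed": "mixed"}
        assert b == flipped[a]


class TestEffectsTable:
    def _medians_slopes(self, panels):
        from lakebnm.core import compute_medians
        from lakebnm.assessment import fit_pe_at_map
        med = {lid: compute_medians(p) for lid, p in panels.items()}
        slopes = {lid: fit_pe_at_map(p)[1] for lid, p in panels.items()}
        return med, slopes

    def test_planted_positive_at_wt_link_recovered_in_all_lakes(
            self, posterior, panels, stocking):
        med, slopes = self._medians_slopes(panels)
        table = effects_table(posterior, med, slopes, stocking)
        at_wt = table[(table.predictor == "AT") & (table.response == "WT")]
        assert at_wt[["positive", "negative", "mixed"]].values.tolist() == [
            [len(panels), 0, 0]]

    def test_row_sums_equal_lake_counts(self, posterior, panels, stocking):
        med, slopes = self._medians_slopes(panels)
        table = effects_table(posterior, med, slopes, stocking)
        n_eligible = sum(stocking.values())
        for _, row in table.iterrows():
            total = row.positive + row.negative + row.mixed
            expected = n_eligible if row.predictor == "ST" else len(panels)
            assert total == expected

    def test_symmetric_draws_classify_as_mixed(self):
        # a hand-built posterior with all coefficients centered at zero
        rng = np.random.default_rng(6)
        terms = {sm: {"L": submodel_terms(sm, False)}
                 for sm in ("WT", "dWL", "CHL", "CATCH")}
        beta = {sm: {"L": rng.normal(0, 1, (2, 400, len(terms[sm]["L"])))}
                for sm in terms}
        sigma = {sm: {"L": np.ones((2, 400))} for sm in terms}
        g = {sm: np.ones((2, 400)) for sm in terms}
        post = PosteriorDraws(beta, sigma, g, terms, ("L",),
                              ModelConfig(), 0)
        med = {"LUag": 30.0, "PE": 0.9}
        draws = pair_effect_draws(post, "L", ("AT", "WL"), med, 0.04)
        assert classify_coefficient(draws) == "mixed"
        table = effects_table(post, {"L": med}, {"L": 0.04}, {"L": False})
        st_row = table[table.predictor == "ST"]
        assert int(st_row[["positive", "negative", "mixed"]].sum(axis=1).iloc[0]) == 0


class TestStockingEligible:
    @pytest.mark.parametrize("years, frac, expected", [
        (11, 0.25, True),    # >20% in >10 years
        (10, 0.25, False),   # exactly 10 years is not enough
        (20, 0.15, False),   # never above the 20% threshold
        (11, 0.20, False),   # exactly 20% is not above it
    ])
    def test_threshold_rules(self, years, frac, expected):
        series = [frac] * years + [0.0] * (45 - years)
        assert stocking_eligible(series) is expected

    def test_fractions_outside_unit_interval_raise(self):
        with pytest.raises(ValueError):
            stocking_eligible([0.5, 1.2])
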