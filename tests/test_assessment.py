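"""Monte-Carlo scenario sampler: window, metrics, decomposition, importance."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from lakebnm.assessment import (
    accept_sample, change_metric, classify_association, flag_importance,
    fit_pe_at_map, importance_cutoff, mediator_catch_effect, propose_driver,
    run_driver_assessment,
)
from lakebnm.core import compute_medians


class TestImportanceCutoff:
    @pytest.mark.parametrize("k, printed", [(3, "9.1"), (2, "13.4"), (1, "25.0")])
    def test_printed_values(self, k, printed):
        assert f"{importance_cutoff(k):.1f}" == printed

    @given(st.integers(1, 10))
    def test_equal_share_identity(self, k):
        # k equal multiplicative shares of the 25% decrease reconstruct it
        c = importance_cutoff(k)
        assert (1 - c / 100) ** k == pytest.approx(0.75, rel=1e-12)

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_k_rejected(self, bad):
        with pytest.raises(ValueError):
            importance_cutoff(bad)


class TestAcceptSample:
    def test_target_ratio_accepted(self):
        assert accept_sample(math.log(0.75), 0.0)

    def test_window_is_closed_at_both_ends(self):
        assert accept_sample(math.log(0.76), 0.0)
        assert accept_sample(math.log(0.74), 0.0)

    def test_just_outside_rejected(self):
        assert not accept_sample(math.log(0.739), 0.0)
        assert not accept_sample(math.log(0.761), 0.0)

    def test_vectorized(self):
        mu = np.log([0.75, 0.70, 0.76])
        np.testing.assert_array_equal(accept_sample(mu, 0.0),
                                      [True, False, True])


class TestChangeMetric:
    def test_air_temperature_actual_difference(self):
        assert change_metric("AT", 15.2, 14.1) == pytest.approx(1.1)

    def test_chl_percent_from_log_difference(self):
        # exp(0.0953) = 1.1000 → +10.0%
        assert change_metric("CHL", 0.0953, 0.0) == pytest.approx(10.0, abs=0.01)

    def test_luag_percentage_points(self):
        assert change_metric("LUag", 42.0, 38.0) == pytest.approx(4.0)

    def test_pre_percent_difference(self):
        assert change_metric("PRE", 1.25, 1.0) == pytest.approx(25.0)

    def test_zero_median_pre_rejected(self):
        with pytest.raises(ValueError):
            change_metric("PRE", 1.0, 0.0)


class TestMediatorCatchEffect:
    def test_zero_coefficient(self):
        assert mediator_catch_effect(0.0, 5.0, 1.0) == 0.0

    def test_no_mediator_change(self):
        assert mediator_catch_effect(-0.3, 2.0, 2.0) == 0.0

    def test_direct_evaluation(self):
        # exp(-0.1 * 2) - 1 = -18.13%
        assert mediator_catch_effect(-0.1, 3.0, 1.0) == pytest.approx(
            -18.1269, abs=1e-3)


def _point_mass_beta(b_wt1=0.8, b_c1=-0.25, n=1):
    """Degenerate posterior: AT→WT→CATCH is the only nonzero pathway."""
    return {
        "WT": np.tile([10.0, b_wt1], (n, 1)),
        "dWL": np.tile([0.0, 0.0, 0.0, 0.0], (n, 1)),
        "CHL": np.tile([2.0, 0.0, 0.0, 0.0, 0.0], (n, 1)),
        "CATCH": np.tile([3.0, b_c1, 0.0, 0.0, 0.5], (n, 1)),
    }


class TestRunDriverAssessment:
    def test_every_accepted_ratio_inside_window(self, posterior, panels,
                                                stocking):
        lid = posterior.lake_ids[0]
        a = run_driver_assessment(panels[lid], "AT", posterior,
                                  stocking_eligible=stocking[lid],
                                  n_accepted=400, seed=3)
        assert a.n_accepted == 400
        assert a.samples["ratio"].min() >= 0.74
        assert a.samples["ratio"].max() <= 0.76

    def test_fixed_seed_reproducible(self, posterior, panels, stocking):
        lid = posterior.lake_ids[1]
        kw = dict(stocking_eligible=stocking[lid], n_accepted=10, seed=8)
        a = run_driver_assessment(panels[lid], "PRE", posterior, **kw)
        b = run_driver_assessment(panels[lid], "PRE", posterior, **kw)
        assert a.samples.equals(b.samples)
        assert a.n_proposed == b.n_proposed

    @pytest.mark.parametrize("driver", ["AT", "PRE", "LUag"])
    def test_mediator_effects_multiply_to_the_catch_ratio(
            self, posterior, panels, stocking, driver):
        """The per-mediator percent effects decompose the ratio exactly."""
        lid = posterior.lake_ids[2]
        a = run_driver_assessment(panels[lid], driver, posterior,
                                  stocking_eligible=stocking[lid],
                                  n_accepted=300, seed=4)
        s = a.samples
        product = ((1 + s["e_WT"] / 100) * (1 + s["e_WL"] / 100)
                   * (1 + s["e_CHL"] / 100))
        np.testing.assert_allclose(product, s["ratio"], rtol=1e-10)
        if driver != "AT":  # no hypothesized WT pathway for PRE / LUag
            np.testing.assert_allclose(s["e_WT"], 0.0, atol=1e-12)
            np.testing.assert_allclose(s["d_WT"], 0.0, atol=1e-12)

    def test_degenerate_posterior_concentrates_at_analytic_root(self, toy_panel):
        beta = _point_mass_beta()
        c = 0.8 * (-0.25)  # d log CATCH / d AT
        medians = compute_medians(toy_panel)
        a = run_driver_assessment(toy_panel, "AT", beta, lake_id="toy",
                                  stocking_eligible=False, n_accepted=200,
                                  seed=5)
        root = math.log(0.75) / c
        lo, hi = sorted([math.log(0.74) / c, math.log(0.76) / c])
        d_at = a.samples["delta_driver"].to_numpy()
        assert np.all((d_at >= lo - 1e-9) & (d_at <= hi + 1e-9))
        assert abs(np.median(d_at) - root) < (hi - lo)
        # and the driver value is the median plus that change
        np.testing.assert_allclose(a.samples["driver_value"],
                                   medians["AT"] + d_at, rtol=1e-12)

    def test_unreachable_target_aborts_with_guidance(self, toy_panel):
        beta = _point_mass_beta(b_c1=0.0)  # no pathway at all: ratio ≡ 1
        with pytest.raises(RuntimeError, match="acceptance rate"):
            run_driver_assessment(toy_panel, "AT", beta, lake_id="toy",
                                  n_accepted=10, seed=6)

    def test_extrapolating_scenarios_warn(self, toy_panel):
        # the only solution sits ~4 driver SDs out: reachable, but beyond
        # the observed range, which must be reported
        at_sd = toy_panel.df["AT"].std(ddof=1)
        c = math.log(0.75) / (4 * at_sd)
        beta = _point_mass_beta(b_wt1=1.0, b_c1=c)
        with pytest.warns(RuntimeWarning, match="outside the observed"):
            run_driver_assessment(toy_panel, "AT", beta, lake_id="toy",
                                  stocking_eligible=False, n_accepted=40,
                                  seed=12)

    def test_unknown_driver_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="driver"):
            run_driver_assessment(toy_panel, "WT", _point_mass_beta(),
                                  n_accepted=1, seed=0)


class TestProposeDriver:
    def test_domain_truncation_by_resampling(self):
        rng = np.random.default_rng(0)
        lu = propose_driver("LUag", 5.0, 20.0, rng, 5000)
        assert np.all((lu > 0) & (lu < 100))
        pre = propose_driver("PRE", 0.2, 0.5, rng, 5000)
        assert np.all(pre > 0)

    def test_pe_at_map_passes_near_observed_cloud(self, toy_panel):
        a, b = fit_pe_at_map(toy_panel)
        df = toy_panel.df
        pred = a + b * df["AT"]
        assert (pred - df["PE"]).abs().mean() < df["PE"].std() * 2


class TestClassifyAssociation:
    def test_all_negative_changes_mean_positive_association(self):
        assert classify_association(np.array([-1.0, -2.0, -0.5])) == "positive"

    def test_all_positive_changes_mean_negative_association(self):
        assert classify_association(np.array([1.0, 2.0, 0.5])) == "negative"

    def test_quartiles_straddling_zero_mixed(self):
        assert classify_association(np.array([-1.0, -0.5, 0.5, 1.0])) == "mixed"

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(rng.normal(), 1.0, 200)
        flipped = {"positive": "negative", "negative": "positive",
                   "mixed": "mixed"}
        assert classify_association(-d) == flipped[classify_association(d)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_association(np.array([]))


class TestFlagImportance:
    def test_large_decrease_is_important(self):
        assert flag_importance(np.full(100, -20.0), k=3)

    def test_small_decrease_is_not(self):
        assert not flag_importance(np.full(100, -5.0), k=3)

    def test_boundary_normal_just_misses_the_cutoff(self):
        # Normal(-13.4, 0.01): q75 ≈ -13.3933, cutoff(2) = 13.3975
        grid = np.linspace(0.001, 0.999, 999)
        draws = -13.4 + 0.01 * norm.ppf(grid)
        assert not flag_importance(draws, k=2)

    def test_boundary_normal_below_the_cutoff_is_important(self):
        grid = np.linspace(0.001, 0.999, 999)
        draws = -13.5 + 0.01 * norm.ppf(grid)
        assert flag_importance(draws, k=2)
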