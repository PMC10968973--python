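import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigreach.data_model import add_derived_columns
from sigreach.ipw_survival import (
    WeightedSurvivalCurve,
    bonferroni_adjust,
    bootstrap_inference,
    ddrmst,
    drmst,
    estimate_weights,
    make_drmst_statistic,
    rmst,
    weighted_km,
)
from sigreach.synthetic import (
    GeneratorConfig,
    closed_form_rmst,
    generate,
)

VIS, COL = "VISUALIZABLE", "REQUIRES_COLONOSCOPY"


def _curve(times, survival, n=100, max_t=None, last_event=True):
    times = np.asarray(times, float)
    return WeightedSurvivalCurve(
        times=times,
        survival=np.asarray(survival, float),
        at_risk_w=np.zeros(len(times)),
        events_w=np.zeros(len(times)),
        n_subjects=n,
        max_observed_time=float(max_t if max_t is not None else times[-1]),
        last_observation_event=last_event,
    )


class TestWeights:
    def test_no_confounding_gives_unit_stabilized_weights(self):
        cfg = GeneratorConfig(n_patients=4_000, seed=2, confounding_log_odds={})
        cohort = add_derived_columns(generate(cfg)[0])
        w = estimate_weights(cohort).weights
        assert np.abs(np.mean(w) - 1.0) < 0.05
        # weights deviate from 1 only through sampling noise in the fit
        assert np.abs(w - 1.0).max() < 0.4

    def test_hand_computed_weights_on_six_patient_fixture(self, tiny_cohort):
        """Sex-only propensity on 6 patients: p-hat(vis | sex) is the
        saturated empirical share, so unstabilized weights are 1/p-hat."""
        w = estimate_weights(tiny_cohort, covariates=("sex",), stabilize=False).weights
        vis = (tiny_cohort["reach"] == VIS).to_numpy()
        for sex in ("female", "male"):
            m = (tiny_cohort["sex"] == sex).to_numpy()
            p = vis[m].mean()
            np.testing.assert_allclose(w[m & vis], 1.0 / p)
            np.testing.assert_allclose(w[m & ~vis], 1.0 / (1.0 - p))

    def test_stabilized_weights_mean_one_per_group(self, default_cohort):
        cohort, _ = default_cohort
        w = estimate_weights(cohort).weights
        vis = (cohort["reach"] == VIS).to_numpy()
        assert abs(w[vis].mean() - 1.0) < 0.05
        assert abs(w[~vis].mean() - 1.0) < 0.05

    def test_weighting_balances_confounded_covariates(self):
        """Standardized difference of the confounder drops below 0.05
        after weighting."""
        cfg = GeneratorConfig(
            n_patients=20_000, seed=8,
            confounding_log_odds={("sex", "male"): 0.8},
        )
        cohort = add_derived_columns(generate(cfg)[0])
        vis = (cohort["reach"] == VIS).to_numpy()
        male = (cohort["sex"] == "male").to_numpy(float)

        def std_diff(weights):
            m1 = np.average(male[vis], weights=weights[vis])
            m0 = np.average(male[~vis], weights=weights[~vis])
            s = np.sqrt((m1 * (1 - m1) + m0 * (1 - m0)) / 2)
            return abs(m1 - m0) / s

        unweighted = std_diff(np.ones(len(cohort)))
        weighted = std_diff(estimate_weights(cohort, ("sex",)).weights)
        assert unweighted > 0.15  # confounding is real before weighting
        assert weighted < 0.05


class TestWeightedKM:
    def test_unit_weights_match_lifelines_kaplan_meier(self, default_cohort):
        lifelines = pytest.importorskip("lifelines")
        cohort, _ = default_cohort
        sub = cohort[cohort["stage"] == "regional"].head(500)
        t = sub["survival_months"].to_numpy(float)
        e = (sub["vital_status"] == "dead").to_numpy()
        curve = weighted_km(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        expected = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, expected, rtol=1e-12)

    def test_single_subject_event(self):
        curve = weighted_km([5.0], [True])
        assert curve.times.tolist() == [5.0]
        assert curve.survival.tolist() == [0.0]
        assert curve.evaluate(4.999) == 1.0
        assert curve.evaluate(5.0) == 0.0

    def test_eight_subject_weighted_fixture_matches_longhand_product_limit(self):
        """Longhand oracle: explicit product over event times with weighted
        death and at-risk sums, events before censorings at ties."""
        times = np.array([2.0, 3.0, 3.0, 5.0, 5.0, 7.0, 9.0, 9.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 0], dtype=bool)
        weights = np.array([1.0, 2.0, 1.5, 0.5, 1.0, 2.0, 1.0, 0.5])

        surv_expected = []
        s = 1.0
        for t in sorted(set(times[events])):
            at_risk = weights[times >= t].sum()
            d = weights[events & (times == t)].sum()
            s *= 1.0 - d / at_risk
            surv_expected.append(s)

        curve = weighted_km(times, events, weights)
        np.testing.assert_allclose(curve.survival, surv_expected, rtol=1e-15)

    def test_all_censored_gives_flat_curve_with_note(self):
        curve = weighted_km([3.0, 8.0], [False, False])
        assert curve.no_events
        assert curve.evaluate(100.0) == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            weighted_km([], [])
        with pytest.raises(ValueError):
            weighted_km([1.0], [True], [-1.0])


class TestRmst:
    def test_flat_curve_gives_tau(self):
        curve = weighted_km([200.0], [True])
        est = rmst(curve, 120.0, min_stratum_n=1)
        assert est.value == pytest.approx(120.0)

    def test_single_event_at_5_tau_10(self):
        est = rmst(weighted_km([5.0], [True]), 10.0, min_stratum_n=1)
        assert est.value == pytest.approx(5.0)

    def test_hand_integral_of_step_curve(self):
        # S=1 on [0,3), 0.5 on [3,7), 0.25 on [7,10): area = 3 + 2 + 0.75
        curve = _curve([3.0, 7.0], [0.5, 0.25], max_t=12.0)
        assert rmst(curve, 10.0).value == pytest.approx(5.75)

    def test_nondecreasing_in_tau_and_bounded(self):
        curve = _curve([3.0, 7.0, 15.0], [0.6, 0.35, 0.1], max_t=20.0)
        values = [rmst(curve, tau).value for tau in (5, 10, 15, 20)]
        assert all(np.diff(values) >= 0)
        assert all(v <= tau for v, tau in zip(values, (5, 10, 15, 20)))

    def test_dominating_curve_has_larger_rmst(self):
        lo = _curve([3.0, 7.0], [0.5, 0.2], max_t=12.0)
        hi = _curve([3.0, 7.0], [0.8, 0.6], max_t=12.0)
        assert rmst(hi, 10.0).value >= rmst(lo, 10.0).value

    def test_not_estimable_when_followup_ends_censored_before_tau(self):
        curve = _curve([10.0], [0.6], max_t=30.0, last_event=False)
        est = rmst(curve, 120.0)
        assert not est.estimable and np.isnan(est.value)

    def test_not_estimable_below_min_stratum_size(self):
        est = rmst(weighted_km([5.0, 9.0], [True, True]), 10.0, min_stratum_n=10)
        assert not est.estimable

    def test_extrapolation_flagged_when_last_event_before_tau(self):
        est = rmst(weighted_km(np.arange(1.0, 21.0), np.ones(20, bool)), 120.0)
        assert est.estimable and est.extrapolated


class TestContrasts:
    def test_drmst_zero_for_identical_groups(self):
        c = weighted_km(np.arange(1.0, 31.0), np.ones(30, bool))
        assert drmst(c, c, 24.0).value == pytest.approx(0.0)

    def test_drmst_antisymmetric_under_group_swap(self):
        a = weighted_km(np.arange(1.0, 31.0), np.ones(30, bool))
        b = weighted_km(np.arange(2.0, 62.0, 2.0), np.ones(30, bool))
        assert drmst(a, b, 24.0).value == pytest.approx(-drmst(b, a, 24.0).value)

    def test_drmst_equals_difference_of_hand_integrals(self):
        cv = _curve([4.0], [0.5], max_t=20.0)   # RMST@10 = 4 + 6*0.5 = 7
        cc = _curve([2.0], [0.25], max_t=20.0)  # RMST@10 = 2 + 8*0.25 = 4
        res = drmst(cv, cc, 10.0)
        assert res.value == pytest.approx(3.0)

    def test_drmst_not_estimable_propagates(self):
        good = weighted_km(np.arange(1.0, 31.0), np.ones(30, bool))
        sparse = weighted_km([5.0], [True])  # below the min stratum size
        res = drmst(good, sparse, 24.0)
        assert not res.estimable and np.isnan(res.value)

    def test_ddrmst_zero_when_components_equal(self):
        comps = {(r, s): 50.0 for r in (VIS, COL) for s in ("localized", "distant")}
        assert ddrmst(comps, 120.0).value == pytest.approx(0.0)

    def test_ddrmst_narrative_example(self):
        # gaps: visualizable 80-9=71, colonoscopy 82-0=82 -> DDRMST -11
        comps = {
            (VIS, "localized"): 80.0,
            (VIS, "distant"): 9.0,
            (COL, "localized"): 82.0,
            (COL, "distant"): 0.0,
        }
        assert ddrmst(comps, 120.0).value == pytest.approx(-11.0)

    @given(st.lists(st.floats(0, 120), min_size=4, max_size=4), st.floats(-30, 30))
    @settings(derandomize=True, max_examples=50)
    def test_ddrmst_formula_and_shift_invariance(self, vals, shift):
        keys = [(VIS, "localized"), (VIS, "distant"), (COL, "localized"), (COL, "distant")]
        comps = dict(zip(keys, vals))
        expected = (vals[0] - vals[1]) - (vals[2] - vals[3])
        assert ddrmst(comps, 60.0).value == pytest.approx(expected, abs=1e-9)
        shifted = {k: v + shift for k, v in comps.items()}
        assert ddrmst(shifted, 60.0).value == pytest.approx(expected, abs=1e-9)


def _stratum_cohort(n, seed, sex_effect=0.5):
    cfg = GeneratorConfig(
        n_patients=n,
        seed=seed,
        age_group_mix={"under45": 0.0, "45to49": 0.0, "50plus": 1.0},
        stage_mix_by_reach={
            VIS: {"localized": 0.0, "regional": 1.0, "distant": 0.0},
            COL: {"localized": 0.0, "regional": 1.0, "distant": 0.0},
        },
        confounding_log_odds={("sex", "male"): sex_effect},
    )
    return add_derived_columns(generate(cfg)[0]), cfg


class TestBootstrap:
    def test_same_seed_is_bit_identical(self):
        cohort, _ = _stratum_cohort(400, seed=5)
        stat = make_drmst_statistic(24.0, covariates=("sex",))
        r1 = bootstrap_inference(cohort, stat, n_reps=50, seed=123)
        r2 = bootstrap_inference(cohort, stat, n_reps=50, seed=123)
        assert r1.se == r2.se and r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high

    def test_degenerate_constant_statistic_is_refused(self):
        """All-identical patients within each group: DRMST is constant
        under resampling, so SE = 0 and inference is refused."""
        identical = pd.DataFrame(
            {
                "reach": [VIS] * 20 + [COL] * 20,
                "sex": ["male"] * 40,
                "survival_months": [12] * 40,
                "vital_status": ["dead"] * 40,
            }
        )
        stat = make_drmst_statistic(24.0, covariates=("sex",), min_stratum_n=1)
        assert stat(identical) == pytest.approx(0.0)
        with pytest.raises(RuntimeError, match="refused"):
            bootstrap_inference(identical, stat, n_reps=30, seed=0)

    def test_unestimable_point_returns_not_estimable(self):
        cohort, _ = _stratum_cohort(400, seed=7)
        vis_only = cohort[cohort["reach"] == VIS].reset_index(drop=True)
        stat = make_drmst_statistic(24.0, covariates=("sex",))
        res = bootstrap_inference(vis_only, stat, n_reps=10, seed=0)
        assert not res.estimable

    def test_bootstrap_se_shrinks_like_one_over_sqrt_n(self):
        """log SE vs log n slope is -1/2 within +/-15% for the DRMST
        statistic across n in {250, 1000, 4000}."""
        ns = [250, 1000, 4000]
        ses = []
        stat = make_drmst_statistic(24.0, covariates=("sex",))
        for n in ns:
            cohort, _ = _stratum_cohort(n, seed=100 + n)
            res = bootstrap_inference(cohort, stat, n_reps=200, seed=n)
            ses.append(res.se)
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert -0.5 * 1.15 < slope < -0.5 * 0.85

    def test_rmst_recovery_matches_exponential_closed_form(self):
        """Weighted KM RMST on an exponential cohort lands within 3
        bootstrap SEs of (1 - e^(-lambda tau))/lambda for both groups."""
        cohort, cfg = _stratum_cohort(4_000, seed=31)
        tau = 60.0
        stat = make_drmst_statistic(tau, covariates=("sex",))
        res = bootstrap_inference(cohort, stat, n_reps=200, seed=31)
        truth = cfg.true_drmst("regional", tau)
        assert abs(res.value - truth) < 3 * res.se


class TestBonferroni:
    def test_family_of_27(self):
        flags = bonferroni_adjust([0.001, 0.01], 27)
        assert flags.tolist() == [True, False]  # threshold 0.001852

    def test_m_1_reduces_to_unadjusted(self):
        assert bonferroni_adjust([0.049, 0.051], 1).tolist() == [True, False]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], 27)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], 0)
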