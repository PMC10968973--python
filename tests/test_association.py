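import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigreach.association import (
    ContingencyTable,
    SeparationError,
    crosstab,
    fit_logistic,
    fit_logistic_irls,
    odds_ratio_univariable,
    proportion_by_stratum,
    round_half_up,
)
from sigreach.data_model import add_derived_columns
from sigreach.synthetic import GeneratorConfig, generate

from conftest import brute_force_counts


def _table(levels, reference):
    return ContingencyTable(factor="f", levels=levels, reference=reference)


class TestCrosstab:
    def test_matches_brute_force_counting_on_random_cohort(self, default_cohort):
        cohort, _ = default_cohort
        small = cohort.sample(50, random_state=0)
        table = crosstab(small, "sex", "female")
        assert {k: v for k, v in table.levels.items()} == brute_force_counts(small, "sex")

    def test_single_level_factor_equals_overall_totals(self, default_cohort):
        cohort, _ = default_cohort
        cohort = cohort.assign(const="all")
        table = crosstab(cohort, "const", "all")
        n_vis = int((cohort["reach"] == "VISUALIZABLE").sum())
        assert table.levels == {"all": (n_vis, len(cohort))}

    def test_unseen_reference_level_is_an_error(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError):
            crosstab(cohort, "sex", "nonbinary-not-in-data")


class TestOddsRatio:
    def test_identical_counts_give_unit_odds_ratio(self):
        table = _table({"ref": (30, 70), "lvl": (30, 70)}, "ref")
        est = odds_ratio_univariable(table, "lvl")
        assert est.odds_ratio == pytest.approx(1.0)

    def test_hand_computed_symmetric_2x2(self):
        # a=b=c=d=2: OR=1, SE(log OR)=sqrt(4/2)=sqrt(2)
        table = _table({"ref": (2, 4), "lvl": (2, 4)}, "ref")
        est = odds_ratio_univariable(table, "lvl")
        z = stats.norm.ppf(0.975)
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.se_log_or == pytest.approx(np.sqrt(2.0))
        assert est.ci_low == pytest.approx(np.exp(-z * np.sqrt(2.0)))
        assert est.ci_high == pytest.approx(np.exp(z * np.sqrt(2.0)))

    def test_zero_cell_raises_with_continuity_guidance(self):
        table = _table({"ref": (2, 4), "lvl": (4, 4)}, "ref")
        with pytest.raises(ZeroDivisionError, match="continuity"):
            odds_ratio_univariable(table, "lvl")
        est = odds_ratio_univariable(table, "lvl", continuity_correction=True)
        assert est.odds_ratio > 1

    def test_level_must_differ_from_reference(self):
        table = _table({"ref": (2, 4), "lvl": (2, 4)}, "ref")
        with pytest.raises(ValueError):
            odds_ratio_univariable(table, "ref")

    @given(
        a=st.integers(2, 200),
        b=st.integers(2, 200),
        c=st.integers(2, 200),
        d=st.integers(2, 200),
        k=st.integers(1, 20),
    )
    @settings(derandomize=True, max_examples=50)
    def test_ci_never_widens_when_cells_scale_up(self, a, b, c, d, k):
        """Scaling all cells by k >= 1 keeps the OR and shrinks the Wald CI."""
        t1 = _table({"ref": (c, c + d), "lvl": (a, a + b)}, "ref")
        tk = _table({"ref": (c * k, (c + d) * k), "lvl": (a * k, (a + b) * k)}, "ref")
        e1 = odds_ratio_univariable(t1, "lvl")
        ek = odds_ratio_univariable(tk, "lvl")
        assert ek.odds_ratio == pytest.approx(e1.odds_ratio)
        width1 = np.log(e1.ci_high) - np.log(e1.ci_low)
        widthk = np.log(ek.ci_high) - np.log(ek.ci_low)
        assert widthk <= width1 + 1e-12


class TestLogisticIRLS:
    def test_single_binary_factor_reproduces_closed_form_or(self, default_cohort):
        """Saturated 2x2 model: IRLS coefficient equals the cross-product
        log odds ratio to 1e-6 relative."""
        cohort, _ = default_cohort
        table = crosstab(cohort, "sex", "female")
        closed = odds_ratio_univariable(table, "male")
        fit = fit_logistic(cohort, {"sex": ["female", "male"]})
        assert fit.coef("sex[male]") == pytest.approx(closed.log_or, rel=1e-6)

    def test_agrees_with_statsmodels_glm(self, default_cohort):
        """Multivariable fit cross-checked against an independent GLM
        implementation (coefficients and standard errors)."""
        sm = pytest.importorskip("statsmodels.api")
        cohort, _ = default_cohort
        factors = {
            "age_group": ["50plus", "45to49", "under45"],
            "sex": ["female", "male"],
            "race_ethnicity": ["NH-White", "Hispanic", "NH-AIAN", "NH-API", "NH-Black", "NH-Unknown"],
        }
        fit = fit_logistic(cohort, factors)
        y = (cohort["reach"] == "VISUALIZABLE").astype(float)
        X = [np.ones(len(cohort))]
        for f, levels in factors.items():
            for lvl in levels[1:]:
                X.append((cohort[f].astype(str) == lvl).to_numpy(float))
        res = sm.GLM(y, np.column_stack(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params, res.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(fit.bse, res.bse, rtol=1e-4)

    def test_recovers_known_coefficients_within_3_se(self):
        """Cohort simulated with a known confounding log-OR vector: the
        fitted male and NH-API effects land within 3 SE of truth."""
        beta_male, beta_api = 0.45, 0.40
        cfg = GeneratorConfig(
            n_patients=20_000,
            seed=99,
            confounding_log_odds={("sex", "male"): beta_male, ("race_ethnicity", "NH-API"): beta_api},
        )
        cohort = add_derived_columns(generate(cfg)[0])
        fit = fit_logistic(
            cohort,
            {
                "age_group": ["50plus", "45to49", "under45"],
                "sex": ["female", "male"],
                "race_ethnicity": ["NH-White", "Hispanic", "NH-AIAN", "NH-API", "NH-Black", "NH-Unknown"],
            },
        )
        for term, truth in [("sex[male]", beta_male), ("race_ethnicity[NH-API]", beta_api)]:
            i = fit.terms.index(term)
            assert abs(fit.params[i] - truth) < 3 * fit.bse[i]

    def test_constant_outcome_is_separation_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError):
            fit_logistic_irls(X, np.ones(10))

    def test_perfect_predictor_is_separation_error(self):
        x = np.repeat([0.0, 1.0], 20)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_logistic_irls(X, x.copy())


class TestProportions:
    def test_matches_brute_force_loop_on_small_fixture(self, default_cohort):
        cohort, _ = default_cohort
        small = cohort.sample(20, random_state=1).reset_index(drop=True)
        table = proportion_by_stratum(small)
        for _, row in table.iterrows():
            mask = np.ones(len(small), bool)
            if row["age_group"] != "all":
                mask &= (small["age_group"] == row["age_group"]).to_numpy()
            if row["stage"] != "all":
                mask &= (small["stage"] == row["stage"]).to_numpy()
            sub = small[mask]
            assert row["n_total"] == len(sub)
            assert row["n_visualizable"] == int((sub["reach"] == "VISUALIZABLE").sum())

    def test_all_visualizable_cohort_is_100_percent_everywhere(self, default_cohort):
        cohort, _ = default_cohort
        vis = cohort[cohort["reach"] == "VISUALIZABLE"].reset_index(drop=True)
        table = proportion_by_stratum(vis)
        filled = table.dropna(subset=["percent"])
        assert (filled["percent"] == 100.0).all()

    def test_empty_stratum_percent_is_not_estimable(self, tiny_cohort):
        table = proportion_by_stratum(tiny_cohort)
        empty = table[table["n_total"] == 0]
        assert len(empty) > 0  # tiny fixture has empty age x stage cells
        assert empty["percent"].isna().all()


def test_round_half_up_at_the_boundary():
    assert round_half_up(73.15, 1) == 73.2
    assert round_half_up(56.25, 1) == 56.3
    assert round_half_up(-1.25, 1) == -1.3
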