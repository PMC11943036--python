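"""Outcome model, risk curves, effect report, baseline table, variants."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import pdatrial as pt
from conftest import make_registry
from pdatrial import cohort, estimation, glm, ipw
from pdatrial.clones import EARLY, LATE, StrategyDef, expand_person_days, make_clones
from pdatrial.estimation import (
    CloneCensorWeight,
    OutcomeModel,
    baseline_table,
    fit_outcome_model,
    mean_ventilator_days,
    risk_curves,
)


class TestOutcomeModel:
    def test_saturated_fit_equals_event_proportions(self, confounded_registry):
        est = CloneCensorWeight(time_spec="saturated", weighted=False).fit(
            confounded_registry.head(800)
        )
        pd_ = est.person_days_
        mask = (pd_["artificial_censor"] == 0) & (pd_["at_risk"] == 1)
        rows = pd_[mask]
        for (s, d), grp in rows.groupby(["strategy", "day"]):
            expected = grp["event"].mean()
            got = est.outcome_model_.hazard(s)[d]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_hazard_curve_closed_form(self):
        model = OutcomeModel.constant(0.05)
        curves = risk_curves(model)
        ci = curves[curves["strategy"] == "early"].set_index("day")["cumulative_incidence"]
        assert ci.loc[14] == pytest.approx(1 - 0.95**15, abs=1e-12)

    def test_null_preset_gives_near_zero_strategy_terms(self):
        df = pt.simulate_registry(pt.get_preset("null", n_subjects=4000), seed=31)
        est = CloneCensorWeight().fit(df)
        curves = est.risk_curves_.pivot(index="day", columns="strategy",
                                        values="cumulative_incidence")
        assert np.max(np.abs((curves["early"] - curves["late"]).to_numpy())) < 0.04

    def test_beneficial_treatment_shows_early_dominance_midway(self, confounded_registry):
        est = CloneCensorWeight().fit(confounded_registry)
        wide = est.risk_curves_.pivot(index="day", columns="strategy",
                                      values="cumulative_incidence")
        assert wide.loc[14, "early"] > wide.loc[14, "late"]

    def test_nonconvergence_reports_context(self):
        day = np.zeros(4, dtype=int)
        strat = np.array([0, 0, 1, 1])
        event = np.array([0, 1, 0, 1])
        w = np.array([1e-12, 1e-12, 1e-12, 1e-12])
        with pytest.raises(glm.CollinearityError):
            estimation._fit_outcome_arrays(day, strat, event, w, ["a", "b"], 45, "cubic")


class TestMeanVentilatorDays:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            (np.zeros(46), 45.0),  # never extubated
            (np.r_[0.0, np.ones(45)], 0.0),  # everyone off the ventilator on day 1
            (np.arange(46) / 45.0, 22.0),  # linear ramp: arithmetic series
        ],
    )
    def test_closed_forms(self, curve, expected):
        assert mean_ventilator_days(curve) == pytest.approx(expected, abs=1e-12)

    def test_identity_with_risk_curve_sum(self, confounded_registry):
        est = CloneCensorWeight().fit(confounded_registry.head(1500))
        for s in ("early", "late"):
            ci = est.risk_curves_[est.risk_curves_["strategy"] == s][
                "cumulative_incidence"
            ].to_numpy()
            assert est.effect_report_.mean_ventilator_days[s] == pytest.approx(
                float(np.sum(1 - ci[1:])), abs=1e-12
            )


class TestKaplanMeierEquivalence:
    def test_saturated_uncensored_matches_km(self):
        # single strategy, everyone treated at day 0, no deviation possible:
        # the pipeline's curve must equal 1 - KM survivor function exactly
        import lifelines

        rng = np.random.default_rng(41)
        rows = []
        for _ in range(60):
            if rng.random() < 0.75:
                d = int(rng.integers(0, 46))
                rows.append(dict(intervention_day=0, extubation_episodes=f"{d}:0"))
            else:
                rows.append(dict(intervention_day=0))
        df = make_registry(rows)
        est = CloneCensorWeight(
            strategies=(EARLY,), time_spec="saturated", weighted=False
        ).fit(df)
        ci = est.risk_curves_.set_index("day")["cumulative_incidence"]

        out = cohort.add_outcome_days(df)["outcome_day"]
        durations = out.fillna(45).to_numpy(dtype=float)
        events = out.notna().to_numpy(dtype=int)
        km = lifelines.KaplanMeierFitter().fit(durations, events, timeline=np.arange(46))
        surv = km.survival_function_.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(ci.to_numpy(), 1 - surv, atol=1e-9)


class TestBaselineTable:
    def _fitted(self, registry):
        return CloneCensorWeight().fit(registry)

    def test_unit_weights_make_weighted_equal_unweighted(self):
        rng = np.random.default_rng(8)
        rows = [
            dict(
                intervention_day=int(rng.integers(0, 4)),  # all early, weight 1
                birth_weight_g=600.0 + 10 * i,
                gestational_age_weeks=float(rng.uniform(23, 28)),
                age_at_referral_days=int(rng.integers(5, 25)),
                sex=i % 2,
                referral_year=2014 + i,
                prior_pharmacotherapy=int(i != 3),
            )
            for i in range(12)
        ]
        df = cohort.add_outcome_days(make_registry(rows))
        clones, _ = make_clones(df, (EARLY, LATE))
        wt = ipw.compute_weights(clones, ipw.InitiationModel.constant(0.2))
        tab = baseline_table(clones, wt)
        early = tab[tab["strategy"] == "early"]  # all treated days 0-3: weight 1
        for _, r in early.iterrows():
            assert r["unweighted"] == r["weighted"], r["variable"]

    def test_scaling_weights_leaves_summaries_unchanged(self, confounded_registry):
        est = self._fitted(confounded_registry.head(1200))
        doubled = est.weight_table_.copy()
        doubled["weight_used"] *= 2.0
        tab1 = baseline_table(est.clones_, est.weight_table_)
        tab2 = baseline_table(est.clones_, doubled)
        for (_, a), (_, b) in zip(tab1.iterrows(), tab2.iterrows()):
            if a["variable"] == "n":
                assert b["weighted"] == pytest.approx(2 * a["weighted"])
            else:
                assert a["weighted"] == b["weighted"], a["variable"]

    def test_weighted_median_matches_hand_computation(self):
        # five clones with weights 1,1,2,1,5: inverted-CDF median = value
        # where cumulative weight first reaches half the total (5.0) -> 40;
        # the weighted 25% point (2.5) falls on the third value -> 30
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        w = np.array([1.0, 1.0, 2.0, 1.0, 5.0])
        assert estimation._weighted_quantile(x, w, 0.5) == 40.0
        assert estimation._weighted_quantile(x, w, 0.25) == 30.0


class TestVariants:
    def test_cde_equals_total_effect_without_deaths(self):
        params = replace(
            pt.get_preset("confounded", n_subjects=800),
            death_hazard_untreated=0.0,
            death_hazard_treated=0.0,
        )
        df = pt.simulate_registry(params, seed=51)
        total = CloneCensorWeight(competing="total").fit(df)
        cde = pt.run_cde_variant(df)
        assert total.person_days_.equals(cde.person_days_)
        assert total.risk_curves_.equals(cde.risk_curves_)

    def test_cde_dominates_total_effect_with_deaths(self):
        params = replace(
            pt.get_preset("confounded", n_subjects=20_000),
            death_hazard_untreated=0.012,
            death_hazard_treated=0.012,
        )
        df = pt.simulate_registry(params, seed=52)
        total = CloneCensorWeight().fit(df)
        cde = pt.run_cde_variant(df)
        for s in ("early", "late"):
            t = total.risk_curves_[total.risk_curves_["strategy"] == s][
                "cumulative_incidence"
            ].to_numpy()
            c = cde.risk_curves_[cde.risk_curves_["strategy"] == s][
                "cumulative_incidence"
            ].to_numpy()
            assert np.all(c >= t - 0.012)
            assert c[45] > t[45]

    def test_duplicated_covariate_surfaces_collinearity(self, confounded_registry):
        df = confounded_registry.head(1000).copy()
        df["birth_weight_copy"] = df["birth_weight_g"]
        with pytest.raises(glm.CollinearityError):
            pt.run_covariate_variant(df, extra_covariates=["birth_weight_copy"])

    def test_missing_extra_covariate_is_schema_error(self, confounded_registry):
        with pytest.raises(cohort.SchemaError, match="nonexistent"):
            pt.run_covariate_variant(confounded_registry, extra_covariates=["nonexistent"])

    def test_noise_covariate_leaves_estimates_alone(self, confounded_registry):
        # referral_site has no hazard effects in this preset
        main = CloneCensorWeight().fit(confounded_registry)
        with_site = pt.run_covariate_variant(confounded_registry)
        a = main.risk_curves_["cumulative_incidence"].to_numpy()
        b = with_site.risk_curves_["cumulative_incidence"].to_numpy()
        assert np.max(np.abs(a - b)) < 0.02

    def test_true_site_confounder_reduces_bias(self):
        params = pt.get_preset("site_confounded", n_subjects=20_000)
        df = pt.simulate_registry(params, seed=53)
        oracle = {}
        for strat in (EARLY, LATE):
            cur = pt.oracle_risk_curve(params, strat, n_mc=150_000, seed=54)
            oracle[strat.name] = cur.set_index("day")["cumulative_incidence"]

        def max_bias(est):
            wide = est.risk_curves_.pivot(index="day", columns="strategy",
                                          values="cumulative_incidence")
            return max(
                np.max(np.abs(wide[s].to_numpy() - oracle[s].to_numpy()))
                for s in ("early", "late")
            )

        without = CloneCensorWeight().fit(df)
        with_site = pt.run_covariate_variant(df)
        assert max_bias(with_site) < max_bias(without) - 0.01

    def test_age_axis_strategies_run_end_to_end(self):
        young = StrategyDef("younger", "age_days", 15, 20, max_age_at_referral=13)
        old = StrategyDef("older", "age_days", 21, 35, max_age_at_referral=13)
        df = pt.simulate_registry(pt.get_preset("confounded", n_subjects=4000), seed=55)
        est = CloneCensorWeight(strategies=(young, old)).fit(df)
        assert (est.clones_["age_at_referral_days"] <= 13).all()
        ci = est.risk_curves_["cumulative_incidence"]
        assert ci.between(0, 1).all()


def test_estimator_is_sklearn_compatible(confounded_registry):
    from sklearn.base import clone

    est = CloneCensorWeight(truncation_pct=95.0, stabilized=True)
    params = est.get_params()
    assert params["truncation_pct"] == 95.0
    twin = clone(est)
    assert twin.get_params() == params
    twin.set_params(time_spec="saturated").fit(confounded_registry.head(600))
    assert hasattr(twin, "risk_curves_")


def test_fast_path_matches_reference_fit(confounded_registry):
    df = confounded_registry.head(2500)
    est = CloneCensorWeight()
    est.fit(df)
    wide = est.risk_curves_.pivot(index="day", columns="strategy",
                                  values="cumulative_incidence")
    fast = est.estimate_curves(est.prepare(df))
    np.testing.assert_allclose(fast[0], wide["early"].to_numpy(), atol=1e-12)
    np.testing.assert_allclose(fast[1], wide["late"].to_numpy(), atol=1e-12)
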