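"""Clone expansion, deviation censoring and person-day bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_registry
from helpers import brute_clone_rows, random_subject
from pdatrial import cohort
from pdatrial.clones import (
    EARLY,
    LATE,
    StrategyDef,
    adherence_flow,
    deviation_day,
    expand_person_days,
    make_clones,
)


def _clones_from(rows):
    df = cohort.add_outcome_days(make_registry(rows))
    return make_clones(df, (EARLY, LATE))


class TestMakeClones:
    def test_two_clones_per_subject(self):
        clones, log = _clones_from([dict(), dict(), dict()])
        assert len(clones) == 6
        assert log["n_clones"] == 6
        assert set(clones["strategy"]) == {"early", "late"}

    def test_duplicate_strategy_names_rejected(self):
        df = cohort.add_outcome_days(make_registry([dict()]))
        with pytest.raises(ValueError, match="duplicate"):
            make_clones(df, (EARLY, StrategyDef("early", "referral_days", 5, 14)))

    def test_age_axis_window_already_closed_excludes_subject(self):
        young = StrategyDef("young", "age_days", 2, 6)
        df = cohort.add_outcome_days(make_registry([dict(age_at_referral_days=10), dict(age_at_referral_days=3)]))
        clones, log = make_clones(df, (young,))
        assert log["window_elapsed"] == 1
        assert len(clones) == 1

    def test_age_cap_excludes_subject(self):
        capped = StrategyDef("young", "age_days", 15, 20, max_age_at_referral=13)
        df = cohort.add_outcome_days(
            make_registry([dict(age_at_referral_days=20), dict(age_at_referral_days=10)])
        )
        clones, log = make_clones(df, (capped,))
        assert log["age_cap"] == 1
        assert clones["window_start_referral"].tolist() == [5]
        assert clones["window_end_referral"].tolist() == [10]


class TestDeviationDay:
    @pytest.mark.parametrize(
        "iday,out,death,ltfu,ws,we,expected",
        [
            (3, None, None, None, 0, 4, None),  # adherent to early
            (3, None, None, None, 5, 14, 3),  # early closure deviates from late
            (None, None, None, None, 0, 4, 4),  # untreated past the deadline
            (None, None, None, None, 5, 14, 14),
            (None, 2, None, None, 0, 4, None),  # extubated before either deadline:
            (None, 2, None, None, 5, 14, None),  # adherent to both strategies
            (None, None, 3, None, 0, 4, None),  # death precludes, not deviates
            (None, None, None, 2, 5, 14, None),  # lost before the deadline
            (None, 4, None, None, 0, 4, None),  # event on the deadline day wins
            (7, None, None, None, 0, 4, 4),  # late closure deviates from early
            (0, None, None, None, 5, 14, 0),
        ],
    )
    def test_rules(self, iday, out, death, ltfu, ws, we, expected):
        assert deviation_day(iday, out, death, ltfu, ws, we) == expected


class TestExpandPersonDays:
    def test_event_terminates_rows(self):
        clones, _ = _clones_from([dict(intervention_day=1, extubation_episodes="7:0")])
        rows = expand_person_days(clones)
        early = rows[rows["strategy"] == "early"]
        assert len(early) == 8  # days 0..7
        assert early["event"].tolist() == [0] * 7 + [1]

    def test_dead_adherent_clone_persists_to_horizon(self):
        clones, _ = _clones_from([dict(intervention_day=2, death_day=10)])
        rows = expand_person_days(clones)
        early = rows[rows["strategy"] == "early"]
        assert len(early) == 46  # total effect: days 0..45, all non-events
        assert early["event"].sum() == 0
        assert early["dead_by_t"].tolist() == [0] * 10 + [1] * 36

    def test_deviating_clone_stops_at_censoring_day(self):
        clones, _ = _clones_from([dict()])  # never treated
        rows = expand_person_days(clones)
        early = rows[rows["strategy"] == "early"]
        assert len(early) == 5  # days 0..4
        assert early["artificial_censor"].tolist() == [0, 0, 0, 0, 1]
        late = rows[rows["strategy"] == "late"]
        assert len(late) == 15
        assert late["artificial_censor"].iloc[-1] == 1

    def test_cde_truncates_at_death_and_flags_not_at_risk(self):
        clones, _ = _clones_from([dict(intervention_day=2, death_day=10)])
        rows = expand_person_days(clones, competing="cde")
        early = rows[rows["strategy"] == "early"]
        assert len(early) == 11  # days 0..10
        assert early["at_risk"].tolist() == [1] * 10 + [0]
        assert early["admin_censor"].iloc[-1] == 1

    def test_no_rows_after_artificial_censoring(self):
        rng = np.random.default_rng(11)
        rows_spec = [random_subject(rng) for _ in range(30)]
        regs = []
        for r in rows_spec:
            eps = f"{r['outcome_day']}:0" if r["outcome_day"] is not None else ""
            regs.append(
                dict(
                    intervention_day=r["intervention_day"] if r["intervention_day"] is not None else pd.NA,
                    extubation_episodes=eps,
                    death_day=r["death_day"] if r["death_day"] is not None else pd.NA,
                    ltfu_day=r["ltfu_day"] if r["ltfu_day"] is not None else pd.NA,
                    age_at_referral_days=r["age_at_referral_days"],
                )
            )
        clones, _ = _clones_from(regs)
        rows = expand_person_days(clones)
        for _, grp in rows.groupby("clone_id"):
            cens = grp.loc[grp["artificial_censor"] == 1, "day"]
            if len(cens):
                assert grp["day"].max() == cens.iloc[0]

    def test_early_and_late_rows_identical_before_divergence(self):
        rng = np.random.default_rng(13)
        regs = []
        for _ in range(40):
            r = random_subject(rng)
            eps = f"{r['outcome_day']}:0" if r["outcome_day"] is not None else ""
            regs.append(
                dict(
                    intervention_day=r["intervention_day"] if r["intervention_day"] is not None else pd.NA,
                    extubation_episodes=eps,
                    death_day=r["death_day"] if r["death_day"] is not None else pd.NA,
                    ltfu_day=r["ltfu_day"] if r["ltfu_day"] is not None else pd.NA,
                )
            )
        clones, _ = _clones_from(regs)
        rows = expand_person_days(clones)
        cols = ["day", "treated_by_t", "at_risk", "event", "admin_censor", "dead_by_t"]
        for sid, grp in rows.groupby("subject_id"):
            early = grp[grp["strategy"] == "early"]
            late = grp[grp["strategy"] == "late"]
            dev = clones.loc[clones["subject_id"] == sid, "deviation_day"]
            d_star = int(dev.dropna().min()) if dev.notna().any() else 46
            e = early[early["day"] < d_star][cols].reset_index(drop=True)
            l = late[late["day"] < d_star][cols].reset_index(drop=True)
            assert e.equals(l), sid

    def test_matches_bruteforce_enumeration_sample(self):
        # the full 200-instance sweep lives in the acceptance suite
        rng = np.random.default_rng(17)
        strategies = (EARLY, LATE)
        for _ in range(30):
            subs = [random_subject(rng) for _ in range(int(rng.integers(1, 8)))]
            regs = []
            for r in subs:
                eps = f"{r['outcome_day']}:0" if r["outcome_day"] is not None else ""
                regs.append(
                    dict(
                        intervention_day=r["intervention_day"] if r["intervention_day"] is not None else pd.NA,
                        extubation_episodes=eps,
                        death_day=r["death_day"] if r["death_day"] is not None else pd.NA,
                        ltfu_day=r["ltfu_day"] if r["ltfu_day"] is not None else pd.NA,
                        age_at_referral_days=r["age_at_referral_days"],
                    )
                )
            df = cohort.add_outcome_days(make_registry(regs))
            clones, _ = make_clones(df, strategies)
            rows = expand_person_days(clones)
            for i, r in enumerate(subs):
                sub = dict(r)
                sub["outcome_day"] = (
                    None if pd.isna(df.loc[i, "outcome_day"]) else int(df.loc[i, "outcome_day"])
                )
                for strat in strategies:
                    got = rows[(rows["subject_id"] == f"S{i}") & (rows["strategy"] == strat.name)]
                    want = brute_clone_rows(sub, strat)
                    assert len(got) == len(want)
                    for col in ["day", "treated_by_t", "at_risk", "event",
                                "artificial_censor", "admin_censor", "dead_by_t"]:
                        assert got[col].tolist() == [w[col] for w in want], (i, strat.name, col)


def test_adherence_flow_counts():
    clones, _ = _clones_from(
        [
            dict(intervention_day=2),  # early only
            dict(intervention_day=8),  # late only
            dict(extubation_episodes="1:0"),  # extubated untreated: both
            dict(),  # neither
        ]
    )
    flow = adherence_flow(clones)
    assert flow == {
        "adherent_early": 2,
        "adherent_late": 2,
        "adherent_both": 1,
        "adherent_neither": 1,
        "n_subjects": 4,
    }
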