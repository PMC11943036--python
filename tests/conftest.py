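import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

import pdatrial as pt
from pdatrial.simulate import HazardSpec, SimParams
from dataclasses import replace


def make_registry_row(subject_id="S1", **kw):
    """One registry row with benign defaults, overridable per test."""
    row = dict(
        subject_id=subject_id,
        gestational_age_weeks=25.0,
        birth_weight_g=700.0,
        age_at_referral_days=14,
        sex=0,
        referral_year=2019,
        prior_pharmacotherapy=1,
        ventilated_at_referral=1,
        complex_chd=0,
        bidirectional_or_r2l_flow=0,
        major_anomaly=0,
        tracheostomy=0,
        pharmacotherapy_contraindicated=0,
        intervention_day=pd.NA,
        extubation_episodes="",
        death_day=pd.NA,
        ltfu_day=pd.NA,
    )
    row.update(kw)
    return row


def make_registry(rows):
    if not rows:
        return pd.DataFrame([make_registry_row("S0")]).iloc[0:0]
    return pd.DataFrame([make_registry_row(f"S{i}", **r) for i, r in enumerate(rows)])


@pytest.fixture(scope="session")
def confounded_registry():
    """Medium synthetic registry under the strongly confounded preset."""
    params = pt.get_preset("confounded", n_subjects=4000)
    return pt.simulate_registry(params, seed=101)


@pytest.fixture
def flat_initiation_params():
    """Constant initiation hazard 0.2, no covariate effects, no exits."""
    return replace(
        SimParams(n_subjects=2000, seed=7),
        initiation=HazardSpec(intercept=float(np.log(0.2 / 0.8))),
        extubation=HazardSpec(intercept=-60.0),
        death_hazard_untreated=0.0,
        death_hazard_treated=0.0,
        ltfu_hazard=0.0,
    )
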