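"""Synthetic referral registry with a known data-generating mechanism.

The generator emulates the world the emulation assumes: premature infants
referred for definitive PDA closure, with a confounded daily hazard of
undergoing the closure procedure, a daily hazard of an extubation attempt
that shifts once the duct is closed, death as a competing event, and loss to
follow-up (retro-transfer) after the intervention.

Time is discrete in whole days on the referral clock (day 0 = referral).  At
most one transition happens per subject-day, evaluated in a fixed order:
death, then extubation attempt, then loss to follow-up, then treatment
initiation.  Because initiation is evaluated last, closure performed on day t
affects hazards from day t+1 on.  A failed extubation attempt (reintubation
within seven days) returns the infant to the ventilated state; the next
attempt can occur from two days later.

Covariate--hazard links are logistic throughout, with coefficients expressed
per standard deviation of each covariate (fixed standardisation constants
below), so hazards are guaranteed to lie in (0, 1) for every covariate value.

The module also provides the forced-adherence Monte-Carlo oracle: the true
per-protocol cumulative incidence under a treatment-timing strategy, obtained
by forcing the intervention day (uniform over the strategy window by default)
and disabling loss to follow-up, with deaths carried as never-extubated
(total-effect convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort
from .clones import StrategyDef

__all__ = [
    "HazardSpec",
    "SimParams",
    "get_preset",
    "PRESETS",
    "simulate_registry",
    "oracle_risk_curve",
    "oracle_outcome_days",
]

# Fixed standardisation constants (centre, scale) used by the hazard links.
# They are part of the data-generating mechanism, not estimated from data.
STANDARDIZATION = {
    "birth_weight_g": (750.0, 150.0),
    "gestational_age_weeks": (24.5, 1.5),
    "age_at_referral_days": (16.0, 8.0),
    "sex": (0.0, 1.0),
    "referral_year": (2018.5, 3.0),
    "prior_pharmacotherapy": (0.0, 1.0),
}

#: Site-specific log-odds offsets are keyed by these labels.
SITES = ("A", "B", "C")


@dataclass(frozen=True)
class HazardSpec:
    """Logistic daily hazard: logit h = intercept + x'beta + day terms."""

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)
    day_slope: float = 0.0
    #: log-odds shift once treated (duct closed), applied from the day after
    #: the procedure; extubation hazard only.
    treated_effect: float = 0.0
    #: additional log-odds per day since treatment.
    treated_day_slope: float = 0.0
    #: optional per-site log-odds offsets, keyed by site label.
    site_effects: dict[str, float] = field(default_factory=dict)

    def logit(self, z: dict[str, np.ndarray], day: int, days_since_treatment: np.ndarray | None,
              site_offset: np.ndarray | None) -> np.ndarray:
        eta = self.intercept + self.day_slope * day
        for name, c in self.coefs.items():
            if name not in z:
                raise ValueError(f"hazard coefficient on unknown covariate {name!r}")
            eta = eta + c * z[name]
        if days_since_treatment is not None:
            treated = days_since_treatment >= 1
            eta = eta + np.where(
                treated,
                self.treated_effect + self.treated_day_slope * np.maximum(days_since_treatment - 1, 0),
                0.0,
            )
        if site_offset is not None:
            eta = eta + site_offset
        return eta


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic registry generator.

    Baseline-covariate distributions are loosely calibrated to the kind of
    referral cohort the emulation assumes (median gestational age about 24--25
    weeks, birth weight around 745 g, referral in the second to third week of
    life); hazards are daily probabilities.
    """

    n_subjects: int = 500
    horizon: int = 45
    seed: int = 0

    # --- baseline covariates ---
    ga_mean: float = 24.6
    ga_sd: float = 1.6
    ga_bounds: tuple[float, float] = (22.0, 29.9)
    bw_mean: float = 760.0
    bw_sd: float = 150.0
    bw_per_ga_week: float = 60.0  # heavier with later gestation
    bw_bounds: tuple[float, float] = (420.0, 1499.0)
    age_log_mean: float = 2.77  # median ~16 days at referral
    age_log_sd: float = 0.45
    age_bounds: tuple[int, int] = (1, 35)
    p_female: float = 0.45
    year_range: tuple[int, int] = (2014, 2023)
    p_prior_pharmacotherapy: float = 0.83
    p_contraindicated: float = 0.5  # among those without a prior course
    site_probs: tuple[float, ...] = (0.5, 0.3, 0.2)

    # --- eligibility-flag prevalences (independent of the hazards) ---
    p_not_ventilated: float = 0.03
    p_complex_chd: float = 0.03
    p_r2l_flow: float = 0.03
    p_major_anomaly: float = 0.02
    p_tracheostomy: float = 0.01

    # --- daily hazards ---
    initiation: HazardSpec = field(
        default_factory=lambda: HazardSpec(intercept=-1.82, coefs={"birth_weight_g": -0.8})
    )
    extubation: HazardSpec = field(
        default_factory=lambda: HazardSpec(
            intercept=-4.2,
            coefs={"birth_weight_g": 0.7, "gestational_age_weeks": 0.25},
            day_slope=0.01,
            treated_effect=1.0,
            treated_day_slope=0.04,
        )
    )
    death_hazard_untreated: float = 0.0015
    death_hazard_treated: float = 0.0015
    ltfu_hazard: float = 0.01  # after intervention only; real rate unknown
    reintubation_prob: float = 0.3

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for name in ("death_hazard_untreated", "death_hazard_treated", "ltfu_hazard",
                     "reintubation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability in [0, 1]")
        for p in ("p_female", "p_prior_pharmacotherapy", "p_contraindicated",
                  "p_not_ventilated", "p_complex_chd", "p_r2l_flow",
                  "p_major_anomaly", "p_tracheostomy"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p}={v} is not a probability in [0, 1]")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise ValueError("site_probs must sum to 1")


def _build_presets() -> dict[str, SimParams]:
    default = SimParams()
    # Strong confounding by birth weight: small infants are closed sooner and
    # are intrinsically harder to extubate, so naive clone estimates without
    # weighting are biased.  The initiation level (~0.14/day at the centre)
    # keeps the realised within-window timing of the deadline regime close to
    # the uniform-regime benchmark.
    confounded = replace(
        default,
        ltfu_hazard=0.005,
        initiation=HazardSpec(
            intercept=-1.15,
            day_slope=-0.055,
            coefs={"birth_weight_g": -0.6, "gestational_age_weeks": -0.15,
                   "prior_pharmacotherapy": 0.15},
        ),
        extubation=HazardSpec(
            intercept=-4.35,
            coefs={"birth_weight_g": 0.9, "gestational_age_weeks": 0.3},
            day_slope=0.012,
            treated_effect=0.7,
            treated_day_slope=0.02,
        ),
    )
    # Null world: closure affects no hazard.  Designed as a precise diagnostic
    # of spurious effects rather than a replica of the confounded world: the
    # initiation hazard is covariate-free and rises over follow-up (clinical
    # pressure to close mounts), which keeps both grace-period deadline
    # weights and arm disjointness -- the two main variance sources of the
    # cloned design -- small; loss to follow-up, deaths and eligibility
    # exclusions are switched off so the full cohort informs both arms.
    null = replace(
        default,
        initiation=HazardSpec(intercept=-1.5, day_slope=0.14),
        extubation=HazardSpec(
            intercept=-4.35,
            coefs={"birth_weight_g": 0.9, "gestational_age_weeks": 0.3},
            day_slope=0.012,
        ),
        death_hazard_untreated=0.0,
        death_hazard_treated=0.0,
        ltfu_hazard=0.0,
        p_not_ventilated=0.0,
        p_complex_chd=0.0,
        p_r2l_flow=0.0,
        p_major_anomaly=0.0,
        p_tracheostomy=0.0,
    )
    site_confounded = replace(
        confounded,
        initiation=replace(confounded.initiation,
                           site_effects={"A": 0.0, "B": -0.9, "C": 0.9}),
        extubation=replace(confounded.extubation,
                           site_effects={"A": 0.0, "B": 0.8, "C": -0.8}),
    )
    paper_shape = replace(default, n_subjects=131)
    return {
        "default": default,
        "confounded": confounded,
        "null": null,
        "site_confounded": site_confounded,
        "paper_shape": paper_shape,
    }


PRESETS = _build_presets()


def get_preset(name: str, **overrides) -> SimParams:
    """Return a named parameter preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


def params_from_config(cfg: dict) -> SimParams:
    """Build :class:`SimParams` from a config mapping (YAML/JSON friendly)."""
    cfg = dict(cfg)
    preset = cfg.pop("preset", "default")
    hazards = {}
    for key in ("initiation", "extubation"):
        if key in cfg:
            hazards[key] = HazardSpec(**cfg.pop(key))
    params = get_preset(preset, **cfg)
    if hazards:
        params = replace(params, **hazards)
    return params


def load_params(path) -> SimParams:
    with open(path) as fh:
        return params_from_config(yaml.safe_load(fh) or {})


def _draw_covariates(params: SimParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    ga = np.clip(rng.normal(params.ga_mean, params.ga_sd, n), *params.ga_bounds)
    bw = params.bw_mean + params.bw_per_ga_week * (ga - params.ga_mean) + rng.normal(
        0.0, params.bw_sd, n
    )
    bw = np.clip(bw, *params.bw_bounds)
    age = np.clip(
        np.rint(np.exp(rng.normal(params.age_log_mean, params.age_log_sd, n))),
        params.age_bounds[0],
        params.age_bounds[1],
    ).astype(int)
    sex = rng.binomial(1, params.p_female, n)
    year = rng.integers(params.year_range[0], params.year_range[1] + 1, n)
    prior = rng.binomial(1, params.p_prior_pharmacotherapy, n)
    contra = np.where(prior == 1, 0, rng.binomial(1, params.p_contraindicated, n))
    site = rng.choice(len(SITES), size=n, p=params.site_probs)
    return pd.DataFrame(
        {
            "gestational_age_weeks": np.round(ga, 1),
            "birth_weight_g": np.round(bw, 0),
            "age_at_referral_days": age,
            "sex": sex,
            "referral_year": year,
            "prior_pharmacotherapy": prior,
            "pharmacotherapy_contraindicated": contra,
            "referral_site": [SITES[i] for i in site],
        }
    )


def _standardize(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    z = {}
    for name, (centre, scale) in STANDARDIZATION.items():
        z[name] = (cov[name].to_numpy(dtype=float) - centre) / scale
    return z


def _site_offsets(spec: HazardSpec, site: np.ndarray) -> np.ndarray | None:
    if not spec.site_effects:
        return None
    table = np.array([spec.site_effects.get(s, 0.0) for s in SITES])
    return table[site]


def _run_event_loop(
    params: SimParams,
    cov: pd.DataFrame,
    rng: np.random.Generator,
    forced_day: np.ndarray | None = None,
    disable_ltfu: bool = False,
):
    """Vectorised day loop shared by the registry generator and the oracle.

    ``forced_day`` replaces the natural initiation process: subject i
    undergoes closure on ``forced_day[i]`` if still alive, ventilated without
    a pending success, and untreated on that day (entries < 0 mean never).
    Returns (intervention_day, death_day, ltfu_day, outcome_day, episodes)
    with -1 encoding "absent".
    """
    n = len(cov)
    z = _standardize(cov)
    site = np.array([SITES.index(s) for s in cov["referral_site"]])
    site_init = _site_offsets(params.initiation, site)
    site_ext = _site_offsets(params.extubation, site)

    from .glm import sigmoid

    int_day = np.full(n, -1, dtype=int)
    death_day = np.full(n, -1, dtype=int)
    ltfu_day = np.full(n, -1, dtype=int)
    outcome_day = np.full(n, -1, dtype=int)
    next_attempt_ok = np.zeros(n, dtype=int)  # earliest day of the next attempt
    episodes: list[tuple[int, int, int]] = []  # (subject index, day, reintubated)

    for t in range(params.horizon + 1):
        active = (death_day < 0) & (ltfu_day < 0) & (outcome_day < 0)
        if not active.any():
            break
        treated = (int_day >= 0) & (int_day < t)
        dst = np.where(treated, t - int_day, 0)

        # 1. death
        p_death = np.where(treated, params.death_hazard_treated, params.death_hazard_untreated)
        dies = active & (rng.random(n) < p_death)
        death_day[dies] = t

        # 2. extubation attempt (while ventilated and past any reintubation)
        can_attempt = active & ~dies & (next_attempt_ok <= t)
        p_ext = sigmoid(params.extubation.logit(z, t, dst, site_ext))
        attempt = can_attempt & (rng.random(n) < p_ext)
        if attempt.any():
            reint = attempt & (rng.random(n) < params.reintubation_prob)
            success = attempt & ~reint
            for i in np.where(attempt)[0]:
                episodes.append((i, t, int(reint[i])))
            outcome_day[success] = t
            # reintubated the following day; at risk again the day after
            next_attempt_ok[reint] = t + 2

        # 3. loss to follow-up (after intervention only)
        if not disable_ltfu and params.ltfu_hazard > 0:
            lost = active & ~dies & ~attempt & treated & (rng.random(n) < params.ltfu_hazard)
            ltfu_day[lost] = t

        # 4. treatment initiation
        untreated = active & ~dies & ~attempt & (int_day < 0)
        if not disable_ltfu and params.ltfu_hazard > 0:
            untreated &= ltfu_day < 0
        if forced_day is None:
            p_init = sigmoid(params.initiation.logit(z, t, None, site_init))
            u = rng.random(n)
            starts = untreated & (u < p_init)
        else:
            # Forced adherence: the procedure happens on the assigned day
            # unless the subject has died or already reached the outcome; a
            # same-day *failed* extubation attempt does not defer it (the
            # one-transition-per-day rule is a property of the observational
            # process, not of the counterfactual regime).
            starts = (
                active & ~dies & (int_day < 0) & (forced_day == t)
                & (outcome_day < 0)
            )
        int_day[starts] = t

    return int_day, death_day, ltfu_day, outcome_day, episodes


def simulate_registry(params: SimParams, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a synthetic referral registry (one row per subject).

    Deterministic for a fixed seed.  The returned frame follows the registry
    schema of :mod:`pdatrial.cohort`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_subjects
    cov = _draw_covariates(params, n, rng)

    flags = pd.DataFrame(
        {
            "ventilated_at_referral": 1 - rng.binomial(1, params.p_not_ventilated, n),
            "complex_chd": rng.binomial(1, params.p_complex_chd, n),
            "bidirectional_or_r2l_flow": rng.binomial(1, params.p_r2l_flow, n),
            "major_anomaly": rng.binomial(1, params.p_major_anomaly, n),
            "tracheostomy": rng.binomial(1, params.p_tracheostomy, n),
        }
    )

    int_day, death_day, ltfu_day, _outcome, episodes = _run_event_loop(params, cov, rng)

    ep_strings = [""] * n
    by_subject: dict[int, list[str]] = {}
    for i, day, reint in episodes:
        by_subject.setdefault(i, []).append(f"{day}:{reint}")
    for i, parts in by_subject.items():
        ep_strings[i] = ";".join(parts)

    df = pd.DataFrame({"subject_id": [f"S{i:05d}" for i in range(n)]})
    df = pd.concat([df, cov, flags], axis=1)
    df["intervention_day"] = pd.array(np.where(int_day < 0, pd.NA, int_day), dtype="Int64")
    df["extubation_episodes"] = ep_strings
    df["death_day"] = pd.array(np.where(death_day < 0, pd.NA, death_day), dtype="Int64")
    df["ltfu_day"] = pd.array(np.where(ltfu_day < 0, pd.NA, ltfu_day), dtype="Int64")
    return df


def oracle_outcome_days(
    params: SimParams,
    strategy: StrategyDef,
    n_mc: int,
    seed: int,
    regime: str = "uniform",
) -> np.ndarray:
    """Outcome days (-1 = never within horizon) under forced adherence.

    ``regime="uniform"``: the intervention day is drawn uniformly over the
    strategy window, the analytical adherence pattern the emulation assumes.
    ``regime="deadline"``: the natural initiation process runs inside the
    window, suppressed outside it, with initiation forced on the final window
    day -- the regime the deadline-censoring estimator identifies.

    Eligibility screening is applied, loss to follow-up is disabled (the
    per-protocol estimand assumes complete follow-up) and deaths are carried
    as never-extubated (total effect).
    """
    params = replace(params, n_subjects=n_mc, ltfu_hazard=0.0)
    params.validate()
    if strategy.window_end < strategy.window_start:
        raise ValueError("strategy window is empty")
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(params, n_mc, rng)

    flags = pd.DataFrame(
        {
            "ventilated_at_referral": 1 - rng.binomial(1, params.p_not_ventilated, n_mc),
            "complex_chd": rng.binomial(1, params.p_complex_chd, n_mc),
            "bidirectional_or_r2l_flow": rng.binomial(1, params.p_r2l_flow, n_mc),
            "major_anomaly": rng.binomial(1, params.p_major_anomaly, n_mc),
            "tracheostomy": rng.binomial(1, params.p_tracheostomy, n_mc),
        }
    )
    screen = pd.concat([cov, flags], axis=1)
    eligible, _ = cohort.apply_eligibility(screen)
    if strategy.max_age_at_referral is not None:
        eligible = eligible.loc[
            eligible["age_at_referral_days"] <= strategy.max_age_at_referral
        ].reset_index(drop=True)
    cov = eligible[cov.columns]
    n = len(cov)
    age = cov["age_at_referral_days"].to_numpy(dtype=int)
    ws, we = strategy.window_on_referral_clock(age)
    if np.any(we < 0):
        raise ValueError("strategy window lies entirely before referral for some subjects")
    ws = np.maximum(ws, 0)

    if regime == "uniform":
        forced = rng.integers(ws, we + 1)  # per-subject uniform over the window
        *_, outcome_day, _eps = _run_event_loop(params, cov, rng, forced_day=forced,
                                                disable_ltfu=True)
    elif regime == "deadline":
        # Natural initiation within the window, forced at the deadline: thin
        # the natural hazard to zero outside [ws, we) and force day we.
        outcome_day = _deadline_regime_loop(params, cov, rng, ws, we)
    else:
        raise ValueError(f"unknown adherence regime {regime!r}")
    return outcome_day


def _deadline_regime_loop(params, cov, rng, ws, we):
    """Event loop for the natural-within-window, forced-at-deadline regime."""
    n = len(cov)
    z = _standardize(cov)
    site = np.array([SITES.index(s) for s in cov["referral_site"]])
    site_init = _site_offsets(params.initiation, site)
    site_ext = _site_offsets(params.extubation, site)
    from .glm import sigmoid

    int_day = np.full(n, -1, dtype=int)
    death_day = np.full(n, -1, dtype=int)
    outcome_day = np.full(n, -1, dtype=int)
    next_attempt_ok = np.zeros(n, dtype=int)

    for t in range(params.horizon + 1):
        active = (death_day < 0) & (outcome_day < 0)
        if not active.any():
            break
        treated = (int_day >= 0) & (int_day < t)
        dst = np.where(treated, t - int_day, 0)
        p_death = np.where(treated, params.death_hazard_treated, params.death_hazard_untreated)
        dies = active & (rng.random(n) < p_death)
        death_day[dies] = t
        can_attempt = active & ~dies & (next_attempt_ok <= t)
        p_ext = sigmoid(params.extubation.logit(z, t, dst, site_ext))
        attempt = can_attempt & (rng.random(n) < p_ext)
        reint = attempt & (rng.random(n) < params.reintubation_prob)
        outcome_day[attempt & ~reint] = t
        next_attempt_ok[reint] = t + 2
        untreated = active & ~dies & ~attempt & (int_day < 0)
        p_init = sigmoid(params.initiation.logit(z, t, None, site_init))
        natural = untreated & (t >= ws) & (t < we) & (rng.random(n) < p_init)
        # deadline: forced even on a failed-attempt day (see _run_event_loop)
        forced = active & ~dies & (int_day < 0) & (t == we) & (outcome_day < 0)
        int_day[natural | forced] = t
    return outcome_day


def oracle_risk_curve(
    params: SimParams,
    strategy: StrategyDef,
    n_mc: int = 200_000,
    seed: int = 0,
    regime: str = "uniform",
) -> pd.DataFrame:
    """True per-protocol cumulative incidence of successful extubation.

    Monte-Carlo forced-adherence simulation; see :func:`oracle_outcome_days`.
    Returns a frame with columns ``strategy``, ``day`` (0..horizon) and
    ``cumulative_incidence``; the curve is non-decreasing and in [0, 1].
    """
    outcome_day = oracle_outcome_days(params, strategy, n_mc, seed, regime=regime)
    n = len(outcome_day)
    days = np.arange(params.horizon + 1)
    counts = np.bincount(outcome_day[outcome_day >= 0], minlength=params.horizon + 1)
    ci = np.cumsum(counts)[: params.horizon + 1] / max(n, 1)
    return pd.DataFrame(
        {"strategy": strategy.name, "day": days, "cumulative_incidence": ci}
    )
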