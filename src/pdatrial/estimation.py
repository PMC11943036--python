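"""Weighted pooled-logistic outcome model and effect estimation.

The outcome model is marginal: daily hazard of successful extubation as a
function of assigned strategy and follow-up time only, fitted on the weighted
clone person-days; confounding is handled entirely by the weights.  The
default time specification is a cubic polynomial in day with full
strategy-by-time interactions; a saturated per-day specification is available
(its maximum-likelihood hazards are the weighted day-specific event
proportions, which is what the estimator computes directly).

Day-indexing convention, used everywhere: the hazard at day t applies to the
interval [t, t+1); the cumulative incidence is reported at the end of day t,
CI(t) = 1 - prod_{k<=t} (1 - h(k)).  Mean ventilator days over a horizon H is
sum_{t=1}^{H} (1 - CI(t)): a day on the ventilator is counted for every day
whose end is reached without successful extubation, and deaths contribute as
ventilated through the horizon via the total-effect curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import cohort, glm, ipw
from .clones import (
    DEFAULT_STRATEGIES,
    StrategyDef,
    _as_sentinel,
    _terminal_days,
    adherence_flow,
    expand_person_days,
    make_clones,
)

__all__ = [
    "OutcomeModel",
    "EffectReport",
    "CloneCensorWeight",
    "fit_outcome_model",
    "risk_curves",
    "mean_ventilator_days",
    "baseline_table",
    "run_cde_variant",
    "run_covariate_variant",
]

SELECTED_DAYS = (7, 14, 30, 45)

#: Registry covariates summarised as medians [IQR] in the baseline table.
CONTINUOUS_BASELINE = [
    "gestational_age_weeks",
    "birth_weight_g",
    "age_at_referral_days",
    "referral_year",
]
#: Registry covariates summarised as weighted percentages.
BINARY_BASELINE = ["sex", "prior_pharmacotherapy"]


@dataclass
class OutcomeModel:
    """Fitted discrete-time hazard of successful extubation."""

    kind: str  # "cubic" or "saturated"
    strategies: list[str]
    horizon: int
    beta: Optional[np.ndarray] = None
    feature_names: Optional[list[str]] = None
    hazards: Optional[np.ndarray] = None  # (n_strategies, horizon+1), saturated

    @classmethod
    def constant(cls, hazard: float, strategies=("early", "late"), horizon: int = 45):
        h = np.full((len(strategies), horizon + 1), float(hazard))
        return cls(kind="saturated", strategies=list(strategies), horizon=horizon, hazards=h)

    def hazard(self, strategy) -> np.ndarray:
        """Daily hazard h(0..horizon) for one strategy (index or name)."""
        s = self.strategies.index(strategy) if isinstance(strategy, str) else int(strategy)
        if self.kind == "saturated":
            return self.hazards[s]
        t = np.arange(self.horizon + 1)
        X = _time_features(t, np.full_like(t, s), len(self.strategies), self.horizon)
        return glm.predict_proba(X, self.beta)

    def coefficients(self) -> dict[str, float]:
        if self.beta is None:
            raise ValueError("saturated model has no coefficient vector")
        return dict(zip(self.feature_names, map(float, self.beta)))


def _time_features(day: np.ndarray, strat_idx: np.ndarray, n_strat: int, horizon: int):
    """Design matrix of the cubic time specification with interactions."""
    u = day / float(horizon)
    base = [np.ones_like(u), u, u**2, u**3]
    cols = list(base)
    for s in range(1, n_strat):
        d = (strat_idx == s).astype(float)
        cols.extend([d, d * u, d * u**2, d * u**3])
    return np.column_stack(cols)


def _time_feature_names(strategies: list[str]) -> list[str]:
    names = ["intercept", "t", "t2", "t3"]
    for s in strategies[1:]:
        names += [f"{s}", f"{s}:t", f"{s}:t2", f"{s}:t3"]
    return names


def _fit_outcome_arrays(
    day: np.ndarray,
    strat_idx: np.ndarray,
    event: np.ndarray,
    weight: np.ndarray,
    strategies: list[str],
    horizon: int,
    time_spec: str,
) -> OutcomeModel:
    n_strat = len(strategies)
    if time_spec == "saturated":
        # MLE of the fully saturated pooled logistic: weighted event
        # proportions per strategy-day; days with no at-risk mass get hazard 0.
        code = strat_idx * (horizon + 1) + day
        size = n_strat * (horizon + 1)
        num = np.bincount(code, weights=weight * event, minlength=size)
        den = np.bincount(code, weights=weight, minlength=size)
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        return OutcomeModel(
            kind="saturated",
            strategies=strategies,
            horizon=horizon,
            hazards=h.reshape(n_strat, horizon + 1),
        )
    if time_spec != "cubic":
        raise ValueError(f"unknown time_spec {time_spec!r}")
    X = _time_features(day, strat_idx, n_strat, horizon)
    names = _time_feature_names(strategies)
    try:
        beta = glm.fit_logistic(X, event.astype(float), sample_weight=weight,
                                column_names=names)
    except glm.ConvergenceError as exc:
        raise glm.ConvergenceError(
            f"outcome model did not converge (rows={len(day)}, "
            f"events={float(np.sum(weight * event)):.1f}): {exc}"
        ) from exc
    return OutcomeModel(
        kind="cubic", strategies=strategies, horizon=horizon, beta=beta, feature_names=names
    )


def fit_outcome_model(
    person_days: pd.DataFrame,
    weights: Optional[np.ndarray] = None,
    time_spec: str = "cubic",
    strategies: Optional[list[str]] = None,
    horizon: int = 45,
) -> OutcomeModel:
    """Fit the weighted pooled-logistic outcome model on clone person-days.

    ``person_days`` is the frame from
    :func:`pdatrial.clones.expand_person_days`; ``weights`` aligns with its
    rows (default 1).  Artificial-censoring rows and rows flagged not at risk
    are excluded from the risk set.
    """
    if strategies is None:
        strategies = list(dict.fromkeys(person_days["strategy"]))
    w = np.ones(len(person_days)) if weights is None else np.asarray(weights, float)
    mask = (person_days["artificial_censor"].to_numpy() == 0) & (
        person_days["at_risk"].to_numpy() == 1
    )
    smap = {s: i for i, s in enumerate(strategies)}
    strat_idx = person_days["strategy"].map(smap).to_numpy()
    return _fit_outcome_arrays(
        person_days["day"].to_numpy()[mask],
        strat_idx[mask],
        person_days["event"].to_numpy()[mask],
        w[mask],
        strategies,
        horizon,
        time_spec,
    )


def risk_curves(model: OutcomeModel) -> pd.DataFrame:
    """Cumulative incidence CI(t) = 1 - prod_{k<=t}(1 - h(k)) per strategy."""
    frames = []
    for s in model.strategies:
        h = model.hazard(s)
        ci = 1.0 - np.cumprod(1.0 - h)
        frames.append(
            pd.DataFrame(
                {"strategy": s, "day": np.arange(model.horizon + 1), "cumulative_incidence": ci}
            )
        )
    return pd.concat(frames, ignore_index=True)


def mean_ventilator_days(curve, horizon: int = 45) -> float:
    """Restricted mean ventilator days from a cumulative-incidence curve.

    ``curve`` is indexable by day 0..horizon (array, Series, or the
    ``cumulative_incidence`` column of a one-strategy frame).
    """
    if isinstance(curve, pd.DataFrame):
        curve = curve.sort_values("day")["cumulative_incidence"].to_numpy()
    ci = np.asarray(curve, dtype=float)
    return float(np.sum(1.0 - ci[1 : horizon + 1]))


def _weighted_quantile(x, w, q):
    return float(np.quantile(np.asarray(x, float), q, weights=np.asarray(w, float),
                             method="inverted_cdf"))


def baseline_table(
    clones: pd.DataFrame,
    weight_table: pd.DataFrame,
    horizon: int = 45,
) -> pd.DataFrame:
    """Weighted and unweighted baseline summary at the end of the grace period.

    Rows are clones that never deviated from their strategy; each contributes
    its weight at the last day it was observed within its grace window.
    Continuous covariates are summarised as median [IQR] (weighted quantiles
    of type inverted-CDF), binary ones as percentages; the weighted
    pseudo-population size is the sum of weights.
    """
    adherent = clones[pd.isna(clones["deviation_day"])].copy()
    T, *_ = _terminal_days(adherent, horizon, "total")
    adherent["_grace_day"] = np.minimum(T, adherent["window_end_referral"].to_numpy())
    wt = weight_table.rename(columns={"day": "_grace_day"})
    merged = adherent.merge(
        wt[["clone_id", "_grace_day", "weight_used"]], on=["clone_id", "_grace_day"], how="left"
    )
    merged["weight_used"] = merged["weight_used"].fillna(1.0)

    rows = []
    for s, grp in merged.groupby("strategy", sort=False):
        w = grp["weight_used"].to_numpy()
        rows.append({"strategy": s, "variable": "n", "unweighted": float(len(grp)),
                     "weighted": float(w.sum())})
        for v in CONTINUOUS_BASELINE:
            x = grp[v].to_numpy(dtype=float)
            med_u, lo_u, hi_u = (np.quantile(x, q, method="inverted_cdf") for q in (0.5, 0.25, 0.75))
            med_w, lo_w, hi_w = (_weighted_quantile(x, w, q) for q in (0.5, 0.25, 0.75))
            rows.append({
                "strategy": s, "variable": v,
                "unweighted": f"{med_u:g} [{lo_u:g}, {hi_u:g}]",
                "weighted": f"{med_w:g} [{lo_w:g}, {hi_w:g}]",
            })
        for v in BINARY_BASELINE:
            x = grp[v].to_numpy(dtype=float)
            rows.append({
                "strategy": s, "variable": f"{v} (%)",
                "unweighted": round(100.0 * x.mean(), 1),
                "weighted": round(100.0 * float(np.average(x, weights=w)), 1),
            })
        if "referral_site" in grp.columns and grp["referral_site"].notna().any():
            for lev in sorted(grp["referral_site"].dropna().unique()):
                x = (grp["referral_site"] == lev).to_numpy(dtype=float)
                rows.append({
                    "strategy": s, "variable": f"referral_site={lev} (%)",
                    "unweighted": round(100.0 * x.mean(), 1),
                    "weighted": round(100.0 * float(np.average(x, weights=w)), 1),
                })
    return pd.DataFrame(rows)


@dataclass
class EffectReport:
    """Point estimates (and optional bootstrap bands) of the emulation."""

    curves: pd.DataFrame  # strategy, day, cumulative_incidence[, lo, hi]
    risk_difference: pd.DataFrame  # day, rd[, lo, hi]; first vs last strategy
    mean_ventilator_days: dict  # per strategy, plus "difference"
    selected_days: pd.DataFrame
    reference: str = ""

    def to_dict(self) -> dict:
        return {
            "reference_strategy": self.reference,
            "curves": self.curves.to_dict(orient="list"),
            "risk_difference": self.risk_difference.to_dict(orient="list"),
            "mean_ventilator_days": self.mean_ventilator_days,
            "selected_days": self.selected_days.to_dict(orient="list"),
        }

    def to_json(self, path=None, indent=2):
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _effect_report(curves: pd.DataFrame, strategies: list[str], horizon: int,
                   selected_days=SELECTED_DAYS) -> EffectReport:
    wide = curves.pivot(index="day", columns="strategy", values="cumulative_incidence")
    first, ref = strategies[0], strategies[-1]
    rd = (wide[first] - wide[ref]).rename("rd").reset_index()
    mvd = {s: mean_ventilator_days(wide[s].to_numpy(), horizon) for s in strategies}
    mvd["difference"] = mvd[first] - mvd[ref]
    sel = []
    for d in selected_days:
        row = {"day": d}
        for s in strategies:
            row[f"ci_{s}_pct"] = round(100.0 * float(wide.loc[d, s]), 1)
        row["rd_pct"] = round(100.0 * float(wide.loc[d, first] - wide.loc[d, ref]), 1)
        sel.append(row)
    return EffectReport(
        curves=curves,
        risk_difference=rd,
        mean_ventilator_days=mvd,
        selected_days=pd.DataFrame(sel),
        reference=ref,
    )


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    """Array views of the eligible cohort for the fast estimation path."""

    subjects: pd.DataFrame
    X_cov: np.ndarray
    cov_names: list[str]
    int_day: np.ndarray
    outcome: np.ndarray
    death: np.ndarray
    ltfu: np.ndarray
    ws: np.ndarray  # (n_strategies, n)
    we: np.ndarray
    strategies: list[str]
    horizon: int
    max_day: int


class CloneCensorWeight(BaseEstimator):
    """Clone--censor--weight estimator of a treatment-timing contrast.

    Each eligible subject contributes one clone per strategy; clones are
    artificially censored at protocol deviation; inverse-probability weights
    from a pooled-logistic treatment-initiation model undo the selection the
    censoring induces; a weighted pooled-logistic outcome model yields
    per-strategy cumulative-incidence curves of successful extubation.

    Parameters
    ----------
    strategies : sequence of StrategyDef, default early (days 0-4 from
        referral) vs. late (days 5-14).
    covariates : adjustment set of the initiation model; default is birth
        weight, gestational age, age at referral, sex, referral year and
        prior pharmacotherapy.
    time_spec : "cubic" (default) or "saturated" time terms of the outcome
        model.
    truncation_pct : weight-truncation percentile within (strategy, day)
        strata; ``None`` disables truncation.
    stabilized : use stabilised weights (covariate-free numerator model).
    competing : "total" (deaths carried as ventilated through follow-up) or
        "cde" (controlled direct effect; censor at death).
    weighted : set False for the naive unweighted clone estimator (used to
        demonstrate the selection bias the weights remove).
    screen_eligibility : apply the trial eligibility criteria to the input
        registry before analysis.

    Attributes (after :meth:`fit`)
    ------------------------------
    eligible_, exclusion_tally_, clones_, clone_log_, adherence_flow_,
    initiation_model_, weight_table_, person_days_, outcome_model_,
    risk_curves_, effect_report_, baseline_table_.
    """

    def __init__(
        self,
        strategies: Sequence[StrategyDef] = DEFAULT_STRATEGIES,
        covariates: Optional[Sequence[str]] = None,
        time_spec: str = "cubic",
        truncation_pct: Optional[float] = None,
        stabilized: bool = False,
        competing: str = "total",
        horizon: int = 45,
        weighted: bool = True,
        screen_eligibility: bool = True,
        selected_days: Sequence[int] = SELECTED_DAYS,
    ):
        self.strategies = strategies
        self.covariates = covariates
        self.time_spec = time_spec
        self.truncation_pct = truncation_pct
        self.stabilized = stabilized
        self.competing = competing
        self.horizon = horizon
        self.weighted = weighted
        self.screen_eligibility = screen_eligibility
        self.selected_days = selected_days

    # -- public API ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "CloneCensorWeight":
        """Run the full emulation on a registry frame (one row per subject)."""
        df = X
        if self.screen_eligibility:
            df, self.exclusion_tally_ = cohort.apply_eligibility(df)
        else:
            self.exclusion_tally_ = {"n_screened": len(df), "n_eligible": len(df)}
        if "outcome_day" not in df.columns:
            df = cohort.add_outcome_days(df, self.horizon)
        self.eligible_ = df

        self.clones_, self.clone_log_ = make_clones(df, self.strategies, self.horizon)
        self.adherence_flow_ = adherence_flow(self.clones_)
        strat_names = [s.name for s in self.strategies]

        covs = list(self.covariates) if self.covariates is not None else list(
            cohort.DEFAULT_ADJUSTMENT_SET
        )
        max_day = int(self.clones_["window_end_referral"].max())
        base = self.clones_.drop_duplicates("subject_id")
        if self.weighted:
            self.initiation_model_ = ipw.fit_initiation_model(base, covs, max_day)
            numerator = ipw.fit_initiation_model(base, [], max_day) if self.stabilized else None
            self.weight_table_ = ipw.compute_weights(
                self.clones_,
                self.initiation_model_,
                numerator_model=numerator,
                truncation_pct=self.truncation_pct,
                horizon=self.horizon,
            )
        else:
            self.initiation_model_ = None
            self.weight_table_ = None

        self.person_days_ = expand_person_days(self.clones_, self.horizon, self.competing)
        if self.weight_table_ is not None:
            merged = self.person_days_.merge(
                self.weight_table_[["clone_id", "day", "weight_used"]],
                on=["clone_id", "day"],
                how="left",
            )
            w = merged["weight_used"].fillna(1.0).to_numpy()
        else:
            w = np.ones(len(self.person_days_))
        self.person_days_ = self.person_days_.assign(weight=w)

        self.outcome_model_ = fit_outcome_model(
            self.person_days_, w, self.time_spec, strat_names, self.horizon
        )
        self.risk_curves_ = risk_curves(self.outcome_model_)
        self.effect_report_ = _effect_report(
            self.risk_curves_, strat_names, self.horizon, tuple(self.selected_days)
        )
        if self.weight_table_ is not None:
            self.baseline_table_ = baseline_table(self.clones_, self.weight_table_, self.horizon)
        else:
            self.baseline_table_ = None
        return self

    def predict_cumulative_incidence(self, days=None) -> pd.DataFrame:
        """Fitted CI(t) per strategy, optionally restricted to given days."""
        if not hasattr(self, "risk_curves_"):
            raise RuntimeError("estimator is not fitted")
        curves = self.risk_curves_
        if days is not None:
            curves = curves[curves["day"].isin(list(days))].reset_index(drop=True)
        return curves

    # -- fast array path (shared with the bootstrap) ------------------------

    def prepare(self, X: pd.DataFrame) -> _Prepared:
        """Precompute per-subject arrays so replicates can be fitted quickly."""
        df = X
        if self.screen_eligibility:
            df, _ = cohort.apply_eligibility(df)
        if "outcome_day" not in df.columns:
            df = cohort.add_outcome_days(df, self.horizon)
        # apply the same baseline-compatibility exclusions as make_clones
        age = df["age_at_referral_days"].to_numpy(dtype=int)
        keep = np.ones(len(df), dtype=bool)
        for s in self.strategies:
            if s.max_age_at_referral is not None:
                keep &= age <= s.max_age_at_referral
            _, we = s.window_on_referral_clock(age)
            keep &= we >= 0
        df = df.loc[keep].reset_index(drop=True)

        covs = list(self.covariates) if self.covariates is not None else list(
            cohort.DEFAULT_ADJUSTMENT_SET
        )
        X_cov, cov_names = ipw.covariate_matrix(df, covs) if self.weighted else (
            np.empty((len(df), 0)), [])
        n = len(df)
        age = df["age_at_referral_days"].to_numpy(dtype=int)
        ws = np.empty((len(self.strategies), n), dtype=int)
        we = np.empty((len(self.strategies), n), dtype=int)
        for j, s in enumerate(self.strategies):
            ws[j], we[j] = s.window_on_referral_clock(age)
            ws[j] = np.maximum(ws[j], 0)
        return _Prepared(
            subjects=df,
            X_cov=X_cov,
            cov_names=cov_names,
            int_day=_as_sentinel(df["intervention_day"], n),
            outcome=_as_sentinel(df["outcome_day"], n),
            death=_as_sentinel(df["death_day"], n),
            ltfu=_as_sentinel(df["ltfu_day"], n),
            ws=ws,
            we=we,
            strategies=[s.name for s in self.strategies],
            horizon=self.horizon,
            max_day=int(we.max()),
        )

    def estimate_curves(self, prep: _Prepared, idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Cumulative-incidence matrix (n_strategies, horizon+1) for a
        (re)sampled cohort given by subject indices ``idx``."""
        from .clones import _terminal_arrays

        if idx is None:
            idx = np.arange(len(prep.int_day))
        int_day = prep.int_day[idx]
        outcome = prep.outcome[idx]
        death = prep.death[idx]
        ltfu = prep.ltfu[idx]
        X_cov = prep.X_cov[idx] if prep.X_cov.shape[1] else prep.X_cov[idx, :]
        horizon = prep.horizon

        if self.weighted:
            model = ipw._fit_initiation(
                X_cov, prep.cov_names, [], int_day, outcome, death, ltfu, prep.max_day
            )
            H = model.hazard_matrix(X_cov)
            H0 = None
            if self.stabilized:
                m0 = ipw._fit_initiation(
                    np.empty((len(idx), 0)), [], [], int_day, outcome, death, ltfu, prep.max_day
                )
                H0 = m0.hazard_matrix(np.empty((len(idx), 0)))
        else:
            H = H0 = None

        days_all = []
        strat_all = []
        event_all = []
        weight_all = []
        for j in range(len(prep.strategies)):
            ws = prep.ws[j][idx]
            we = prep.we[j][idx]
            from .clones import _deviation_days_vec

            dev = _deviation_days_vec(int_day, outcome, death, ltfu, ws, we)
            T, is_event, is_art, is_admin, term_dead = _terminal_arrays(
                outcome, dev, ltfu, death, horizon, self.competing
            )
            lengths = T + 1
            nrows = int(lengths.sum())
            ci = np.repeat(np.arange(len(T)), lengths)
            starts = np.cumsum(lengths) - lengths
            day = np.arange(nrows) - np.repeat(starts, lengths)
            ends = np.cumsum(lengths) - 1
            event = np.zeros(nrows, dtype=np.int8)
            event[ends[is_event]] = 1
            fit_mask = np.ones(nrows, dtype=bool)
            fit_mask[ends[is_art]] = False
            fit_mask[ends[term_dead]] = False

            if self.weighted:
                W, SW = ipw._weight_profiles(
                    int_day, outcome, death, ltfu, ws, we, H, horizon, H0
                )
                prof = SW if (self.stabilized and SW is not None) else W
                w_rows = prof[ci, day]
                if self.truncation_pct is not None:
                    w_rows, _ = ipw.truncate_by_day(day[fit_mask], w_rows[fit_mask],
                                                    self.truncation_pct)
                    day = day[fit_mask]
                    event = event[fit_mask]
                    fit_mask = np.ones(len(day), dtype=bool)
                    w_use = w_rows
                else:
                    w_use = w_rows[fit_mask]
                    day = day[fit_mask]
                    event = event[fit_mask]
                    fit_mask = np.ones(len(day), dtype=bool)
            else:
                day = day[fit_mask]
                event = event[fit_mask]
                w_use = np.ones(len(day))

            days_all.append(day)
            strat_all.append(np.full(len(day), j))
            event_all.append(event)
            weight_all.append(w_use)

        model = _fit_outcome_arrays(
            np.concatenate(days_all),
            np.concatenate(strat_all),
            np.concatenate(event_all),
            np.concatenate(weight_all),
            prep.strategies,
            horizon,
            self.time_spec,
        )
        out = np.empty((len(prep.strategies), horizon + 1))
        for j, s in enumerate(prep.strategies):
            out[j] = 1.0 - np.cumprod(1.0 - model.hazard(j))
        return out


def run_cde_variant(registry: pd.DataFrame, **params) -> CloneCensorWeight:
    """Sensitivity analysis 1: controlled direct effect (censor at death)."""
    params.setdefault("competing", "cde")
    return CloneCensorWeight(**params).fit(registry)


def run_covariate_variant(
    registry: pd.DataFrame, extra_covariates: Sequence[str] = ("referral_site",), **params
) -> CloneCensorWeight:
    """Sensitivity analysis 2: augment the initiation-model adjustment set."""
    covs = list(params.pop("covariates", cohort.DEFAULT_ADJUSTMENT_SET))
    for c in extra_covariates:
        if c not in registry.columns:
            raise cohort.SchemaError(f"extra covariate column {c!r} not in registry")
        if c not in covs:
            covs.append(c)
    return CloneCensorWeight(covariates=covs, **params).fit(registry)
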