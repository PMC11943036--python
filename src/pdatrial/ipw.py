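"""Treatment-initiation model and inverse-probability-of-adherence weights.

The initiation model is a pooled (discrete-time) logistic hazard of
undergoing definitive closure on day t given no closure through day t-1,
fitted on subject-days at risk of initiation over the grace periods, adjusted
for the baseline covariates.  Time enters as per-day indicator strata, pooled
greedily so that every stratum contains at least one initiation and one
non-initiation (the documented fallback that prevents separation).

Weights undo the artificial censoring of the clone--censor--weight design
under the deadline scheme.  For a clone whose window on the referral clock is
[ws, we]:

* each day k < ws on which its subject is still untreated multiplies the
  weight by 1 / (1 - h(k|L))  (remaining uncensored requires *not* initiating);
* days inside the window contribute 1;
* a clone reaching the deadline day we untreated is kept only if closure
  happens that day, contributing 1 / h(we|L); otherwise it is censored there.

Weights are frozen once the window is resolved.  The day-k factor applies to
rows that pass through day k without the outcome; an event-day row carries
the cumulative weight through k-1, because the outcome is ascertained before
the within-day censoring opportunity.  On days after death (total-effect
carry-forward) no censoring can occur and factors are 1.

Stabilised weights multiply by the analogous probabilities from a
covariate-free (time-only) initiation model.  Truncation caps weights at a
percentile computed within (strategy, day) strata, so that the structurally
large boundary-day weights of the deadline scheme are not clipped wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import glm
from .clones import StrategyDef, DEFAULT_STRATEGIES, _as_sentinel, _terminal_days, _NEVER

__all__ = [
    "InitiationModel",
    "PositivityError",
    "fit_initiation_model",
    "compute_weights",
    "covariate_matrix",
]

_EPS = 1e-12


class PositivityError(RuntimeError):
    """A needed initiation probability is numerically 0 or 1."""


def covariate_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Build a numeric covariate matrix (no intercept) from registry columns.

    Categorical columns (``referral_site`` or any non-numeric column) are
    expanded into indicator columns, dropping the first level.
    """
    cols = []
    names = []
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"covariate column {c!r} not in registry")
        s = df[c]
        if s.dtype == object or str(s.dtype) == "category":
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _pool_day_bins(day: np.ndarray, y: np.ndarray, max_day: int) -> np.ndarray:
    """Greedy pooling of day strata so each bin has >= 1 event and non-event.

    Returns ``bin_of_day`` (length max_day+1).  Days beyond the data are
    assigned to the last bin.  Raises if there are no initiations at all.
    """
    events = np.bincount(day[y == 1], minlength=max_day + 1)
    totals = np.bincount(day, minlength=max_day + 1)
    if events.sum() == 0:
        raise glm.SeparationError("no treatment initiations in the at-risk person-days")
    bin_of_day = np.zeros(max_day + 1, dtype=int)
    b = 0
    ev = nonev = 0
    for d in range(max_day + 1):
        bin_of_day[d] = b
        ev += events[d]
        nonev += totals[d] - events[d]
        if ev >= 1 and nonev >= 1 and d < max_day:
            b += 1
            ev = nonev = 0
    if ev == 0 or nonev == 0:
        # fold an incomplete trailing bin into the previous one
        last = bin_of_day.max()
        if last > 0:
            bin_of_day[bin_of_day == last] = last - 1
    # renumber densely
    _, bin_of_day = np.unique(bin_of_day, return_inverse=True)
    return bin_of_day


@dataclass
class InitiationModel:
    """Fitted pooled-logistic hazard of treatment initiation."""

    beta: np.ndarray
    feature_names: list[str]
    bin_of_day: np.ndarray  # day -> pooled time stratum
    covariates: list[str]  # registry columns the model adjusts for
    max_day: int

    @classmethod
    def constant(cls, hazard: float, max_day: int = 14) -> "InitiationModel":
        """Model with a single constant daily hazard (used for injection tests)."""
        if not 0 < hazard < 1:
            raise ValueError("hazard must be in (0, 1)")
        logit = float(np.log(hazard / (1 - hazard)))
        return cls(
            beta=np.array([logit]),
            feature_names=["intercept"],
            bin_of_day=np.zeros(max_day + 1, dtype=int),
            covariates=[],
            max_day=max_day,
        )

    @property
    def n_bins(self) -> int:
        return int(self.bin_of_day.max()) + 1

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.feature_names, map(float, self.beta)))

    def hazard_matrix(self, X_cov: np.ndarray) -> np.ndarray:
        """Predicted daily initiation hazard, shape (n, max_day+1)."""
        n = X_cov.shape[0]
        nb = self.n_bins
        b0 = self.beta[0]
        bin_eff = np.zeros(self.max_day + 1)
        for b in range(1, nb):
            bin_eff[self.bin_of_day == b] = self.beta[b]
        eta_cov = X_cov @ self.beta[nb:] if X_cov.shape[1] else np.zeros(n)
        eta = b0 + bin_eff[None, :] + eta_cov[:, None]
        return glm.sigmoid(eta)


def _initiation_risk_rows(int_day, outcome, death, ltfu, max_day):
    """Subject-day rows at risk of initiation: (subject index, day, y).

    A subject contributes day k while untreated through k-1, with k capped at
    ``max_day`` and strictly before the first of outcome/death/loss to
    follow-up (on the day of another event no initiation can occur under the
    one-transition-per-day bookkeeping).
    """
    stop = np.minimum(np.minimum(outcome, death), ltfu)
    K = np.minimum(np.minimum(int_day, stop - 1), max_day)
    K = np.maximum(K, -1)
    lengths = K + 1
    nrows = int(lengths.sum())
    subj = np.repeat(np.arange(len(K)), lengths)
    starts = np.cumsum(lengths) - lengths
    day = np.arange(nrows) - np.repeat(starts, lengths)
    y = (day == int_day[subj]).astype(float)
    return subj, day, y


def fit_initiation_model(
    subjects: pd.DataFrame,
    covariates: Sequence[str],
    max_day: int = 14,
) -> InitiationModel:
    """Fit the grace-period treatment model on eligible subjects.

    ``subjects`` must carry ``outcome_day`` (see
    :func:`pdatrial.cohort.add_outcome_days`).  Pass ``covariates=[]`` for the
    covariate-free numerator model of stabilised weights.
    """
    n = len(subjects)
    int_day = _as_sentinel(subjects["intervention_day"], n)
    outcome = _as_sentinel(subjects["outcome_day"], n)
    death = _as_sentinel(subjects["death_day"], n)
    ltfu = _as_sentinel(subjects["ltfu_day"], n)
    X_cov, names = covariate_matrix(subjects, covariates)
    return _fit_initiation(X_cov, names, list(covariates), int_day, outcome, death, ltfu, max_day)


def _fit_initiation(X_cov, cov_names, covariates, int_day, outcome, death, ltfu, max_day):
    subj, day, y = _initiation_risk_rows(int_day, outcome, death, ltfu, max_day)
    if len(day) == 0:
        raise ValueError("no subject-days at risk of initiation")
    bin_of_day = _pool_day_bins(day, y.astype(int), max_day)
    nb = int(bin_of_day.max()) + 1
    X = np.empty((len(day), 1 + (nb - 1) + X_cov.shape[1]))
    X[:, 0] = 1.0
    bins = bin_of_day[day]
    for b in range(1, nb):
        X[:, b] = (bins == b).astype(float)
    if X_cov.shape[1]:
        X[:, nb:] = X_cov[subj]
    feature_names = ["intercept"] + [f"day_bin_{b}" for b in range(1, nb)] + cov_names
    beta = glm.fit_logistic(X, y, column_names=feature_names)
    return InitiationModel(
        beta=beta,
        feature_names=feature_names,
        bin_of_day=bin_of_day,
        covariates=covariates,
        max_day=max_day,
    )


def _weight_profiles(
    int_day: np.ndarray,
    outcome: np.ndarray,
    death: np.ndarray,
    ltfu: np.ndarray,
    ws: np.ndarray,
    we: np.ndarray,
    H: np.ndarray,
    horizon: int,
    H0: Optional[np.ndarray] = None,
):
    """Per-clone cumulative weight profiles, shape (m, horizon+1).

    ``H`` is the per-subject hazard matrix (m, >= max(we)+1).  Returns
    (W, SW); SW is None unless a numerator hazard vector/matrix ``H0`` is
    given.  Raises :class:`PositivityError` if a needed hazard is 0 or 1.
    """
    m = len(int_day)
    days = np.arange(horizon + 1)[None, :]
    stop = np.minimum(np.minimum(outcome, death), ltfu)[:, None]
    untreated = days <= int_day[:, None]
    in_obs = days < stop
    Hp = np.ones((m, horizon + 1)) * 0.5
    Hp[:, : H.shape[1]] = H[:, : horizon + 1]

    F = np.ones((m, horizon + 1))
    pre = (days < ws[:, None]) & untreated & in_obs & (days != int_day[:, None])
    if pre.any():
        h = Hp[pre]
        if np.any(h >= 1 - _EPS):
            bad = np.unique(np.where(pre & (Hp >= 1 - _EPS))[1])
            raise PositivityError(
                f"initiation probability numerically 1 on day(s) {bad.tolist()}; "
                "no subject could remain untreated"
            )
        F[pre] = 1.0 / (1.0 - h)
    deadline = (days == we[:, None]) & (days == int_day[:, None]) & in_obs
    if deadline.any():
        h = Hp[deadline]
        if np.any(h <= _EPS):
            bad = np.unique(np.where(deadline & (Hp <= _EPS))[1])
            raise PositivityError(
                f"initiation probability numerically 0 on deadline day(s) {bad.tolist()}"
            )
        F[deadline] = 1.0 / h
    W = np.cumprod(F, axis=1)

    SW = None
    if H0 is not None:
        H0p = np.ones((m, horizon + 1)) * 0.5
        H0m = H0 if H0.ndim == 2 else np.broadcast_to(H0[None, :], (m, H0.shape[0]))
        H0p[:, : H0m.shape[1]] = H0m[:, : horizon + 1]
        # Numerator factors on pre-window days only, applied to *every* row
        # regardless of the clone's own history, so the cumulative factor is a
        # deterministic function of (strategy, day).  Being a common per-day
        # scalar within each (strategy, day) stratum, stabilisation leaves
        # saturated-in-time point estimates exactly unchanged.  A per-clone
        # numerator (e.g. one including the deadline-day factor) would
        # reweight deadline initiators against within-window initiators and
        # bias the marginal hazard.
        G = np.ones((m, horizon + 1))
        pre_num = days < ws[:, None]
        G[pre_num] = 1.0 - H0p[pre_num]
        SW = W * np.cumprod(G, axis=1)
    return W, SW


def truncate_by_day(day: np.ndarray, w: np.ndarray, pct: float):
    """Cap weights at the ``pct`` percentile within each day stratum."""
    capped = w.copy()
    flag = np.zeros(len(w), dtype=bool)
    for d in np.unique(day):
        sel = day == d
        cap = np.percentile(w[sel], pct)
        over = sel & (w > cap)
        capped[over] = cap
        flag |= over
    return capped, flag


def compute_weights(
    clones: pd.DataFrame,
    model: InitiationModel,
    numerator_model: Optional[InitiationModel] = None,
    truncation_pct: Optional[float] = None,
    horizon: int = 45,
) -> pd.DataFrame:
    """Per-clone-day weight table for the clone--censor--weight analysis.

    Returns one row per clone per follow-up day (same rows as
    :func:`pdatrial.clones.expand_person_days`) with columns ``weight``
    (unstabilised, untruncated), ``stabilized_weight`` (if a numerator model
    is given), ``weight_used`` (after truncation within strategy-day strata)
    and ``truncated``.
    """
    m = len(clones)
    int_day = _as_sentinel(clones["intervention_day"], m)
    outcome = _as_sentinel(clones["outcome_day"], m)
    death = _as_sentinel(clones["death_day"], m)
    ltfu = _as_sentinel(clones["ltfu_day"], m)
    ws = clones["window_start_referral"].to_numpy(dtype=int)
    we = clones["window_end_referral"].to_numpy(dtype=int)

    X_cov, _ = covariate_matrix(clones, model.covariates)
    H = model.hazard_matrix(X_cov)
    H0 = None
    if numerator_model is not None:
        X0, _ = covariate_matrix(clones, numerator_model.covariates)
        H0 = numerator_model.hazard_matrix(X0)
    W, SW = _weight_profiles(int_day, outcome, death, ltfu, ws, we, H, horizon, H0)

    T, is_event, *_ = _terminal_days(clones, horizon, "total")
    # event-day rows carry the weight through the previous day
    lengths = T + 1
    nrows = int(lengths.sum())
    idx = np.repeat(np.arange(m), lengths)
    starts = np.cumsum(lengths) - lengths
    day = np.arange(nrows) - np.repeat(starts, lengths)
    w_rows = W[idx, day]
    ends = np.cumsum(lengths) - 1
    ev_rows = ends[is_event & (T > 0)]
    w_rows[ev_rows] = W[idx[ev_rows], day[ev_rows] - 1]

    table = pd.DataFrame(
        {
            "clone_id": clones["clone_id"].to_numpy()[idx],
            "strategy": clones["strategy"].to_numpy()[idx],
            "day": day,
            "weight": w_rows,
        }
    )
    if SW is not None:
        sw_rows = SW[idx, day]
        sw_rows[ev_rows] = SW[idx[ev_rows], day[ev_rows] - 1]
        table["stabilized_weight"] = sw_rows

    base = table["stabilized_weight"] if SW is not None else table["weight"]
    if truncation_pct is not None:
        used = np.empty(nrows)
        flag = np.zeros(nrows, dtype=bool)
        for s in table["strategy"].unique():
            sel = (table["strategy"] == s).to_numpy()
            capped, f = truncate_by_day(day[sel], base.to_numpy()[sel], truncation_pct)
            used[sel] = capped
            flag[sel] = f
        table["weight_used"] = used
        table["truncated"] = flag.astype(np.int8)
    else:
        table["weight_used"] = base.to_numpy()
        table["truncated"] = np.int8(0)
    return table
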