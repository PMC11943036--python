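"""Clone expansion, protocol-deviation censoring and the person-day table.

Each eligible infant contributes one clone per treatment-timing strategy.  A
clone is artificially censored the day its subject's data deviate from the
assigned strategy: at the intervention day if closure happens before the
window opens, or at the final window day (the grace-period deadline) if the
subject is still untreated then.  The outcome, death, or loss to follow-up
occurring on or before the would-be deviation day cancels the deviation
(events take precedence over censoring; death before the deadline precludes
the outcome rather than constituting a deviation).

Same-day precedence is fixed everywhere as: event > artificial censoring >
administrative censoring.  Under the total-effect convention, death does not
terminate a clone's rows: dead clones persist, event-free, through the end of
follow-up.  Under the controlled-direct-effect variant, rows stop at death,
with the death-day row flagged as administratively censored and not at risk
(within a day, death is evaluated before the extubation attempt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrategyDef",
    "EARLY",
    "LATE",
    "DEFAULT_STRATEGIES",
    "make_clones",
    "deviation_day",
    "expand_person_days",
    "adherence_flow",
]

_NEVER = 10_000  # sentinel well past any horizon


@dataclass(frozen=True)
class StrategyDef:
    """A treatment-timing regime: undergo closure within a day window.

    ``axis`` is the clock of the window: ``referral_days`` (days since
    referral, the main analysis) or ``age_days`` (days since birth, the
    age-based sensitivity analysis).  Windows are closed intervals of whole
    days; treatment strictly before ``window_start`` is a deviation.  For the
    age axis an eligibility cap on age at referral may be attached.
    """

    name: str
    axis: str = "referral_days"
    window_start: int = 0
    window_end: int = 4
    max_age_at_referral: Optional[int] = None

    def __post_init__(self):
        if self.axis not in ("referral_days", "age_days"):
            raise ValueError(f"unknown strategy axis {self.axis!r}")
        if not (0 <= self.window_start <= self.window_end):
            raise ValueError(
                f"invalid window [{self.window_start}, {self.window_end}] for {self.name!r}"
            )

    def window_on_referral_clock(self, age_at_referral):
        """Map the window onto the referral clock (vectorised over ages).

        For the age axis the bounds are shifted by age at referral; the start
        is clipped at day 0.  The end may be negative, meaning the window
        closed before referral (such subjects cannot follow the strategy).
        """
        age = np.asarray(age_at_referral)
        if self.axis == "referral_days":
            ws = np.full(age.shape, self.window_start, dtype=int)
            we = np.full(age.shape, self.window_end, dtype=int)
        else:
            ws = np.maximum(self.window_start - age, 0).astype(int)
            we = (self.window_end - age).astype(int)
        return ws, we


EARLY = StrategyDef("early", "referral_days", 0, 4)
LATE = StrategyDef("late", "referral_days", 5, 14)
DEFAULT_STRATEGIES = (EARLY, LATE)


def deviation_day(
    intervention_day: Optional[int],
    outcome_day: Optional[int],
    death_day: Optional[int],
    ltfu_day: Optional[int],
    window_start: int,
    window_end: int,
) -> Optional[int]:
    """Day a clone deviates from its strategy, or ``None`` if adherent.

    The window is on the referral clock.  Deviation is (a) the intervention
    day when closure precedes the window, or (b) the grace-period deadline
    (``window_end``) when the subject is still untreated there.  The outcome
    or death on or before that day, or loss to follow-up strictly before it,
    cancels the deviation.
    """
    iday = _NEVER if intervention_day is None else int(intervention_day)
    if iday < window_start:
        dev = iday
    elif iday > window_end:
        dev = window_end
    else:
        return None
    if outcome_day is not None and outcome_day <= dev:
        return None
    if death_day is not None and death_day <= dev:
        return None
    if ltfu_day is not None and ltfu_day < dev:
        return None
    return int(dev)


def _as_sentinel(series_or_array, n) -> np.ndarray:
    """Nullable ints to plain ints with _NEVER for missing."""
    arr = pd.array(series_or_array, dtype="Int64")
    out = np.full(n, _NEVER, dtype=int)
    mask = ~pd.isna(arr)
    out[np.asarray(mask)] = np.asarray(arr[mask], dtype=int)
    return out


def _deviation_days_vec(int_day, outcome, death, ltfu, ws, we) -> np.ndarray:
    """Vectorised deviation day; _NEVER encodes adherent."""
    dev = np.where(int_day < ws, int_day, np.where(int_day > we, we, _NEVER))
    cancelled = (outcome <= dev) | (death <= dev) | (ltfu < dev)
    return np.where(cancelled, _NEVER, dev)


def make_clones(
    eligible: pd.DataFrame,
    strategies: Sequence[StrategyDef] = DEFAULT_STRATEGIES,
    horizon: int = 45,
) -> tuple[pd.DataFrame, dict]:
    """Expand eligible subjects into one clone per strategy.

    ``eligible`` must carry an ``outcome_day`` column (see
    :func:`pdatrial.cohort.add_outcome_days`).  Subjects incompatible with the
    strategy set at baseline -- beyond an age cap, or with an age-axis window
    already closed at referral -- are excluded from the whole analysis with a
    logged reason.  Returns the clone table (one row per clone, carrying the
    subject's covariates, referral-clock window and deviation day) and the
    exclusion log.
    """
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {names}")
    if "outcome_day" not in eligible.columns:
        raise ValueError("eligible frame lacks 'outcome_day'; run add_outcome_days first")

    n = len(eligible)
    age = eligible["age_at_referral_days"].to_numpy(dtype=int)
    keep = np.ones(n, dtype=bool)
    log = {"age_cap": 0, "window_elapsed": 0}
    for s in strategies:
        if s.max_age_at_referral is not None:
            over = age > s.max_age_at_referral
            log["age_cap"] += int((over & keep).sum())
            keep &= ~over
        _, we = s.window_on_referral_clock(age)
        gone = we < 0
        log["window_elapsed"] += int((gone & keep).sum())
        keep &= ~gone
    base = eligible.loc[keep].reset_index(drop=True)
    m = len(base)

    int_day = _as_sentinel(base["intervention_day"], m)
    outcome = _as_sentinel(base["outcome_day"], m)
    death = _as_sentinel(base["death_day"], m)
    ltfu = _as_sentinel(base["ltfu_day"], m)
    age_k = base["age_at_referral_days"].to_numpy(dtype=int)

    frames = []
    for s in strategies:
        ws, we = s.window_on_referral_clock(age_k)
        dev = _deviation_days_vec(int_day, outcome, death, ltfu, ws, we)
        f = base.copy()
        f.insert(0, "clone_id", [f"{sid}:{s.name}" for sid in base["subject_id"]])
        f.insert(1, "strategy", s.name)
        f["window_start_referral"] = ws
        f["window_end_referral"] = we
        f["deviation_day"] = pd.array(np.where(dev == _NEVER, pd.NA, dev), dtype="Int64")
        frames.append(f)
    clones = pd.concat(frames, ignore_index=True)
    log["n_subjects"] = m
    log["n_clones"] = len(clones)
    return clones, log


def _terminal_arrays(outcome, dev, ltfu, death, horizon: int, competing: str):
    """Last row day and terminal flags per clone (array inputs, _NEVER = absent).

    Returns (T, is_event, is_artificial, is_admin, not_at_risk_terminal).
    """
    m = len(outcome)
    admin = np.minimum(ltfu, horizon)
    terminal_dead = np.zeros(m, dtype=bool)
    if competing == "cde":
        admin = np.minimum(admin, death)
    elif competing != "total":
        raise ValueError(f"competing must be 'total' or 'cde', got {competing!r}")

    T = np.minimum(np.minimum(outcome, dev), admin)
    # precedence at ties: event > artificial censor > administrative censor
    is_event = outcome == T
    is_artificial = ~is_event & (dev == T)
    is_admin = ~is_event & ~is_artificial
    if competing == "cde":
        # death-day row: emitted but not at risk (death precedes the
        # within-day extubation assessment)
        terminal_dead = is_admin & (death == T) & (ltfu > T)
    return T, is_event, is_artificial, is_admin, terminal_dead


def _terminal_days(clones: pd.DataFrame, horizon: int, competing: str):
    """Frame wrapper around :func:`_terminal_arrays`."""
    m = len(clones)
    outcome = _as_sentinel(clones["outcome_day"], m)
    dev = _as_sentinel(clones["deviation_day"], m)
    ltfu = _as_sentinel(clones["ltfu_day"], m)
    death = _as_sentinel(clones["death_day"], m)
    return _terminal_arrays(outcome, dev, ltfu, death, horizon, competing)


def expand_person_days(
    clones: pd.DataFrame,
    horizon: int = 45,
    competing: str = "total",
) -> pd.DataFrame:
    """Expand the clone table into one row per clone per follow-up day.

    Rows run from day 0 to the terminal day: the outcome day, the deviation
    day, the loss-to-follow-up day or the end of the horizon, whichever comes
    first (with the same-day precedence fixed in the module docstring).  Under
    ``competing="total"`` death does not terminate rows; under
    ``competing="cde"`` rows stop at the death day.

    The ``at_risk`` column marks rows that belong to the outcome risk set;
    it is 0 only for the not-at-risk death-day row of the CDE variant.
    Artificial-censoring rows are emitted (so row counts match a per-subject
    enumeration) but are excluded from model fitting downstream.
    """
    T, is_event, is_artificial, is_admin, terminal_dead = _terminal_days(
        clones, horizon, competing
    )
    lengths = T + 1
    nrows = int(lengths.sum())
    idx = np.repeat(np.arange(len(clones)), lengths)
    starts = np.cumsum(lengths) - lengths
    day = np.arange(nrows) - np.repeat(starts, lengths)
    ends = np.cumsum(lengths) - 1  # positions of terminal rows
    event = np.zeros(nrows, dtype=np.int8)
    artificial = np.zeros(nrows, dtype=np.int8)
    admin = np.zeros(nrows, dtype=np.int8)
    event[ends[is_event]] = 1
    artificial[ends[is_artificial]] = 1
    admin[ends[is_admin]] = 1
    at_risk = np.ones(nrows, dtype=np.int8)
    at_risk[ends[terminal_dead]] = 0

    m = len(clones)
    int_day = _as_sentinel(clones["intervention_day"], m)
    death = _as_sentinel(clones["death_day"], m)

    out = pd.DataFrame(
        {
            "clone_id": clones["clone_id"].to_numpy()[idx],
            "subject_id": clones["subject_id"].to_numpy()[idx],
            "strategy": clones["strategy"].to_numpy()[idx],
            "day": day,
            "treated_by_t": (int_day[idx] <= day).astype(np.int8),
            "at_risk": at_risk,
            "event": event,
            "artificial_censor": artificial,
            "admin_censor": admin,
            "dead_by_t": (death[idx] <= day).astype(np.int8),
        }
    )
    return out


def adherence_flow(clones: pd.DataFrame) -> dict:
    """Flowchart-style adherence counts: early/late/both/neither adherent.

    A subject is adherent to a strategy when its clone has no deviation day.
    Counts generalise to any number of strategies via per-strategy totals plus
    the both/neither decomposition over the first two.
    """
    piv = clones.pivot(index="subject_id", columns="strategy", values="deviation_day")
    adherent = piv.isna()
    flow = {f"adherent_{s}": int(adherent[s].sum()) for s in adherent.columns}
    cols = list(adherent.columns)
    if len(cols) >= 2:
        a, b = cols[0], cols[1]
        flow["adherent_both"] = int((adherent[a] & adherent[b]).sum())
        flow["adherent_neither"] = int((~adherent[a] & ~adherent[b]).sum())
    flow["n_subjects"] = int(len(adherent))
    return flow
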