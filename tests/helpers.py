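"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the clone bookkeeping with a plain day-by-day
loop and explicit conditionals, independent of the vectorised implementation
they are used to check.
"""

from __future__ import annotations


def referral_window(strategy, age):
    """Strategy window mapped onto the referral clock."""
    if strategy.axis == "age_days":
        ws = strategy.window_start - age
        we = strategy.window_end - age
    else:
        ws, we = strategy.window_start, strategy.window_end
    return max(ws, 0), we


def brute_deviation_day(sub: dict, ws: int, we: int):
    """Deviation day of one clone by direct application of the rules."""
    iday = sub.get("intervention_day")
    if iday is not None and iday < ws:
        dev = iday
    elif iday is None or iday > we:
        dev = we
    else:
        return None
    out = sub.get("outcome_day")
    death = sub.get("death_day")
    ltfu = sub.get("ltfu_day")
    if out is not None and out <= dev:
        return None
    if death is not None and death <= dev:
        return None
    if ltfu is not None and ltfu < dev:
        return None
    return dev


def brute_clone_rows(sub: dict, strategy, horizon: int = 45, competing: str = "total"):
    """Person-day rows for one clone, enumerated one day at a time.

    ``sub`` maps event names to days (``None`` = absent) and must include
    ``age_at_referral_days`` for age-axis strategies.  Returns a list of row
    dicts with the same flag columns as ``expand_person_days``.
    """
    ws, we = referral_window(strategy, sub.get("age_at_referral_days", 0))
    dev = brute_deviation_day(sub, ws, we)
    iday = sub.get("intervention_day")
    out = sub.get("outcome_day")
    death = sub.get("death_day")
    ltfu = sub.get("ltfu_day")

    rows = []
    for t in range(horizon + 1):
        row = {
            "day": t,
            "treated_by_t": int(iday is not None and iday <= t),
            "at_risk": 1,
            "event": 0,
            "artificial_censor": 0,
            "admin_censor": 0,
            "dead_by_t": int(death is not None and death <= t),
        }
        stop = False
        if out is not None and t == out:
            row["event"] = 1
            stop = True
        elif dev is not None and t == dev:
            row["artificial_censor"] = 1
            stop = True
        elif competing == "cde" and death is not None and t == death and (
            ltfu is None or ltfu > t
        ):
            row["admin_censor"] = 1
            row["at_risk"] = 0
            stop = True
        elif ltfu is not None and t == ltfu:
            row["admin_censor"] = 1
            stop = True
        elif t == horizon:
            row["admin_censor"] = 1
            stop = True
        rows.append(row)
        if stop:
            break
    return rows


def random_subject(rng, horizon: int = 45) -> dict:
    """A random, internally consistent event history for oracle checks."""
    iday = int(rng.integers(0, horizon + 6)) if rng.random() < 0.7 else None
    if iday is not None and iday > horizon:
        iday = None
    out = int(rng.integers(0, horizon + 1)) if rng.random() < 0.5 else None
    death = int(rng.integers(0, horizon + 11)) if rng.random() < 0.25 else None
    if death is not None and death > horizon:
        death = None
    ltfu = None
    if rng.random() < 0.25 and iday is not None:
        ltfu = int(rng.integers(iday + 1, horizon + 2))
        if ltfu > horizon:
            ltfu = None
    # enforce the registry invariants: nothing follows death; the outcome
    # precedes death and loss to follow-up; one transition per day
    if death is not None:
        if iday is not None and iday >= death:
            iday = None
        if ltfu is not None:
            ltfu = None
    if out is not None:
        if death is not None and out >= death:
            out = None
        elif ltfu is not None and out >= ltfu:
            out = None
    return {
        "intervention_day": iday,
        "outcome_day": out,
        "death_day": death,
        "ltfu_day": ltfu,
        "age_at_referral_days": int(rng.integers(1, 30)),
    }
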