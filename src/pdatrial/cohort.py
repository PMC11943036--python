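"""Registry data model, I/O, eligibility screening and outcome derivation.

The unit of analysis is one premature infant referred for definitive closure
of a patent ductus arteriosus (PDA).  All event days are integers on the
*referral clock*: day 0 is the day of referral, which is also time zero of
follow-up and the day eligibility is assessed.  Intervals are closed.

The registry is a plain CSV with one row per infant.  Extubation episodes are
encoded in a single column as ``day:reintubated`` pairs separated by
semicolons, e.g. ``"10:1;20:0"`` means an extubation on day 10 followed by
reintubation within seven days, then an extubation on day 20 that was not.
Missing event days are empty cells.  Unknown columns are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "SchemaError",
    "ValidationError",
    "COVARIATE_COLUMNS",
    "DEFAULT_ADJUSTMENT_SET",
    "FLAG_COLUMNS",
    "EVENT_COLUMNS",
    "MANDATORY_COLUMNS",
    "parse_episodes",
    "format_episodes",
    "read_registry",
    "write_registry",
    "validate_registry",
    "apply_eligibility",
    "derive_outcome_day",
    "add_outcome_days",
]


class SchemaError(ValueError):
    """The registry file does not match the documented column schema."""


class ValidationError(ValueError):
    """A registry row violates the event-day invariants."""


#: Baseline covariates carried by every subject.
COVARIATE_COLUMNS = [
    "gestational_age_weeks",
    "birth_weight_g",
    "age_at_referral_days",
    "sex",
    "referral_year",
    "prior_pharmacotherapy",
]

#: Adjustment set of the treatment-initiation model in the main analysis:
#: birth weight, gestational age, age at referral, sex, year of enrollment and
#: prior pharmacotherapy.  Referral site is added only in a sensitivity run.
DEFAULT_ADJUSTMENT_SET = list(COVARIATE_COLUMNS)

#: Eligibility flags (binary; 1 = condition present).
FLAG_COLUMNS = [
    "ventilated_at_referral",
    "complex_chd",
    "bidirectional_or_r2l_flow",
    "major_anomaly",
    "tracheostomy",
    "pharmacotherapy_contraindicated",
]

#: Integer event-day columns (empty cell = event absent).
EVENT_COLUMNS = ["intervention_day", "death_day", "ltfu_day"]

MANDATORY_COLUMNS = (
    ["subject_id"]
    + COVARIATE_COLUMNS
    + FLAG_COLUMNS
    + ["intervention_day", "extubation_episodes", "death_day", "ltfu_day"]
)

#: Optional categorical covariate used by sensitivity analysis 2.
OPTIONAL_COLUMNS = ["referral_site"]


@dataclass
class SubjectRecord:
    """One infant's baseline covariates and event history on the referral clock."""

    subject_id: str
    gestational_age_weeks: float
    birth_weight_g: float
    age_at_referral_days: int
    sex: int
    referral_year: int
    prior_pharmacotherapy: int
    ventilated_at_referral: int = 1
    complex_chd: int = 0
    bidirectional_or_r2l_flow: int = 0
    major_anomaly: int = 0
    tracheostomy: int = 0
    pharmacotherapy_contraindicated: int = 0
    referral_site: Optional[str] = None
    intervention_day: Optional[int] = None
    extubation_episodes: list[tuple[int, bool]] = field(default_factory=list)
    death_day: Optional[int] = None
    ltfu_day: Optional[int] = None

    def to_row(self) -> dict:
        row = {k: getattr(self, k) for k in MANDATORY_COLUMNS if k != "extubation_episodes"}
        row["extubation_episodes"] = format_episodes(self.extubation_episodes)
        if self.referral_site is not None:
            row["referral_site"] = self.referral_site
        return row

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        def _opt(v):
            return None if pd.isna(v) else int(v)

        return cls(
            subject_id=str(row["subject_id"]),
            gestational_age_weeks=float(row["gestational_age_weeks"]),
            birth_weight_g=float(row["birth_weight_g"]),
            age_at_referral_days=int(row["age_at_referral_days"]),
            sex=int(row["sex"]),
            referral_year=int(row["referral_year"]),
            prior_pharmacotherapy=int(row["prior_pharmacotherapy"]),
            ventilated_at_referral=int(row["ventilated_at_referral"]),
            complex_chd=int(row["complex_chd"]),
            bidirectional_or_r2l_flow=int(row["bidirectional_or_r2l_flow"]),
            major_anomaly=int(row["major_anomaly"]),
            tracheostomy=int(row["tracheostomy"]),
            pharmacotherapy_contraindicated=int(row["pharmacotherapy_contraindicated"]),
            referral_site=(str(row["referral_site"]) if "referral_site" in row and not pd.isna(row["referral_site"]) else None),
            intervention_day=_opt(row["intervention_day"]),
            extubation_episodes=parse_episodes(row["extubation_episodes"]),
            death_day=_opt(row["death_day"]),
            ltfu_day=_opt(row["ltfu_day"]),
        )


def parse_episodes(text) -> list[tuple[int, bool]]:
    """Parse the ``day:reintubated`` episode encoding into a list of tuples."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    episodes = []
    for part in text.split(";"):
        day_s, _, flag_s = part.partition(":")
        episodes.append((int(day_s), bool(int(flag_s or 0))))
    return episodes


def format_episodes(episodes: Iterable[tuple[int, bool]]) -> str:
    return ";".join(f"{int(d)}:{int(bool(r))}" for d, r in episodes)


def _coerce_event_days(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce event-day columns to nullable integers, naming the bad row."""
    for col in EVENT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise SchemaError(
                f"column {col!r}: cannot parse value {df[col].iloc[row]!r} as an "
                f"integer day (row {row})"
            )
        frac = vals.dropna() % 1
        if (frac != 0).any():
            row = int(vals.index.get_indexer([frac[frac != 0].index[0]])[0])
            raise SchemaError(f"column {col!r}: non-integer event day (row {row})")
        df[col] = vals.astype("Int64")
    return df


def read_registry(path, validate: bool = True) -> pd.DataFrame:
    """Read a registry CSV into a typed DataFrame (one row per subject).

    Lines starting with ``#`` (e.g. the seed comment written by the simulator)
    are ignored.  Raises :class:`SchemaError` for a missing mandatory column
    or an unparseable event day and :class:`ValidationError` if ``validate``
    and a row violates the event-day invariants.
    """
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry is missing mandatory column(s): {missing}")
    df = _coerce_event_days(df)
    df["extubation_episodes"] = df["extubation_episodes"].fillna("")
    if validate:
        validate_registry(df)
    return df


def write_registry(df: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write a registry CSV; records the generator seed as a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# pdatrial synthetic registry; seed={seed}\n")
        df.to_csv(fh, index=False, na_rep="")


def validate_registry(df: pd.DataFrame) -> None:
    """Check per-row event-day invariants.

    Event days must be non-negative; extubation episodes strictly increasing;
    no recorded event may occur after death.
    """
    for col in EVENT_COLUMNS:
        neg = df[col].dropna() < 0
        if neg.any():
            raise ValidationError(f"column {col!r}: negative event day (row {neg.idxmax()})")
    for idx, row in df.iterrows():
        eps = parse_episodes(row["extubation_episodes"])
        days = [d for d, _ in eps]
        if any(d < 0 for d in days):
            raise ValidationError(f"row {idx}: negative extubation day")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"row {idx}: extubation episodes not strictly increasing")
        death = row["death_day"]
        if not pd.isna(death):
            others = list(days)
            for col in ("intervention_day", "ltfu_day"):
                if not pd.isna(row[col]):
                    others.append(int(row[col]))
            if any(d > death for d in others):
                raise ValidationError(
                    f"row {idx}: event recorded after death_day={int(death)}"
                )


# Order in which exclusion reasons are tallied; each excluded subject is
# attributed to the first criterion it fails.
ELIGIBILITY_CRITERIA = [
    "missing_flags",
    "not_preterm_or_low_birth_weight",
    "not_ventilated_at_referral",
    "no_prior_pharmacotherapy",
    "complex_chd",
    "bidirectional_or_r2l_flow",
    "major_anomaly",
    "tracheostomy",
]


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Screen the registry against the trial eligibility criteria.

    Inclusion: born before 30 weeks of gestation *or* birth weight below
    1500 g; mechanically ventilated at referral; at least one prior course of
    PDA pharmacotherapy unless contraindicated.  Exclusion: complex congenital
    cardiac disease, bidirectional or right-to-left ductal flow, major
    congenital anomalies, tracheostomy.  A missing flag renders the subject
    ineligible (tallied under ``missing_flags``).

    Returns the eligible subset and an ordered exclusion tally (counts per
    criterion, first-failure attribution) suitable for a flowchart report.
    """
    tally = {k: 0 for k in ELIGIBILITY_CRITERIA}
    flags = df[FLAG_COLUMNS]
    missing = flags.isna().any(axis=1)

    preterm = (df["gestational_age_weeks"] < 30) | (df["birth_weight_g"] < 1500)
    ventilated = df["ventilated_at_referral"].fillna(0).astype(float) == 1
    pharm = (df["prior_pharmacotherapy"].fillna(0).astype(float) == 1) | (
        df["pharmacotherapy_contraindicated"].fillna(0).astype(float) == 1
    )
    fails = {
        "missing_flags": missing,
        "not_preterm_or_low_birth_weight": ~preterm,
        "not_ventilated_at_referral": ~ventilated,
        "no_prior_pharmacotherapy": ~pharm,
        "complex_chd": df["complex_chd"].fillna(1).astype(float) == 1,
        "bidirectional_or_r2l_flow": df["bidirectional_or_r2l_flow"].fillna(1).astype(float) == 1,
        "major_anomaly": df["major_anomaly"].fillna(1).astype(float) == 1,
        "tracheostomy": df["tracheostomy"].fillna(1).astype(float) == 1,
    }
    excluded = pd.Series(False, index=df.index)
    for crit in ELIGIBILITY_CRITERIA:
        newly = fails[crit] & ~excluded
        tally[crit] = int(newly.sum())
        excluded |= fails[crit]
    eligible = df.loc[~excluded].reset_index(drop=True)
    tally["n_screened"] = int(len(df))
    tally["n_eligible"] = int(len(eligible))
    return eligible, tally


def derive_outcome_day(
    episodes: list[tuple[int, bool]],
    death_day: Optional[int] = None,
    ltfu_day: Optional[int] = None,
    horizon: int = 45,
) -> Optional[int]:
    """Day of the first *successful* extubation, or ``None``.

    Successful extubation means no invasive mechanical ventilation for at
    least seven days after extubation.  The registry records, per episode,
    whether reintubation occurred within seven days; the first episode without
    reintubation whose day is within the horizon and strictly precedes death
    and loss to follow-up is the outcome.  When the seven-day confirmation
    window extends beyond the last observed day, the episode still counts as a
    success if no reintubation was recorded in the observed portion
    (optimistic truncation convention).
    """
    for day, reintubated in episodes:
        if day > horizon:
            break
        if death_day is not None and day >= death_day:
            break
        if ltfu_day is not None and day >= ltfu_day:
            break
        if not reintubated:
            return int(day)
    return None


def add_outcome_days(df: pd.DataFrame, horizon: int = 45) -> pd.DataFrame:
    """Return a copy of the registry with a derived ``outcome_day`` column."""
    out = df.copy()
    vals = []
    for _, row in df.iterrows():
        death = None if pd.isna(row["death_day"]) else int(row["death_day"])
        ltfu = None if pd.isna(row["ltfu_day"]) else int(row["ltfu_day"])
        vals.append(
            derive_outcome_day(parse_episodes(row["extubation_episodes"]), death, ltfu, horizon)
        )
    out["outcome_day"] = pd.array(vals, dtype="Int64")
    return out
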