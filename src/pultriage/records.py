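"""Cohort records for pregnancies of unknown location (PUL).

A PUL cohort is carried as a :class:`pandas.DataFrame` with one row per
woman and a fixed column schema (:data:`COHORT_COLUMNS`); a single row can
be materialised as a :class:`PULRecord` for the scalar triage operations.

Units are fixed throughout the package: serum beta-hCG in IU/l,
progesterone in nmol/l.  Empty CSV cells are missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: Final PUL outcomes. Persistent PUL counts as EP throughout.
OUTCOMES = ("FPUL", "IUP", "EP")
#: Outcome code for women lost to follow-up (unknown final outcome).
LTFU = "LTFU"

#: Vaginal-bleeding categories recorded at presentation.
BLEEDING_LEVELS = ("none", "minimal", "moderate", "soaked", "clots")

#: Fixed cohort CSV schema, one row per PULRecord.
COHORT_COLUMNS = [
    "record_id",
    "centre_id",
    "age",
    "prog0",
    "hcg0",
    "hcg48",
    "interval_days",
    "prog_supplement",
    "bleeding",
    "outcome",
]


class InvalidMeasurementError(ValueError):
    """A biomarker value outside its physical domain (e.g. hCG <= 0)."""


class MissingPredictorError(ValueError):
    """A model was evaluated on a record lacking a required predictor."""


@dataclass
class PULRecord:
    """One woman's presentation measurements, follow-up and final outcome.

    Parameters
    ----------
    record_id, centre_id
        Identifiers; centre_id groups records for clustered analyses.
    age
        Age in years, optional.
    prog0
        Progesterone at presentation (nmol/l), >= 0; optional (missing when
        not measured or invalidated by progesterone supplements).
    hcg0
        Serum beta-hCG at presentation (IU/l), > 0; always recorded.
    hcg48
        Second beta-hCG (IU/l), > 0; optional. Present iff ``interval_days``
        is present.
    interval_days
        Whole days between the two hCG samples.
    prog_supplement
        Whether the woman was on progesterone supplements (which make the
        measured progesterone unreliable).
    outcome
        Final outcome: FPUL, IUP, EP, or LTFU when lost to follow-up.
    """

    record_id: str
    centre_id: str
    hcg0: float
    age: Optional[float] = None
    prog0: Optional[float] = None
    hcg48: Optional[float] = None
    interval_days: Optional[int] = None
    prog_supplement: bool = False
    bleeding: Optional[str] = None
    outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.hcg0) or self.hcg0 <= 0:
            raise InvalidMeasurementError(
                f"hcg0 must be a positive hCG level in IU/l, got {self.hcg0!r}"
            )
        if self.hcg48 is not None and self.hcg48 <= 0:
            raise InvalidMeasurementError(
                f"hcg48 must be positive when present, got {self.hcg48!r}"
            )
        if self.prog0 is not None and self.prog0 < 0:
            raise InvalidMeasurementError(
                f"prog0 must be non-negative, got {self.prog0!r}"
            )
        if (self.hcg48 is None) != (self.interval_days is None):
            raise ValueError(
                "interval_days must be present exactly when hcg48 is present"
            )
        if self.interval_days is not None and self.interval_days < 0:
            raise ValueError("interval_days must be >= 0")
        if self.outcome is not None and self.outcome not in OUTCOMES + (LTFU,):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def hcg_ratio(self) -> Optional[float]:
        """hcg48 / hcg0, or None when no second sample is available."""
        if self.hcg48 is None:
            return None
        return self.hcg48 / self.hcg0


def cohort_from_records(records: list[PULRecord]) -> pd.DataFrame:
    """Assemble a cohort DataFrame from individual records."""
    rows = [
        {
            "record_id": r.record_id,
            "centre_id": r.centre_id,
            "age": r.age,
            "prog0": r.prog0,
            "hcg0": r.hcg0,
            "hcg48": r.hcg48,
            "interval_days": r.interval_days,
            "prog_supplement": r.prog_supplement,
            "bleeding": r.bleeding,
            "outcome": r.outcome,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def record_from_row(row: pd.Series) -> PULRecord:
    """Materialise a single cohort row as a PULRecord."""

    def _opt(v):
        return None if pd.isna(v) else float(v)

    iv = row.get("interval_days")
    return PULRecord(
        record_id=str(row["record_id"]),
        centre_id=str(row["centre_id"]),
        hcg0=float(row["hcg0"]),
        age=_opt(row.get("age")),
        prog0=_opt(row.get("prog0")),
        hcg48=_opt(row.get("hcg48")),
        interval_days=None if pd.isna(iv) else int(iv),
        prog_supplement=bool(row.get("prog_supplement", False)),
        bleeding=None if pd.isna(row.get("bleeding")) else str(row["bleeding"]),
        outcome=None if pd.isna(row.get("outcome")) else str(row["outcome"]),
    )


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a cohort DataFrame.

    Returns the cohort (with columns in canonical order) or raises.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing columns: {missing_cols}")
    if cohort["record_id"].duplicated().any():
        raise ValueError("duplicate record_id values in cohort")
    if (cohort["hcg0"] <= 0).any() or cohort["hcg0"].isna().any():
        raise InvalidMeasurementError("hcg0 must be present and > 0 for all records")
    h48 = cohort["hcg48"]
    if (h48.dropna() <= 0).any():
        raise InvalidMeasurementError("hcg48 must be > 0 when present")
    if (cohort["prog0"].dropna() < 0).any():
        raise InvalidMeasurementError("prog0 must be >= 0 when present")
    if (h48.isna() != cohort["interval_days"].isna()).any():
        raise ValueError("interval_days must be present exactly when hcg48 is")
    bad = set(cohort["outcome"].dropna()) - set(OUTCOMES) - {LTFU}
    if bad:
        raise ValueError(f"unknown outcome codes: {sorted(bad)}")
    return cohort[COHORT_COLUMNS + [c for c in cohort.columns if c not in COHORT_COLUMNS]]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty cell = missing) and validate it."""
    df = pd.read_csv(path)
    if "prog_supplement" in df.columns:
        df["prog_supplement"] = (
            df["prog_supplement"].fillna(False).astype(bool)
        )
    return validate_cohort(df)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV with missing values as empty cells."""
    validate_cohort(cohort[COHORT_COLUMNS])
    cohort[COHORT_COLUMNS].to_csv(path, index=False)
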