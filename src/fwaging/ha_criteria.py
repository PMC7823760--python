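"""Operational scoring of the four healthy-aging (HA) criteria.

A respondent is *healthy aging* when they simultaneously satisfy:

* **Y1 — physical health**: no disability and at most two chronic conditions;
* **Y2 — daily activities**: every one of the 10 ADL items graded 1 or 2
  (grades run 1 = no difficulty .. 4 = cannot do);
* **Y3 — mental health**: the 10 depression items (graded 1..4) sum to 20
  or less;
* **Y4 — social participation**: at least two distinct social activities
  attended in the last month (out of 8 tracked activities).

The module also provides cohort prevalence summaries and Cronbach's alpha
for scale-reliability reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UndefinedStatisticError

__all__ = [
    "MicroRecord",
    "HAProfile",
    "CronbachResult",
    "COVARIATE_NAMES",
    "N_ADL_ITEMS",
    "N_DEPRESSION_ITEMS",
    "N_ACTIVITIES",
    "MAX_CHRONIC",
    "DEPRESSION_CUTOFF",
    "MIN_ACTIVITIES",
    "score_physical",
    "score_adl",
    "score_mental",
    "score_social",
    "score_profile",
    "prevalence",
    "cronbach_alpha",
    "read_records_csv",
    "write_records_csv",
    "read_profiles_csv",
    "write_profiles_csv",
]

N_ADL_ITEMS = 10
N_DEPRESSION_ITEMS = 10
N_ACTIVITIES = 8

MAX_CHRONIC = 2          # Y1: at most this many chronic conditions
ADL_INDEPENDENT_MAX = 2  # Y2: per-item grade <= 2 means independent
DEPRESSION_CUTOFF = 20   # Y3: item sum <= 20 means good mental health
MIN_ACTIVITIES = 2       # Y4: distinct activities attended per month

COVARIATE_NAMES = tuple(f"X{i}" for i in range(1, 13))


@dataclass(frozen=True)
class MicroRecord:
    """One respondent's raw item responses plus binary covariates X1..X12."""

    id: str
    adl_grades: tuple[int, ...]
    depression_grades: tuple[int, ...]
    activity_counts: tuple[int, ...]
    disabled: bool
    n_chronic: int
    x: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "adl_grades", tuple(int(g) for g in self.adl_grades))
        object.__setattr__(
            self, "depression_grades", tuple(int(g) for g in self.depression_grades)
        )
        object.__setattr__(
            self, "activity_counts", tuple(int(c) for c in self.activity_counts)
        )
        if len(self.adl_grades) != N_ADL_ITEMS:
            raise ValueError(f"expected {N_ADL_ITEMS} ADL grades, got {len(self.adl_grades)}")
        if len(self.depression_grades) != N_DEPRESSION_ITEMS:
            raise ValueError(
                f"expected {N_DEPRESSION_ITEMS} depression grades, got {len(self.depression_grades)}"
            )
        if len(self.activity_counts) != N_ACTIVITIES:
            raise ValueError(
                f"expected {N_ACTIVITIES} activity counts, got {len(self.activity_counts)}"
            )
        if any(g < 1 or g > 4 for g in self.adl_grades):
            raise ValueError("ADL grades must lie in 1..4")
        if any(g < 1 or g > 4 for g in self.depression_grades):
            raise ValueError("depression grades must lie in 1..4")
        if any(c < 0 for c in self.activity_counts):
            raise ValueError("activity counts must be non-negative")
        if self.n_chronic < 0:
            raise ValueError("n_chronic must be non-negative")
        missing = [k for k in COVARIATE_NAMES if k not in self.x]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        bad = {k: v for k, v in self.x.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"covariates must be binary 0/1, got {bad}")


@dataclass(frozen=True)
class HAProfile:
    """The four criterion outcomes plus the composite for one respondent."""

    id: str
    y1_physical: bool
    y2_adl: bool
    y3_mental: bool
    y4_social: bool
    y_ha: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        conj = self.y1_physical and self.y2_adl and self.y3_mental and self.y4_social
        if self.y_ha is None:
            object.__setattr__(self, "y_ha", conj)
        elif bool(self.y_ha) != conj:
            raise ValueError("y_ha must equal the conjunction of y1..y4")

    CRITERIA = ("y1_physical", "y2_adl", "y3_mental", "y4_social", "y_ha")


def score_physical(record: MicroRecord) -> bool:
    """Y1: no disability and at most ``MAX_CHRONIC`` chronic conditions."""
    return (not record.disabled) and record.n_chronic <= MAX_CHRONIC


def score_adl(record: MicroRecord) -> bool:
    """Y2: independent (grade <= 2) on every one of the 10 ADL items."""
    return all(g <= ADL_INDEPENDENT_MAX for g in record.adl_grades)


def score_mental(record: MicroRecord) -> bool:
    """Y3: depression item total <= ``DEPRESSION_CUTOFF``.

    Items are summed as recorded; no reverse-coding is applied.
    """
    return sum(record.depression_grades) <= DEPRESSION_CUTOFF


def score_social(record: MicroRecord) -> bool:
    """Y4: at least ``MIN_ACTIVITIES`` *distinct* activities attended.

    An activity counts once if attended at least once in the last month,
    regardless of frequency.
    """
    return sum(1 for c in record.activity_counts if c >= 1) >= MIN_ACTIVITIES


def score_profile(record: MicroRecord) -> HAProfile:
    """Score all four criteria; the composite is their conjunction."""
    return HAProfile(
        id=record.id,
        y1_physical=score_physical(record),
        y2_adl=score_adl(record),
        y3_mental=score_mental(record),
        y4_social=score_social(record),
    )


def prevalence(profiles: Sequence[HAProfile]) -> dict[str, tuple[int, float]]:
    """Count and proportion of respondents meeting each criterion.

    Returns a map from criterion name (``y1_physical`` .. ``y_ha``) to
    ``(count, proportion)``.

    Raises
    ------
    EmptyInputError
        If ``profiles`` is empty.
    """
    if not profiles:
        raise EmptyInputError("prevalence requires at least one profile")
    n = len(profiles)
    out: dict[str, tuple[int, float]] = {}
    for crit in HAProfile.CRITERIA:
        count = sum(1 for p in profiles if getattr(p, crit))
        out[crit] = (count, count / n)
    return out


@dataclass(frozen=True)
class CronbachResult:
    alpha: float
    alpha_if_deleted: tuple[float, ...]
    n_items: int
    n_respondents: int


def cronbach_alpha(item_matrix) -> CronbachResult:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item var) / var(row sums))``.

    Variances use the sample (n-1) denominator.  Also reports alpha with
    each item deleted in turn (``nan`` when fewer than 2 items remain).

    Raises
    ------
    UndefinedStatisticError
        If the total-score variance is zero or the matrix is too small.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise UndefinedStatisticError("need at least 2 respondents and 2 items")

    def _alpha(mat: np.ndarray) -> float:
        k = mat.shape[1]
        total_var = mat.sum(axis=1).var(ddof=1)
        if total_var == 0:
            raise UndefinedStatisticError("total-score variance is zero")
        item_var = mat.var(axis=0, ddof=1).sum()
        return k / (k - 1) * (1.0 - item_var / total_var)

    alpha = _alpha(m)
    deleted = []
    for j in range(m.shape[1]):
        rest = np.delete(m, j, axis=1)
        if rest.shape[1] < 2:
            deleted.append(float("nan"))
            continue
        try:
            deleted.append(_alpha(rest))
        except UndefinedStatisticError:
            deleted.append(float("nan"))
    return CronbachResult(
        alpha=alpha,
        alpha_if_deleted=tuple(deleted),
        n_items=m.shape[1],
        n_respondents=m.shape[0],
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_ADL_COLS = [f"adl{i:02d}" for i in range(1, N_ADL_ITEMS + 1)]
_DEP_COLS = [f"dep{i:02d}" for i in range(1, N_DEPRESSION_ITEMS + 1)]
_ACT_COLS = [f"act{i}" for i in range(1, N_ACTIVITIES + 1)]
_X_COLS = [x.lower() for x in COVARIATE_NAMES]

RECORD_COLUMNS = ["id"] + _ADL_COLS + _DEP_COLS + _ACT_COLS + ["disabled", "n_chronic"] + _X_COLS


def records_to_frame(records: Iterable[MicroRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "disabled": int(r.disabled), "n_chronic": r.n_chronic}
        row.update(dict(zip(_ADL_COLS, r.adl_grades)))
        row.update(dict(zip(_DEP_COLS, r.depression_grades)))
        row.update(dict(zip(_ACT_COLS, r.activity_counts)))
        row.update({c: int(r.x[c.upper()]) for c in _X_COLS})
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MicroRecord]:
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"record table lacks columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            MicroRecord(
                id=str(d["id"]),
                adl_grades=tuple(d[c] for c in _ADL_COLS),
                depression_grades=tuple(d[c] for c in _DEP_COLS),
                activity_counts=tuple(d[c] for c in _ACT_COLS),
                disabled=bool(d["disabled"]),
                n_chronic=int(d["n_chronic"]),
                x={c.upper(): int(d[c]) for c in _X_COLS},
            )
        )
    return records


def write_records_csv(records: Iterable[MicroRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[MicroRecord]:
    return frame_to_records(pd.read_csv(path))


def profiles_to_frame(profiles: Iterable[HAProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "y1": int(p.y1_physical),
                "y2": int(p.y2_adl),
                "y3": int(p.y3_mental),
                "y4": int(p.y4_social),
                "y_ha": int(p.y_ha),
            }
            for p in profiles
        ],
        columns=["id", "y1", "y2", "y3", "y4", "y_ha"],
    )


def frame_to_profiles(frame: pd.DataFrame) -> list[HAProfile]:
    return [
        HAProfile(
            id=str(row.id),
            y1_physical=bool(row.y1),
            y2_adl=bool(row.y2),
            y3_mental=bool(row.y3),
            y4_social=bool(row.y4),
        )
        for row in frame.itertuples(index=False)
    ]


def write_profiles_csv(profiles: Iterable[HAProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path) -> list[HAProfile]:
    return frame_to_profiles(pd.read_csv(path))


def reliability_report(records: Sequence[MicroRecord]) -> dict:
    """Cronbach's alpha for the ADL and depression scales of a cohort."""
    if not records:
        raise EmptyInputError("reliability report needs at least one record")
    adl = np.array([r.adl_grades for r in records], dtype=float)
    dep = np.array([r.depression_grades for r in records], dtype=float)
    out = {}
    for name, mat in (("adl", adl), ("depression", dep)):
        try:
            res = cronbach_alpha(mat)
            out[name] = {
                "alpha": res.alpha,
                "alpha_if_item_deleted": list(res.alpha_if_deleted),
                "n_items": res.n_items,
                "n_respondents": res.n_respondents,
            }
        except UndefinedStatisticError as exc:
            out[name] = {"error": str(exc)}
    return out


def write_reliability_report(records: Sequence[MicroRecord], path) -> None:
    Path(path).write_text(json.dumps(reliability_report(records), indent=2))
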