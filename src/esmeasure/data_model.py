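"""Long-format item-score datasets, visit schedules, I/O and eligibility filters.

The in-memory containers are pandas DataFrames — one row per record — wrapped
in a validated :class:`Dataset`:

- ``scores``: columns ``subject_id, visit, item, score``; ``score`` is a
  nullable integer in 0-4 and a missing value is an explicit <NA>, never 0
  (0 is a meaningful clinical response).
- ``subjects``: columns ``subject_id, arm, stx_time_months, age, sex, hy``;
  ``stx_time_months`` is months from baseline to first dopaminergic therapy
  (<NA> = never started).

Visit identity is by scheduled visit code ("BL", "W3", ..., "M24"), not
calendar date; mapping real-trial calendar dates into visit windows is out of
scope.  The default schedule is baseline, weeks 3 and 6, then every 3 months
to month 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

from esmeasure.exceptions import FormatError, ValidationError
from esmeasure.items import ALL_ITEMS

VISIT_CLASSES = ("scheduled", "unscheduled", "telephone", "safety", "washout")
ARMS = ("active", "placebo")

SCORE_COLUMNS = ("subject_id", "visit", "item", "score")
SUBJECT_COLUMNS = ("subject_id", "arm", "stx_time_months", "age", "sex", "hy")


@dataclass(frozen=True)
class Visit:
    """One protocol visit: a code, a nominal time and a protocol class."""

    code: str
    months: float
    visit_class: str = "scheduled"

    def __post_init__(self) -> None:
        if self.visit_class not in VISIT_CLASSES:
            raise ValidationError(
                f"visit {self.code!r}: unknown visit_class {self.visit_class!r}"
            )


class VisitSchedule(Sequence[Visit]):
    """Ordered protocol visit list; nominal times strictly increasing, BL at 0."""

    def __init__(self, visits: Iterable[Visit]):
        self._visits: tuple[Visit, ...] = tuple(visits)
        if not self._visits:
            raise ValidationError("schedule must contain at least one visit")
        times = [v.months for v in self._visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("schedule nominal times must be strictly increasing")
        if self._visits[0].months != 0:
            raise ValidationError("first scheduled visit must be baseline at 0 months")
        self._by_code = {v.code: v for v in self._visits}
        if len(self._by_code) != len(self._visits):
            raise ValidationError("duplicate visit codes in schedule")

    def __len__(self) -> int:
        return len(self._visits)

    def __getitem__(self, i):  # type: ignore[override]
        return self._visits[i]

    def __iter__(self) -> Iterator[Visit]:
        return iter(self._visits)

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VisitSchedule) and self._visits == other._visits

    def by_code(self, code: str) -> Visit:
        return self._by_code[code]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(v.code for v in self._visits)

    @property
    def baseline(self) -> Visit:
        return self._visits[0]

    def scheduled(self) -> "VisitSchedule":
        """The sub-schedule of protocol-class 'scheduled' visits."""
        return VisitSchedule(v for v in self._visits if v.visit_class == "scheduled")

    def post_baseline(self) -> tuple[Visit, ...]:
        return self._visits[1:]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VisitSchedule":
        """Read an ordered list of ``{code, months, class}`` mappings."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise FormatError(f"{path}: schedule YAML must be a list of mappings")
        visits = []
        for i, entry in enumerate(raw):
            try:
                visits.append(
                    Visit(
                        code=str(entry["code"]),
                        months=float(entry["months"]),
                        visit_class=str(entry.get("class", "scheduled")),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}: bad schedule entry {i}: {exc}") from exc
        return cls(visits)

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {"code": v.code, "months": v.months, "class": v.visit_class}
            for v in self._visits
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


#: Baseline, weeks 3/6, then 3-monthly to month 24 — all analysis visits.
DEFAULT_SCHEDULE = VisitSchedule(
    [
        Visit("BL", 0.0),
        Visit("W3", 0.75),
        Visit("W6", 1.5),
        Visit("M3", 3.0),
        Visit("M6", 6.0),
        Visit("M9", 9.0),
        Visit("M12", 12.0),
        Visit("M15", 15.0),
        Visit("M18", 18.0),
        Visit("M21", 21.0),
        Visit("M24", 24.0),
    ]
)


def _validate_scores(scores: pd.DataFrame, schedule: VisitSchedule,
                     subject_ids: set) -> pd.DataFrame:
    missing_cols = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing_cols:
        raise FormatError(f"scores table is missing column(s): {', '.join(missing_cols)}")
    scores = scores.loc[:, list(SCORE_COLUMNS)].copy()
    scores["subject_id"] = scores["subject_id"].astype(str)
    scores["visit"] = scores["visit"].astype(str)
    scores["item"] = scores["item"].astype(str)
    try:
        scores["score"] = scores["score"].astype("Int64")
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer score value: {exc}") from exc

    present = scores["score"].notna()
    bad = present & ~scores["score"].isin([0, 1, 2, 3, 4])
    if bad.any():
        idx = scores.index[bad][0]
        raise ValidationError(
            f"score out of range 0-4 at row {idx}: {scores.loc[idx, 'score']}"
        )
    unknown_visit = ~scores["visit"].isin(schedule.codes)
    if unknown_visit.any():
        idx = scores.index[unknown_visit][0]
        raise ValidationError(f"unknown visit code at row {idx}: {scores.loc[idx, 'visit']!r}")
    unknown_item = ~scores["item"].isin(ALL_ITEMS)
    if unknown_item.any():
        idx = scores.index[unknown_item][0]
        raise ValidationError(f"unknown item code at row {idx}: {scores.loc[idx, 'item']!r}")
    unknown_subj = ~scores["subject_id"].isin(subject_ids)
    if unknown_subj.any():
        idx = scores.index[unknown_subj][0]
        raise ValidationError(
            f"score row {idx} references unknown subject {scores.loc[idx, 'subject_id']!r}"
        )
    dup = scores.duplicated(subset=["subject_id", "visit", "item"])
    if dup.any():
        idx = scores.index[dup][0]
        raise ValidationError(
            "duplicate (subject, visit, item) record at row "
            f"{idx}: {tuple(scores.loc[idx, ['subject_id', 'visit', 'item']])}"
        )
    return scores.reset_index(drop=True)


def _validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing_cols:
        raise FormatError(
            f"subjects table is missing column(s): {', '.join(missing_cols)}"
        )
    subjects = subjects.loc[:, list(SUBJECT_COLUMNS)].copy()
    subjects["subject_id"] = subjects["subject_id"].astype(str)
    if subjects["subject_id"].duplicated().any():
        dup_id = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup_id!r}")
    bad_arm = ~subjects["arm"].isin(ARMS)
    if bad_arm.any():
        idx = subjects.index[bad_arm][0]
        raise ValidationError(f"unknown arm at row {idx}: {subjects.loc[idx, 'arm']!r}")
    subjects["stx_time_months"] = pd.to_numeric(
        subjects["stx_time_months"], errors="coerce"
    )
    neg = subjects["stx_time_months"] < 0
    if neg.any():
        idx = subjects.index[neg][0]
        raise ValidationError(f"negative stx_time_months at row {idx}")
    subjects["age"] = pd.to_numeric(subjects["age"], errors="coerce")
    subjects["hy"] = pd.to_numeric(subjects["hy"], errors="coerce")
    return subjects.reset_index(drop=True)


@dataclass
class Dataset:
    """A validated cohort: subject table + long-format score records + schedule."""

    subjects: pd.DataFrame
    scores: pd.DataFrame
    schedule: VisitSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)

    def __post_init__(self) -> None:
        self.subjects = _validate_subjects(pd.DataFrame(self.subjects))
        self.scores = _validate_scores(
            pd.DataFrame(self.scores), self.schedule, set(self.subjects["subject_id"])
        )

    # -- convenience -------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_records(self) -> int:
        return len(self.scores)

    def subject_scores(self, subject_id: str) -> pd.DataFrame:
        return self.scores[self.scores["subject_id"] == subject_id]

    def stx_time(self, subject_id: str) -> float | None:
        row = self.subjects.loc[self.subjects["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        t = row["stx_time_months"].iloc[0]
        return None if pd.isna(t) else float(t)

    def equals(self, other: "Dataset") -> bool:
        return (
            self.schedule == other.schedule
            and self.subjects.equals(other.subjects)
            and self.scores.equals(other.scores)
        )


def read_dataset(
    scores_path: str | Path,
    subjects_path: str | Path,
    schedule: VisitSchedule | None = None,
) -> Dataset:
    """Read and validate the two long-format CSVs into a :class:`Dataset`.

    Malformed rows are rejected with an error naming the offending column or
    row index — never silently dropped.
    """
    schedule = schedule if schedule is not None else DEFAULT_SCHEDULE
    for path in (scores_path, subjects_path):
        if not Path(path).exists():
            raise FormatError(f"file not found: {path}")
    scores = pd.read_csv(scores_path, dtype=str, keep_default_na=False)
    scores = scores.replace({"score": {"": None}})
    try:
        scores["score"] = pd.array(
            [None if v is None else int(v) for v in scores.get("score", [])],
            dtype="Int64",
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"scores file {scores_path}: non-integer score ({exc})") from exc
    subjects = pd.read_csv(subjects_path, dtype=str, keep_default_na=False)
    subjects = subjects.replace(
        {"stx_time_months": {"": None}, "age": {"": None}, "hy": {"": None}}
    )
    return Dataset(subjects=subjects, scores=scores, schedule=schedule)


def write_dataset(
    ds: Dataset, scores_path: str | Path, subjects_path: str | Path
) -> None:
    """Write the two CSVs (UTF-8, comma-separated, blank field = missing)."""
    ds.scores.to_csv(scores_path, index=False)
    ds.subjects.to_csv(subjects_path, index=False)


def filter_analysis_visits(ds: Dataset) -> Dataset:
    """Drop records from unscheduled / telephone / safety / washout visits.

    Only protocol-class 'scheduled' visits carry analyzable MDS-UPDRS data;
    the others are most often adverse-event driven and do not consistently
    report the scale.  Subjects are retained even if all their records go.
    Idempotent.
    """
    keep_codes = {v.code for v in ds.schedule if v.visit_class == "scheduled"}
    scores = ds.scores[ds.scores["visit"].isin(keep_codes)].reset_index(drop=True)
    return Dataset(subjects=ds.subjects.copy(), scores=scores,
                   schedule=ds.schedule.scheduled())


def filter_subjects_with_followup(ds: Dataset) -> Dataset:
    """Remove subjects with no scored item at any post-baseline scheduled visit.

    A participant contributes nothing to change-from-baseline analyses without
    at least one follow-up assessment; such subjects are removed together with
    their records.  Idempotent.
    """
    post_codes = {
        v.code
        for v in ds.schedule.post_baseline()
        if v.visit_class == "scheduled"
    }
    scored = ds.scores[ds.scores["score"].notna() & ds.scores["visit"].isin(post_codes)]
    keep = set(scored["subject_id"])
    subjects = ds.subjects[ds.subjects["subject_id"].isin(keep)].reset_index(drop=True)
    scores = ds.scores[ds.scores["subject_id"].isin(keep)].reset_index(drop=True)
    return Dataset(subjects=subjects, scores=scores, schedule=ds.schedule)
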