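"""Shared fixtures: compact dataset builders used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from esmeasure.data_model import DEFAULT_SCHEDULE, Dataset, VisitSchedule
from esmeasure.items import IB_PLUS_II, ITEM_SETS
from esmeasure.scoring import ESConfig


def build_dataset(
    score_rows: list[tuple],
    subjects: list[tuple] | None = None,
    schedule: VisitSchedule = DEFAULT_SCHEDULE,
) -> Dataset:
    """Build a validated Dataset from (subject, visit, item, score) tuples.

    ``score=None`` writes an explicitly-missing record.  Subjects default to
    placebo arm, no symptomatic therapy; pass (subject_id, arm, stx_time)
    tuples to override.
    """
    sids = sorted({r[0] for r in score_rows} | {s[0] for s in (subjects or [])})
    sub_over = {s[0]: s for s in (subjects or [])}
    subject_frame = pd.DataFrame(
        {
            "subject_id": sids,
            "arm": [sub_over.get(s, (s, "placebo", None))[1] for s in sids],
            "stx_time_months": [sub_over.get(s, (s, "placebo", None))[2] for s in sids],
            "age": [60.0] * len(sids),
            "sex": ["F"] * len(sids),
            "hy": [1.5] * len(sids),
        }
    )
    score_frame = pd.DataFrame(
        {
            "subject_id": [r[0] for r in score_rows],
            "visit": [r[1] for r in score_rows],
            "item": [r[2] for r in score_rows],
            "score": pd.array([r[3] for r in score_rows], dtype="Int64"),
        }
    )
    return Dataset(subjects=subject_frame, scores=score_frame, schedule=schedule)


def random_fixture(rng: np.random.Generator, n_subjects: int = 30,
                   missing_prob: float = 0.1) -> Dataset:
    """A random IB+II cohort on the default schedule, with missingness.

    Scores are drawn to put plenty of mass on 0 at baseline (so ES events
    exist) and to include explicit missing records and absent visits.
    """
    rows = []
    visits = DEFAULT_SCHEDULE.codes
    for i in range(n_subjects):
        sid = f"R{i:03d}"
        skip_visits = set(
            rng.choice(visits[1:], size=rng.integers(0, 3), replace=False)
        )
        for visit in visits:
            if visit in skip_visits:
                continue
            for item in IB_PLUS_II:
                if rng.random() < missing_prob:
                    rows.append((sid, visit, item, None))
                else:
                    # skewed ordinal draw, most mass at 0/1
                    score = int(rng.choice([0, 1, 2, 3, 4], p=[0.55, 0.25, 0.12, 0.05, 0.03]))
                    rows.append((sid, visit, item, score))
    subjects = [
        (f"R{i:03d}", "placebo", float(rng.integers(1, 24)) if rng.random() < 0.3 else None)
        for i in range(n_subjects)
    ]
    return build_dataset(rows, subjects=subjects)


@pytest.fixture
def two_subject_ds() -> Dataset:
    """Two subjects, three visits, two items — small enough to reason by hand."""
    return build_dataset(
        [
            ("A", "BL", "1.7", 0), ("A", "BL", "2.11", 1),
            ("A", "W3", "1.7", 1), ("A", "W3", "2.11", 0),
            ("A", "M12", "1.7", 2), ("A", "M12", "2.11", 3),
            ("B", "BL", "1.7", 0), ("B", "BL", "2.11", 0),
            ("B", "W3", "1.7", 0), ("B", "W3", "2.11", None),
            ("B", "M12", "1.7", 0), ("B", "M12", "2.11", 1),
        ],
        subjects=[("A", "active", 7.0), ("B", "placebo", None)],
    )


# ---------------------------------------------------------------------------
# naive reference implementation: explicit per-record loops, no arrays


def score_lookup(ds: Dataset) -> dict:
    out = {}
    for row in ds.scores.itertuples(index=False):
        out[(row.subject_id, row.visit, row.item)] = (
            None if pd.isna(row.score) else int(row.score)
        )
    return out


def naive_es_events(ds: Dataset, subject: str, visit: str, cfg: ESConfig) -> int:
    lookup = score_lookup(ds)
    codes = [v.code for v in ds.schedule if v.visit_class == "scheduled"]
    bl = codes[0]
    count = 0
    for item in ITEM_SETS[cfg.item_set]:
        if lookup.get((subject, bl, item)) != 0:
            continue
        if cfg.stability_rule == "confirmed_baseline_zero":
            confirm = None
            for v in codes[1:]:
                val = lookup.get((subject, v, item))
                if val is not None:
                    confirm = val
                    break
            if confirm != 0:
                continue
        val = lookup.get((subject, visit, item))
        if val is None or val < cfg.threshold:
            continue
        if cfg.stability_rule == "two_consecutive_emergent":
            nxt = None
            for v in codes[codes.index(visit) + 1:]:
                nv = lookup.get((subject, v, item))
                if nv is not None:
                    nxt = nv
                    break
            if nxt is None or nxt < cfg.threshold:
                continue
        count += 1
    return count


def naive_frequency(ds: Dataset, visit: str, cfg: ESConfig):
    lookup = score_lookup(ds)
    n_eval, patients, events = 0, 0, []
    for sid in ds.subject_ids:
        scored = any(
            lookup.get((sid, visit, item)) is not None
            for item in ITEM_SETS[cfg.item_set]
        )
        if not scored:
            continue
        n_eval += 1
        ev = naive_es_events(ds, sid, visit, cfg)
        events.append(ev)
        patients += ev >= 1
    return n_eval, patients, events
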