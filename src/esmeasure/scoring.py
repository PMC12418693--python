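"""Emergent-symptom (ES) detection, counting, stability variants and tables.

An ES for a subject at a follow-up visit is an item of the chosen set
(Part IB, Part II, or both) that was scored exactly 0 at baseline and is
scored at or above the threshold (1, 2 or 3) at that visit.  ``es_events``
counts such items for one subject-visit; a subject is an "ES patient" at a
visit if the count is at least 1.

Two stability variants probe the robustness of the measure against
visit-to-visit response instability:

- ``confirmed_baseline_zero``: the baseline 0 must be confirmed by a 0 at
  the first post-baseline visit with a non-missing score for that item
  (two consecutive zeroes to qualify as symptom-free at entry);
- ``two_consecutive_emergent``: the item must reach the threshold at the
  qualifying visit AND at the next visit with a non-missing score
  (persistence of the emergent symptom).

Missing-data policy: items missing at baseline are ineligible (a baseline 0
cannot be verified); items missing at a follow-up visit contribute no event
at that visit; "consecutive" means adjacent within the sequence of visits at
which the item is non-missing, so isolated missing assessments do not destroy
otherwise-stable evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from esmeasure.data_model import Dataset, Visit
from esmeasure.exceptions import ConfigurationError, DomainError, EligibilityError
from esmeasure.items import ALL_ITEMS, ITEM_SETS

STABILITY_RULES = ("none", "two_consecutive_emergent", "confirmed_baseline_zero")


@dataclass(frozen=True)
class ESConfig:
    """Parameterizes every ES computation: threshold, item set, stability rule."""

    threshold: int = 1
    item_set: str = "IB_plus_II"
    stability_rule: str = "none"

    def __post_init__(self) -> None:
        if self.threshold not in (1, 2, 3):
            raise ConfigurationError(f"threshold must be 1, 2 or 3, got {self.threshold}")
        if self.item_set not in ITEM_SETS:
            raise ConfigurationError(
                f"item_set must be one of {sorted(ITEM_SETS)}, got {self.item_set!r}"
            )
        if self.stability_rule not in STABILITY_RULES:
            raise ConfigurationError(
                f"stability_rule must be one of {STABILITY_RULES}, got {self.stability_rule!r}"
            )

    @property
    def items(self) -> tuple[str, ...]:
        return ITEM_SETS[self.item_set]


def round_percent(k: int, n: int) -> float:
    """Percentage to 1 decimal, half-up (table style)."""
    if n == 0:
        return float("nan")
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


class ESEngine:
    """Vectorized scoring engine over a subject x visit x item score cube.

    Built once per (dataset, config); the per-subject module functions are
    thin wrappers.  Only protocol-class 'scheduled' visits enter the cube.
    """

    def __init__(self, ds: Dataset, cfg: ESConfig):
        self.ds = ds
        self.cfg = cfg
        self.visits: list[Visit] = [v for v in ds.schedule if v.visit_class == "scheduled"]
        self.visit_codes = [v.code for v in self.visits]
        self.subject_ids = ds.subject_ids
        self.items = list(cfg.items)
        self._sidx = {s: i for i, s in enumerate(self.subject_ids)}
        self._vidx = {c: i for i, c in enumerate(self.visit_codes)}
        self._iidx = {c: i for i, c in enumerate(self.items)}
        self.cube = self._build_cube()
        self._has_baseline_record = self._baseline_presence()
        self.baseline_zero = self._baseline_zero_mask()
        self._next_nonmissing = self._next_nonmissing_values()

    def _build_cube(self) -> np.ndarray:
        n_s, n_v, n_i = len(self.subject_ids), len(self.visits), len(self.items)
        cube = np.full((n_s, n_v, n_i), np.nan)
        sub = self.ds.scores[
            self.ds.scores["item"].isin(self._iidx)
            & self.ds.scores["visit"].isin(self._vidx)
        ]
        if len(sub):
            si = sub["subject_id"].map(self._sidx).to_numpy()
            vi = sub["visit"].map(self._vidx).to_numpy()
            ii = sub["item"].map(self._iidx).to_numpy()
            cube[si, vi, ii] = sub["score"].astype("float64").to_numpy()
        return cube

    def _baseline_presence(self) -> np.ndarray:
        # a subject "has a baseline visit" if any item-set record row exists
        # at BL (even an explicitly-missing one)
        bl_code = self.visits[0].code
        sub = self.ds.scores[
            (self.ds.scores["visit"] == bl_code)
            & self.ds.scores["item"].isin(self._iidx)
        ]
        present = np.zeros(len(self.subject_ids), dtype=bool)
        present[[self._sidx[s] for s in set(sub["subject_id"])]] = True
        return present

    def _baseline_zero_mask(self) -> np.ndarray:
        bl = self.cube[:, 0, :]
        mask = bl == 0  # NaN compares False: missing-at-baseline ineligible
        if self.cfg.stability_rule == "confirmed_baseline_zero":
            post = self.cube[:, 1:, :]
            notna = ~np.isnan(post)
            has_post = notna.any(axis=1)
            first_idx = notna.argmax(axis=1)
            first_val = np.take_along_axis(post, first_idx[:, None, :], axis=1)[:, 0, :]
            mask = mask & has_post & (first_val == 0)
        return mask

    def _next_nonmissing_values(self) -> np.ndarray:
        # nxt[:, v, :] = score at the next visit after v with a non-missing
        # score for that subject-item (NaN if none)
        nxt = np.full_like(self.cube, np.nan)
        carry = np.full(self.cube.shape[::2], np.nan)
        for v in range(self.cube.shape[1] - 1, -1, -1):
            nxt[:, v, :] = carry
            cur = self.cube[:, v, :]
            carry = np.where(np.isnan(cur), carry, cur)
        return nxt

    # -- queries -----------------------------------------------------------
    def visit_index(self, visit: str) -> int:
        if visit not in self._vidx:
            raise DomainError(f"unknown or non-scheduled visit {visit!r}")
        return self._vidx[visit]

    def subject_index(self, subject: str) -> int:
        if subject not in self._sidx:
            raise DomainError(f"unknown subject {subject!r}")
        return self._sidx[subject]

    def event_matrix(self, visit: str) -> np.ndarray:
        """Boolean (subject x item) ES-event matrix at a post-baseline visit."""
        v = self.visit_index(visit)
        if v == 0:
            raise DomainError("ES is undefined at the baseline visit")
        events = self.baseline_zero & (self.cube[:, v, :] >= self.cfg.threshold)
        if self.cfg.stability_rule == "two_consecutive_emergent":
            events = events & (self._next_nonmissing[:, v, :] >= self.cfg.threshold)
        return events

    def events_per_subject(self, visit: str) -> np.ndarray:
        return self.event_matrix(visit).sum(axis=1)

    def evaluable(self, visit: str) -> np.ndarray:
        """Subjects with >= 1 non-missing item-set score at the visit."""
        v = self.visit_index(visit)
        return (~np.isnan(self.cube[:, v, :])).any(axis=1)


@dataclass(frozen=True)
class ESVisitSummary:
    """ES frequency at one visit for one (threshold, item set) combination."""

    visit: str
    threshold: int
    item_set: str
    stability_rule: str
    n_evaluable: int
    n_es_patients: int
    subject_ids: tuple[str, ...]  # the evaluable subjects, in dataset order
    es_events_per_subject: tuple[int, ...]  # aligned with subject_ids

    @property
    def percent(self) -> float:
        return round_percent(self.n_es_patients, self.n_evaluable)

    @property
    def mean_events(self) -> float:
        return float(np.mean(self.es_events_per_subject)) if self.subject_ids else float("nan")


# ---------------------------------------------------------------------------
# per-subject operations


def baseline_zero_items(ds: Dataset, subject: str, cfg: ESConfig) -> set[str]:
    """Item-set items eligible to become emergent: scored exactly 0 at baseline.

    Under ``confirmed_baseline_zero`` the 0 must recur at the first
    post-baseline visit with a non-missing score.  Items missing at baseline
    are excluded.  Raises :class:`EligibilityError` for subjects without a
    baseline assessment.
    """
    eng = ESEngine(ds, cfg)
    s = eng.subject_index(subject)
    if not eng._has_baseline_record[s]:
        raise EligibilityError(f"subject {subject!r} has no baseline assessment")
    mask = eng.baseline_zero[s]
    return {eng.items[i] for i in np.flatnonzero(mask)}


def es_events(ds: Dataset, subject: str, visit: str, cfg: ESConfig) -> int:
    """Number of baseline-zero items at or above threshold at a follow-up visit."""
    eng = ESEngine(ds, cfg)
    s = eng.subject_index(subject)
    if not eng._has_baseline_record[s]:
        raise EligibilityError(f"subject {subject!r} has no baseline assessment")
    return int(eng.event_matrix(visit)[s].sum())


def es_indicator(ds: Dataset, subject: str, visit: str, cfg: ESConfig) -> bool:
    """True iff the subject has at least one ES at the visit."""
    return es_events(ds, subject, visit, cfg) >= 1


# ---------------------------------------------------------------------------
# cohort tables


def es_frequency_table(
    ds: Dataset,
    visits: list[str] | None = None,
    thresholds: tuple[int, ...] = (1, 2, 3),
    item_sets: tuple[str, ...] = ("IB_plus_II", "IB", "II"),
    stability_rule: str = "none",
) -> list[ESVisitSummary]:
    """ES frequency per (visit, threshold, item set).

    ``n_evaluable`` counts subjects with at least one non-missing item-set
    score at the visit (so N varies with attrition); subjects without a
    baseline assessment contribute zero events vacuously.
    """
    summaries: list[ESVisitSummary] = []
    for item_set in item_sets:
        for tau in thresholds:
            cfg = ESConfig(threshold=tau, item_set=item_set, stability_rule=stability_rule)
            eng = ESEngine(ds, cfg)
            use_visits = visits if visits is not None else eng.visit_codes[1:]
            for visit in use_visits:
                ev = eng.events_per_subject(visit)
                ok = eng.evaluable(visit)
                ids = tuple(np.asarray(eng.subject_ids, dtype=object)[ok])
                counts = tuple(int(c) for c in ev[ok])
                summaries.append(
                    ESVisitSummary(
                        visit=visit,
                        threshold=tau,
                        item_set=item_set,
                        stability_rule=stability_rule,
                        n_evaluable=int(ok.sum()),
                        n_es_patients=int((ev[ok] >= 1).sum()),
                        subject_ids=ids,
                        es_events_per_subject=counts,
                    )
                )
    return summaries


def frequency_dataframe(summaries: list[ESVisitSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per visit/threshold/item set)."""
    return pd.DataFrame(
        {
            "item_set": [s.item_set for s in summaries],
            "threshold": [s.threshold for s in summaries],
            "visit": [s.visit for s in summaries],
            "n": [s.n_evaluable for s in summaries],
            "es_patients": [s.n_es_patients for s in summaries],
            "percent": [s.percent for s in summaries],
            "mean_events": [s.mean_events for s in summaries],
        }
    )


def endorsed_item_count(
    ds: Dataset, subject: str, visit: str, threshold: int = 1,
    item_set: str = "IB_plus_II",
) -> int:
    """Items at or above threshold at a visit, regardless of baseline status."""
    cfg = ESConfig(threshold=threshold, item_set=item_set)
    eng = ESEngine(ds, cfg)
    s = eng.subject_index(subject)
    v = eng.visit_index(visit)
    return int((eng.cube[s, v, :] >= threshold).sum())


def endorsed_count_table(
    ds: Dataset,
    visits: list[str] | None = None,
    threshold: int = 1,
    item_sets: tuple[str, ...] = ("IB", "II"),
) -> pd.DataFrame:
    """Mean and SD of the per-subject endorsed-item count at each visit.

    The stability diagnostic: if endorsement simply accumulated, these means
    would grow; response flicker keeps them nearly flat while per-visit ES
    frequency climbs.
    """
    rows = []
    for item_set in item_sets:
        cfg = ESConfig(threshold=threshold, item_set=item_set)
        eng = ESEngine(ds, cfg)
        for visit in visits if visits is not None else eng.visit_codes:
            v = eng.visit_index(visit)
            counts = (eng.cube[:, v, :] >= threshold).sum(axis=1)
            ok = eng.evaluable(visit)
            rows.append(
                {
                    "item_set": item_set,
                    "visit": visit,
                    "n": int(ok.sum()),
                    "mean": float(counts[ok].mean()) if ok.any() else float("nan"),
                    "sd": float(counts[ok].std(ddof=1)) if ok.sum() > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HeatmapMatrix:
    """Subject x visit endorsement grid for one item.

    Cell values: "zero" (score 0), "endorsed" (score >= 1), "missing".
    """

    item: str
    cells: pd.DataFrame  # index subject_id, columns scheduled visit codes

    def to_codes(self) -> pd.DataFrame:
        """Numeric export: 0 = zero, 1 = endorsed, NA = missing."""
        mapping = {"zero": 0, "endorsed": 1, "missing": pd.NA}
        return pd.DataFrame(
            {col: self.cells[col].map(mapping) for col in self.cells.columns},
            index=self.cells.index,
        ).astype("Int64")

    def plot(self, ax=None, path=None):
        """Render the grid (grey = 0, black = endorsed, white = missing)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        codes = self.to_codes().astype("float64").to_numpy()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        cmap = ListedColormap(["#b0b0b0", "#000000"])
        cmap.set_bad("#ffffff")
        ax.imshow(np.ma.masked_invalid(codes), aspect="auto", cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks(range(len(self.cells.columns)), self.cells.columns, rotation=90)
        ax.set_yticks([])
        ax.set_xlabel("visit")
        ax.set_ylabel("subject")
        ax.set_title(f"Item {self.item}")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def heatmap_matrix(ds: Dataset, item: str) -> HeatmapMatrix:
    """Endorsement grid for one item across all subjects and scheduled visits."""
    if item not in ALL_ITEMS:
        raise DomainError(f"unknown item {item!r}")
    visits = [v.code for v in ds.schedule if v.visit_class == "scheduled"]
    sub = ds.scores[(ds.scores["item"] == item) & ds.scores["visit"].isin(visits)]
    grid = pd.DataFrame("missing", index=pd.Index(ds.subject_ids, name="subject_id"),
                        columns=visits)
    present = sub[sub["score"].notna()]
    for _, row in present.iterrows():
        grid.loc[row["subject_id"], row["visit"]] = (
            "zero" if row["score"] == 0 else "endorsed"
        )
    return HeatmapMatrix(item=item, cells=grid)


# ---------------------------------------------------------------------------
# symptomatic therapy


def stx_classify(ds: Dataset, cutoff_months: float = 12.0) -> dict[str, list[str]]:
    """Partition subjects by symptomatic-therapy initiation.

    STx-yes: first dopaminergic therapy before or at ``cutoff_months``;
    STx-no: later than the cutoff, or never.
    """
    t = ds.subjects["stx_time_months"]
    yes = t.notna() & (t <= cutoff_months)
    ids = ds.subjects["subject_id"]
    return {"STx_yes": list(ids[yes]), "STx_no": list(ids[~yes])}


def last_visit_before_stx(
    ds: Dataset,
    subject: str,
    item_set: str = "IB_plus_II",
    cutoff_months: float = 12.0,
) -> Visit | None:
    """Latest post-baseline scheduled visit strictly before STx initiation
    with at least one non-missing item-set score; None if no such visit.

    Only defined for STx-yes subjects (therapy by the cutoff); baseline is
    excluded because ES is undefined there.
    """
    stx_t = ds.stx_time(subject)
    if stx_t is None or stx_t > cutoff_months:
        raise DomainError(f"subject {subject!r} is not STx-yes by {cutoff_months} months")
    cfg = ESConfig(item_set=item_set)
    eng = ESEngine(ds, cfg)
    s = eng.subject_index(subject)
    best: Visit | None = None
    for vi, visit in enumerate(eng.visits):
        if vi == 0 or visit.months >= stx_t:
            continue
        if (~np.isnan(eng.cube[s, vi, :])).any():
            best = visit
    return best
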