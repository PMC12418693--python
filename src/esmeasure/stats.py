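"""Inferential comparisons: proportion tests, location tests, correlations.

Conventions match the R defaults the field habitually reports: proportion
tests are chi-square with Yates continuity correction (switchable), the
t-test is Welch (unequal variances), and the Wilcoxon rank-sum test is exact
for small tie-free samples (combined n <= 20) and a tie-corrected,
continuity-corrected normal approximation otherwise.  No multiple-testing
adjustment is applied anywhere — tables report raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from esmeasure.data_model import Dataset
from esmeasure.exceptions import DomainError, UndefinedCorrelationError
from esmeasure.items import SCORE_BLOCKS
from esmeasure.scoring import ESConfig, ESEngine, round_percent, stx_classify

ES_MEASURES = ("events_per_patient", "es_indicator")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    warning: str | None = None


@dataclass(frozen=True)
class Correlation:
    """A correlation coefficient with its two-sided p-value."""

    r: float
    p_value: float
    method: str
    n: int


@dataclass(frozen=True)
class CorrelationCell:
    """One cell of a correlation table: ES measure vs a summed-score block."""

    visit: str
    score_block: str
    measure: str
    r: float
    p_value: float
    n: int
    available: bool


# ---------------------------------------------------------------------------
# summed scores


def part_sum(ds: Dataset, subject: str, visit: str, block: str) -> float:
    """Sum of the block's item scores at a visit; NaN unless complete.

    Complete-case: a single missing item invalidates the sum (no imputation).
    Blocks: I (= IA+IB), II, III, I_II_III, IB_II.
    """
    frame = part_sum_frame(ds, block)
    try:
        return float(frame.loc[subject, visit])
    except KeyError as exc:
        raise DomainError(f"unknown subject or visit: {exc}") from exc


def part_sum_frame(ds: Dataset, block: str) -> pd.DataFrame:
    """Subject x visit matrix of complete-case block sums (NaN if incomplete)."""
    if block not in SCORE_BLOCKS:
        raise DomainError(f"unknown score block {block!r}; use one of {sorted(SCORE_BLOCKS)}")
    codes = SCORE_BLOCKS[block]
    visits = [v.code for v in ds.schedule if v.visit_class == "scheduled"]
    sub = ds.scores[ds.scores["item"].isin(codes) & ds.scores["visit"].isin(visits)]
    n_s, n_v, n_i = len(ds.subject_ids), len(visits), len(codes)
    cube = np.full((n_s, n_v, n_i), np.nan)
    if len(sub):
        sidx = {s: i for i, s in enumerate(ds.subject_ids)}
        vidx = {c: i for i, c in enumerate(visits)}
        iidx = {c: i for i, c in enumerate(codes)}
        cube[
            sub["subject_id"].map(sidx).to_numpy(),
            sub["visit"].map(vidx).to_numpy(),
            sub["item"].map(iidx).to_numpy(),
        ] = sub["score"].astype("float64").to_numpy()
    complete = ~np.isnan(cube).any(axis=2)
    sums = np.where(complete, np.nansum(cube, axis=2), np.nan)
    return pd.DataFrame(sums, index=pd.Index(ds.subject_ids, name="subject_id"),
                        columns=visits)


# ---------------------------------------------------------------------------
# elementary tests


def one_sample_prop_test(
    k: int, n: int, p0: float = 0.5, continuity: bool = True
) -> TestResult:
    """Chi-square test of one proportion against ``p0``, two-sided.

    Yates-corrected by default (the correction is capped at ``|k - n*p0|``).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not 0 <= k <= n:
        raise DomainError("k must satisfy 0 <= k <= n")
    dev = abs(k - n * p0)
    cc = min(0.5, dev) if continuity else 0.0
    chi2 = (dev - cc) ** 2 / (n * p0 * (1 - p0))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(chi2, p, "one-sample proportion (chi-square, Yates)", (n,))


def two_sample_prop_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> TestResult:
    """Chi-square test of two independent proportions, two-sided.

    Degenerate pooled margins (all successes or all failures) carry no
    information about a difference: p = 1 is returned with a warning flag.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise DomainError("counts must satisfy 0 <= k <= n, n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any():
        return TestResult(
            0.0, 1.0, "two-sample proportion (chi-square, Yates)", (n1, n2),
            warning="degenerate margin: pooled outcomes are all identical",
        )
    res = sps.chi2_contingency(table, correction=continuity)
    return TestResult(
        float(res.statistic), float(res.pvalue),
        "two-sample proportion (chi-square, Yates)", (n1, n2),
    )


def two_sample_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t-test, two-sided."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each sample must have >= 2 observations")
    if x.std() == 0 and y.std() == 0:
        # no within-group variability: equal means are indistinguishable
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "Welch t-test", (len(x), len(y)),
                              warning="zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "Welch t-test",
                      (len(x), len(y)))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact enumeration when the combined sample is small (n1 + n2 <= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise DomainError("each sample must have >= 1 observation")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"Wilcoxon rank-sum ({method})", (len(x), len(y)))


def _corr(x, y, method: str) -> Correlation:
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DomainError("correlation requires >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return Correlation(float(res.statistic), float(res.pvalue), method, len(x))


def pearson(x: Sequence[float], y: Sequence[float]) -> Correlation:
    """Pearson r with two-sided p via the t transform on n-2 df."""
    return _corr(x, y, "pearson")


def spearman(x: Sequence[float], y: Sequence[float]) -> Correlation:
    """Spearman rank correlation (Pearson on mid-ranks), two-sided p."""
    return _corr(x, y, "spearman")


# ---------------------------------------------------------------------------
# cohort tables


def correlation_table(
    ds: Dataset,
    cfg: ESConfig,
    measure: str = "events_per_patient",
    visits: list[str] | None = None,
    blocks: tuple[str, ...] = ("I", "II", "III", "I_II_III", "IB_II"),
    method: str = "pearson",
) -> list[CorrelationCell]:
    """Correlate a per-subject ES measure with summed scores, per visit/block.

    ``events_per_patient`` is the ES event count; ``es_indicator`` is the
    0/1 ES-patient flag (its correlation with a sum is the point-biserial
    coefficient).  Pairwise complete-case across subjects; a cell with fewer
    than 3 complete pairs, or with a constant measure, is marked unavailable.
    """
    if measure not in ES_MEASURES:
        raise DomainError(f"measure must be one of {ES_MEASURES}")
    eng = ESEngine(ds, cfg)
    use_visits = visits if visits is not None else eng.visit_codes[1:]
    frames = {b: part_sum_frame(ds, b) for b in blocks}
    cells: list[CorrelationCell] = []
    for visit in use_visits:
        ev = eng.events_per_subject(visit).astype(float)
        if measure == "es_indicator":
            ev = (ev >= 1).astype(float)
        ev = np.where(eng.evaluable(visit), ev, np.nan)
        for block in blocks:
            sums = frames[block][visit].to_numpy()
            ok = ~(np.isnan(ev) | np.isnan(sums))
            try:
                c = _corr(ev[ok], sums[ok], method)
                cells.append(CorrelationCell(visit, block, measure, c.r,
                                             c.p_value, c.n, True))
            except (DomainError, UndefinedCorrelationError):
                cells.append(CorrelationCell(visit, block, measure,
                                             float("nan"), float("nan"),
                                             int(ok.sum()), False))
    return cells


def correlation_dataframe(cells: list[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "visit": [c.visit for c in cells],
            "score_block": [c.score_block for c in cells],
            "measure": [c.measure for c in cells],
            "r": [c.r for c in cells],
            "p_value": [c.p_value for c in cells],
            "n": [c.n for c in cells],
            "available": [c.available for c in cells],
        }
    )


@dataclass
class STxTables:
    """ES frequency and ES event-count comparisons by symptomatic therapy."""

    proportions: pd.DataFrame
    events: pd.DataFrame


def _group_stats(counts: np.ndarray) -> tuple[int, float, float]:
    n = len(counts)
    mean = float(np.mean(counts)) if n else float("nan")
    sd = float(np.std(counts, ddof=1)) if n > 1 else float("nan")
    return n, mean, sd


def stx_comparison_tables(
    ds: Dataset,
    cfg: ESConfig,
    cutoff_months: float = 12.0,
    visits: list[str] | None = None,
) -> STxTables:
    """Per-visit ES comparisons between STx-yes and STx-no subjects.

    ``proportions``: ES-patient counts per group with the two-sample
    proportion p-value.  ``events``: per-subject ES event count mean (SD)
    per group with Welch-t and Wilcoxon p-values.  Each table ends with a
    "Last Visit Before STx" row evaluating STx-yes subjects at their final
    assessment preceding therapy.  Unavailable entries are NaN.
    """
    from esmeasure.scoring import last_visit_before_stx

    eng = ESEngine(ds, cfg)
    use_visits = visits if visits is not None else eng.visit_codes[1:]
    groups = stx_classify(ds, cutoff_months)
    yes = np.isin(eng.subject_ids, groups["STx_yes"])
    no = ~yes

    prop_rows, event_rows = [], []
    for visit in use_visits:
        ev = eng.events_per_subject(visit)
        ok = eng.evaluable(visit)
        ev_y, ev_n = ev[ok & yes], ev[ok & no]
        n_y, mean_y, sd_y = _group_stats(ev_y)
        n_n, mean_n, sd_n = _group_stats(ev_n)
        k_y, k_n = int((ev_y >= 1).sum()), int((ev_n >= 1).sum())
        if n_y >= 1 and n_n >= 1:
            p_prop = two_sample_prop_test(k_y, n_y, k_n, n_n).p_value
        else:
            p_prop = float("nan")
        try:
            p_t = two_sample_t_test(ev_y, ev_n).p_value
            p_w = wilcoxon_rank_sum(ev_y, ev_n).p_value
        except DomainError:
            p_t = p_w = float("nan")
        prop_rows.append(
            {"visit": visit, "n_stx_yes": n_y, "es_stx_yes": k_y,
             "pct_stx_yes": round_percent(k_y, n_y) if n_y else float("nan"),
             "n_stx_no": n_n, "es_stx_no": k_n,
             "pct_stx_no": round_percent(k_n, n_n) if n_n else float("nan"),
             "p_value": p_prop}
        )
        event_rows.append(
            {"visit": visit, "n_stx_yes": n_y, "mean_stx_yes": mean_y,
             "sd_stx_yes": sd_y, "n_stx_no": n_n, "mean_stx_no": mean_n,
             "sd_stx_no": sd_n, "p_t": p_t, "p_wilcoxon": p_w}
        )

    # last assessment before therapy, STx-yes subjects only
    lv_events = []
    for sid in groups["STx_yes"]:
        visit = last_visit_before_stx(ds, sid, item_set=cfg.item_set,
                                      cutoff_months=cutoff_months)
        if visit is not None:
            s = eng.subject_index(sid)
            lv_events.append(int(eng.event_matrix(visit.code)[s].sum()))
    lv = np.asarray(lv_events)
    n_lv, mean_lv, sd_lv = _group_stats(lv)
    k_lv = int((lv >= 1).sum()) if n_lv else 0
    prop_rows.append(
        {"visit": "last_visit_before_stx", "n_stx_yes": n_lv, "es_stx_yes": k_lv,
         "pct_stx_yes": round_percent(k_lv, n_lv) if n_lv else float("nan"),
         "n_stx_no": 0, "es_stx_no": 0, "pct_stx_no": float("nan"),
         "p_value": float("nan")}
    )
    event_rows.append(
        {"visit": "last_visit_before_stx", "n_stx_yes": n_lv,
         "mean_stx_yes": mean_lv, "sd_stx_yes": sd_lv, "n_stx_no": 0,
         "mean_stx_no": float("nan"), "sd_stx_no": float("nan"),
         "p_t": float("nan"), "p_wilcoxon": float("nan")}
    )
    return STxTables(pd.DataFrame(prop_rows), pd.DataFrame(event_rows))
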