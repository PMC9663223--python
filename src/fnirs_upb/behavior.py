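"""Behavioral and self-report statistics: group summaries and pooled t-tests.

The study compares the two task conditions with independent-samples Student
t-tests (pooled variance, df = n1 + n2 − 2); the within-subject structure is
deliberately ignored to mirror the original analysis.  ``t_from_summary``
works from printed group summaries (mean, SD, n) so published tables can be
checked directly; the raw-data paths reduce to it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(float(np.mean(values)), float(np.std(values, ddof=1)), values.size)

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled-variance independent-samples t-test from group summaries.

    t = (µ1 − µ2) / sqrt(s_p²·(1/n1 + 1/n2)) with
    s_p² = ((n1−1)σ1² + (n2−1)σ2²)/(n1+n2−2); df = n1 + n2 − 2; two-sided p.
    Zero pooled variance with equal means yields t = 0 (identical groups);
    with unequal means it is an error (the statistic diverges).
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)


def _validate_counts(b: pd.DataFrame, max_count: int = 4) -> None:
    if ((b["count"] < 0) | (b["count"] > max_count)).any():
        raise ValueError(f"purchase counts must lie in 0..{max_count}")


def purchase_summary(b: pd.DataFrame, max_count: int = 4) -> dict:
    """Summarize a purchase-count table (columns subject/condition/category/count).

    Returns per-condition subject totals with mean ± SD, the pooled t-test on
    the totals, and per-category sums, per-subject-count SDs and t-tests.
    Per-category rows report both the sum across subjects and the SD of the
    per-subject counts (the two quantities published side by side).
    """
    _validate_counts(b, max_count)
    totals = (
        b.groupby(["condition", "subject"], sort=True)["count"].sum().unstack(0)
    )
    groups = {c: GroupSummary.from_values(totals[c].to_numpy()) for c in CONDITIONS}
    total_test = t_from_summary(groups["Task1"], groups["Task2"])

    categories = {}
    for cat, sub in b.groupby("category", sort=False):
        per = {}
        for cond in CONDITIONS:
            vals = sub.loc[sub["condition"] == cond, "count"].to_numpy(float)
            per[cond] = {
                "sum": float(vals.sum()),
                "count_sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        g1 = sub.loc[sub["condition"] == "Task1", "count"].to_numpy(float)
        g2 = sub.loc[sub["condition"] == "Task2", "count"].to_numpy(float)
        degenerate = np.std(g1, ddof=1) == 0 and np.std(g2, ddof=1) == 0 and np.mean(
            g1
        ) == np.mean(g2)
        if degenerate:
            per["t_test"] = None  # flagged: undefined for identical constant groups
        else:
            per["t_test"] = t_from_summary(
                GroupSummary.from_values(g1), GroupSummary.from_values(g2)
            )
        categories[cat] = per
    return {
        "totals": {c: groups[c] for c in CONDITIONS},
        "total_t_test": total_test,
        "categories": categories,
    }


def likert_summary(l: pd.DataFrame) -> dict:
    """Summarize a Likert table (columns subject/condition/item/response).

    A subject's score per condition is the mean over items; groups are then
    compared with the pooled t-test.
    """
    if ((l["response"] < 1) | (l["response"] > 5)).any():
        raise ValueError("Likert responses must lie in 1..5")
    scores = (
        l.groupby(["condition", "subject"], sort=True)["response"].mean().unstack(0)
    )
    groups = {c: GroupSummary.from_values(scores[c].to_numpy()) for c in CONDITIONS}
    if groups["Task1"].sd == 0 and groups["Task2"].sd == 0 and (
        groups["Task1"].mean == groups["Task2"].mean
    ):
        test = TTestResult(t=0.0, df=groups["Task1"].n + groups["Task2"].n - 2, p=1.0)
    else:
        test = t_from_summary(groups["Task1"], groups["Task2"])
    return {"groups": groups, "t_test": test, "scores": scores}
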