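"""Per-condition statistics over per-cell particle counts.

The unit of analysis is the single cell: each condition/time point is
summarized as mean ± SEM over its cells, and pairs of groups are compared
with the unpaired two-sample Student's t-test (pooled variance by default;
Welch behind a flag). Significance flags: ``*`` for 0.01 ≤ p < 0.05 and
``**`` for p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionSummary",
    "PairwiseTest",
    "summarize_condition",
    "t_test_unpaired",
    "summarize_dataset",
    "plot_condition_bars",
]


@dataclass
class ConditionSummary:
    condition: str
    time_h: float
    n_cells: int
    mean_count: float
    sem_count: float | None  # None when n == 1 (undefined)


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    stars: str  # "ns" | "*" | "**"


def stars_for_p(p: float) -> str:
    """Significance flag: ``**`` if p < 0.01, ``*`` if 0.01 ≤ p < 0.05, else ``ns``."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_condition(
    counts, condition: str = "", time_h: float = 0.0
) -> ConditionSummary:
    """Mean ± SEM of per-cell counts; SEM uses the n−1 sample sd over √n."""
    counts = np.asarray(list(counts), dtype=np.float64)
    if counts.size == 0:
        raise ValueError("empty count list")
    mean = float(counts.mean())
    if counts.size == 1:
        sem = None
    else:
        sem = float(counts.std(ddof=1) / math.sqrt(counts.size))
    return ConditionSummary(
        condition=condition,
        time_h=float(time_h),
        n_cells=int(counts.size),
        mean_count=mean,
        sem_count=sem,
    )


def t_test_unpaired(
    a, b, label_a: str = "a", label_b: str = "b", welch: bool = False
) -> PairwiseTest:
    """Unpaired two-sample t-test (classical pooled-variance Student by default).

    Two-sided p. Degenerate case: both groups constant with equal means →
    t = 0, p = 1 by convention.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 cells")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return PairwiseTest(label_a, label_b, 0.0, 1.0, "ns")
        return PairwiseTest(label_a, label_b, math.inf, 0.0, "**")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return PairwiseTest(label_a, label_b, float(t), float(p), stars_for_p(float(p)))


def summarize_dataset(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a per-cell table (columns condition, time_h, count) per group."""
    rows = []
    for (cond, t), grp in table.groupby(["condition", "time_h"], sort=True):
        s = summarize_condition(grp["count"], cond, t)
        rows.append(
            {
                "condition": s.condition,
                "time_h": s.time_h,
                "n_cells": s.n_cells,
                "mean_count": s.mean_count,
                "sem_count": np.nan if s.sem_count is None else s.sem_count,
            }
        )
    return pd.DataFrame(rows)


def plot_condition_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Grouped bar chart of mean ± SEM per time point, one bar set per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted(summary["condition"].unique())
    times = sorted(summary["time_h"].unique())
    width = 0.8 / max(1, len(conditions))
    fig, ax = plt.subplots(figsize=(6, 4))
    shades = ["white", "0.4", "0.7", "0.2"]
    for i, cond in enumerate(conditions):
        sub = summary[summary["condition"] == cond].set_index("time_h")
        means = [sub["mean_count"].get(t, np.nan) for t in times]
        sems = [sub["sem_count"].get(t, 0.0) for t in times]
        x = np.arange(len(times)) + (i - (len(conditions) - 1) / 2) * width
        ax.bar(
            x, means, width=width, yerr=sems, capsize=3,
            color=shades[i % len(shades)], edgecolor="black", label=str(cond),
        )
    ax.set_xticks(np.arange(len(times)))
    ax.set_xticklabels([f"{t:g}" for t in times])
    ax.set_xlabel("incubation time (h)")
    ax.set_ylabel("particles per cell (mean ± SEM)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
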