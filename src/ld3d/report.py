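"""Line- and group-level aggregation: means +/- SD and HO vs LO comparison.

Each breeding line contributes replicate measurements (one per imaged
field); a line is summarized as mean and sample SD (n-1 denominator), and
groups are compared on their line means with Welch's unequal-variance
two-sample t test (an exhaustive permutation test is available as an
alternative). Group means are unweighted means of line means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LineSummary", "GroupComparison", "summarize_line", "compare_groups",
           "export_reports"]


@dataclass
class LineSummary:
    line_id: str
    group: str
    metric: str
    values: tuple
    n: int
    mean: float
    sd: float  # NaN (missing) when n < 2


@dataclass
class GroupComparison:
    metric: str
    ho_line_means: tuple
    lo_line_means: tuple
    ho_mean: float
    lo_mean: float
    difference: float
    statistic: float
    pvalue: float
    test: str = "welch"


def summarize_line(values, line_id: str = "", group: str = "",
                   metric: str = "") -> LineSummary:
    """Mean and sample SD of a line's replicate measurements.

    The SD uses the n-1 denominator and is NaN for a single replicate.
    """
    vals = tuple(float(v) for v in values)
    if len(vals) == 0:
        raise ValueError("summarize_line requires at least one value")
    arr = np.asarray(vals)
    sd = float(np.std(arr, ddof=1)) if len(vals) >= 2 else float("nan")
    return LineSummary(line_id=line_id, group=group, metric=metric, values=vals,
                       n=len(vals), mean=float(arr.mean()), sd=sd)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: both groups constant; defined by the difference alone
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _permutation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = a.mean() - b.mean()
    idx = range(len(pooled))
    hits = total = 0
    for pick in combinations(idx, n_a):
        pick = set(pick)
        ga = pooled[[i in pick for i in idx]]
        gb = pooled[[i not in pick for i in idx]]
        if abs(ga.mean() - gb.mean()) >= abs(observed) - 1e-12:
            hits += 1
        total += 1
    return float(observed), hits / total


def compare_groups(ho, lo, test: str = "welch") -> GroupComparison:
    """Compare HO and LO line means for one metric.

    ``ho`` and ``lo`` are lists of :class:`LineSummary` for the same metric.
    The statistic is computed on line means; each line's replicate values
    remain available in the summaries.
    """
    if not ho or not lo:
        raise ValueError("both groups need at least one line")
    metric = ho[0].metric
    a = np.asarray([s.mean for s in ho], dtype=float)
    b = np.asarray([s.mean for s in lo], dtype=float)
    if test == "welch":
        statistic, pvalue = _welch(a, b)
    elif test == "permutation":
        statistic, pvalue = _permutation(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        ho_line_means=tuple(a.tolist()),
        lo_line_means=tuple(b.tolist()),
        ho_mean=float(a.mean()),
        lo_mean=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        statistic=statistic,
        pvalue=pvalue,
        test=test,
    )


def export_reports(summaries, comparisons, out_dir, sizes_long: pd.DataFrame | None = None):
    """Write line_summaries.csv, group_comparison.csv and (optionally)
    sizes_long.csv with deterministic row order (group, line, metric).

    Empty inputs produce headers-only files. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    line_rows = [{
        "group": s.group, "line_id": s.line_id, "metric": s.metric,
        "n": s.n, "mean": s.mean, "sd": s.sd,
        "values": ";".join(repr(v) for v in s.values),
    } for s in summaries]
    lines = pd.DataFrame(line_rows, columns=["group", "line_id", "metric",
                                             "n", "mean", "sd", "values"])
    lines = lines.sort_values(["group", "line_id", "metric"], kind="stable")
    lines_path = out_dir / "line_summaries.csv"
    lines.to_csv(lines_path, index=False)

    cmp_rows = [{
        "metric": c.metric, "ho_mean": c.ho_mean, "lo_mean": c.lo_mean,
        "difference": c.difference, "statistic": c.statistic,
        "pvalue": c.pvalue, "test": c.test,
    } for c in comparisons]
    comps = pd.DataFrame(cmp_rows, columns=["metric", "ho_mean", "lo_mean",
                                            "difference", "statistic", "pvalue", "test"])
    comps = comps.sort_values("metric", kind="stable")
    comps_path = out_dir / "group_comparison.csv"
    comps.to_csv(comps_path, index=False)

    paths = [lines_path, comps_path]
    if sizes_long is not None:
        sizes_path = out_dir / "sizes_long.csv"
        sizes_long.to_csv(sizes_path, index=False)
        paths.append(sizes_path)
    return paths
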