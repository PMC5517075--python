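"""Group-comparison statistics and report assembly.

Comparisons use the classic pooled-variance unpaired two-tailed Student's
t-test (Welch's correction available behind a flag), with standard errors
s.d./sqrt(n) and significance stars at *P<0.05, 0.001<**P<0.01, ***P<0.001
(strict inequalities as printed).  No multiple-testing correction is
applied; a report that runs more than five comparisons carries a flag
noting it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "GroupComparison",
    "students_t",
    "percent_difference",
    "star_code",
    "build_report",
]


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** 0.001<p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    standard_errors: tuple[float, float]
    t_statistic: float
    p_value: float
    star: str
    percent_difference: float
    degenerate: bool = False


def students_t(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed Student's t-test between two samples.

    Pooled-variance t with df = n_a + n_b - 2 by default; ``welch=True``
    switches to Welch's unequal-variance form.  With zero pooled variance
    the test degenerates: equal means give p = 1, unequal means are
    flagged degenerate with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("samples must be finite")

    means = (float(a.mean()), float(b.mean()))
    ses = (
        float(a.std(ddof=1) / np.sqrt(len(a))),
        float(b.std(ddof=1) / np.sqrt(len(b))),
    )
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    degenerate = False
    if pooled_var == 0 and not welch:
        if means[0] == means[1]:
            t, p = 0.0, 1.0
        else:
            t, p, degenerate = np.inf if means[0] > means[1] else -np.inf, 0.0, True
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)

    pct = (
        percent_difference(means[0], means[1]) if means[0] > 0 else float("nan")
    )
    return GroupComparison(
        labels=labels,
        n=(len(a), len(b)),
        means=means,
        standard_errors=ses,
        t_statistic=t,
        p_value=p,
        star=star_code(p),
        percent_difference=pct,
        degenerate=degenerate,
    )


def percent_difference(mean_ctrl: float, mean_other: float) -> float:
    """Percent difference of a group mean relative to control:
    ``(mean_other - mean_ctrl) / mean_ctrl * 100``.

    Positive values are elongations/increases; a reduction reported as
    "x% shorter" corresponds to a value of -x here.
    """
    if not mean_ctrl > 0:
        raise ParameterError("control mean must be > 0")
    return (mean_other - mean_ctrl) / mean_ctrl * 100.0


def _box_stats(x: pd.Series) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
    }


@dataclass
class MeasurementReport:
    """Tidy per-object measurements plus group summaries and comparisons."""

    measurements: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries.to_dict(orient="records"),
            "comparisons": {
                k: {
                    "labels": list(c.labels),
                    "n": list(c.n),
                    "means": list(c.means),
                    "standard_errors": list(c.standard_errors),
                    "t": c.t_statistic,
                    "p": c.p_value,
                    "star": c.star,
                    "percent_difference": c.percent_difference,
                }
                for k, c in self.comparisons.items()
            },
            "flags": list(self.flags),
        }


def build_report(
    measurements: pd.DataFrame,
    group_col: str = "group",
    metrics: list[str] | None = None,
    control_group: str | None = None,
) -> MeasurementReport:
    """Summarize a tidy measurement table by group and compare groups.

    For every metric column: per-group n, mean, s.e. and box-plot summary
    stats (median, quartiles, whiskers at 1.5*IQR).  With exactly two
    groups each metric also gets a pooled t-test; ``control_group`` fixes
    which group is the reference for the percent difference.
    """
    flags: list[str] = []
    if measurements.empty:
        warnings.warn("empty measurement table; empty report")
        return MeasurementReport(
            measurements,
            pd.DataFrame(columns=[group_col, "metric", "n", "mean", "se"]),
            flags=["empty"],
        )
    if group_col not in measurements.columns:
        raise ParameterError(f"missing group column {group_col!r}")
    if metrics is None:
        metrics = [
            c
            for c in measurements.columns
            if c != group_col and pd.api.types.is_numeric_dtype(measurements[c])
        ]
    groups = sorted(measurements[group_col].unique())
    if control_group is not None:
        if control_group not in groups:
            raise ParameterError(
                f"unknown control group {control_group!r}; have {groups}"
            )
        groups = [control_group] + [g for g in groups if g != control_group]

    rows = []
    comparisons: dict[str, GroupComparison] = {}
    for metric in metrics:
        for g in groups:
            x = measurements.loc[measurements[group_col] == g, metric].dropna()
            row = {
                "group": g,
                "metric": metric,
                "n": len(x),
                "mean": float(x.mean()) if len(x) else np.nan,
                "se": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
            }
            if len(x):
                row.update(_box_stats(x))
            rows.append(row)
        if len(groups) == 2:
            a = measurements.loc[measurements[group_col] == groups[0], metric].dropna()
            b = measurements.loc[measurements[group_col] == groups[1], metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                comparisons[metric] = students_t(
                    a.to_numpy(), b.to_numpy(), labels=(groups[0], groups[1])
                )
    if len(comparisons) > 5:
        flags.append(
            f"{len(comparisons)} comparisons in one run with no multiple-testing "
            "correction"
        )
    return MeasurementReport(measurements, pd.DataFrame(rows), comparisons, flags)
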