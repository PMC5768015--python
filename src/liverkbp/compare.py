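"""Paired comparison of two plan cohorts.

Given per-patient metric panels for two planning arms (e.g. manual vs.
automated plans of the same patients), this module produces the standard
comparison report: paired two-sided t-tests per metric with means and SDs
per arm, blind-review vote tallies, the monitor-unit increase ratio and
mean-DVH overlay plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import STANDARD_METRICS, CumulativeDVH, PlanMetrics, mean_dvh_curve
from .errors import DegenerateTestError, DomainError

__all__ = [
    "TTestResult",
    "PairedComparisonRow",
    "paired_t_test",
    "compare_plans",
    "comparison_report",
    "vote_tally",
    "mu_increase_ratio",
    "plot_mean_dvh_overlay",
]

ALPHA = 0.05  # two-sided significance cutoff


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int


@dataclass(frozen=True)
class PairedComparisonRow:
    """One metric's row of the comparison table."""

    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired t-test on a - b with df = n - 1.

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (including identical arms), where t is undefined — this is an
    explicit error, never a silent p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError(f"paired vectors must be 1D of equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise DomainError("need at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        raise DegenerateTestError("differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=a.size - 1)


def compare_plans(
    metrics_a: Sequence[PlanMetrics],
    metrics_b: Sequence[PlanMetrics],
    metric_names: Sequence[str] | None = None,
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[PairedComparisonRow]:
    """Per-metric paired comparison of two plan arms for the same patients.

    Arms must carry identical patient ids in order (pairing is by patient).
    A metric whose differences have zero variance yields a row flagged
    ``degenerate`` with NaN statistics and ``significant=False`` instead of
    aborting the whole table.  ``holm`` applies a Holm step-down correction
    across metrics; the default mirrors common practice of reporting
    uncorrected per-metric p-values.
    """
    ids_a = [m.patient_id for m in metrics_a]
    ids_b = [m.patient_id for m in metrics_b]
    if ids_a != ids_b:
        raise DomainError("patient ids differ between arms; cannot pair plans")
    if metric_names is None:
        metric_names = STANDARD_METRICS
    rows = []
    for name in metric_names:
        a = np.array([m[name] for m in metrics_a], dtype=float)
        b = np.array([m[name] for m in metrics_b], dtype=float)
        try:
            res = paired_t_test(a, b)
            rows.append(
                PairedComparisonRow(
                    metric=name,
                    mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                    mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                    t=res.t, p=res.p, significant=bool(res.p < alpha),
                )
            )
        except DegenerateTestError:
            rows.append(
                PairedComparisonRow(
                    metric=name,
                    mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                    mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                    t=float("nan"), p=float("nan"),
                    significant=False, degenerate=True,
                )
            )
    if holm:
        rows = _apply_holm(rows, alpha)
    return rows


def _apply_holm(rows: list[PairedComparisonRow], alpha: float) -> list[PairedComparisonRow]:
    testable = [r for r in rows if not r.degenerate]
    order = np.argsort([r.p for r in testable])
    m = len(testable)
    decisions: dict[str, bool] = {}
    alive = True
    for rank, idx in enumerate(order):
        row = testable[idx]
        reject = alive and row.p < alpha / (m - rank)
        alive = alive and reject
        decisions[row.metric] = reject
    return [
        PairedComparisonRow(**{**r.__dict__, "significant": decisions.get(r.metric, False)})
        for r in rows
    ]


def comparison_report(rows: Sequence[PairedComparisonRow]) -> pd.DataFrame:
    """Comparison table as a DataFrame ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "mean_a": r.mean_a, "sd_a": r.sd_a,
                "mean_b": r.mean_b, "sd_b": r.sd_b,
                "t": r.t, "p": r.p,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in rows
        ]
    )


def vote_tally(votes: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Per-physician percentage splits of a blind plan review.

    ``votes[i][j]`` is physician i's verdict on patient j: one of ``'A'``
    (arm A better), ``'B'`` (arm B better) or ``'tie'``.  Percentages are
    kept as exact rationals (:class:`fractions.Fraction`) so each row sums
    to exactly 100; they compare equal to floats and format naturally.
    """
    if len(votes) == 0 or any(len(row) == 0 for row in votes):
        raise DomainError("vote matrix must be non-empty")
    records = []
    for i, row in enumerate(votes):
        bad = [v for v in row if v not in ("A", "B", "tie")]
        if bad:
            raise DomainError(f"unknown vote categories {bad}; use 'A', 'B' or 'tie'")
        n = len(row)
        pct = {
            cat: Fraction(sum(v == cat for v in row) * 100, n)
            for cat in ("A", "B", "tie")
        }
        assert sum(pct.values()) == 100
        records.append(
            {
                "physician": i + 1,
                "pct_a_better": pct["A"],
                "pct_b_better": pct["B"],
                "pct_comparable": pct["tie"],
            }
        )
    return pd.DataFrame(records)


def mu_increase_ratio(mu_a, mu_b, per_patient: bool = False) -> float:
    """Percentage increase of arm A monitor units over arm B.

    Default convention: ratio of cohort means,
    100·(mean(a) - mean(b)) / mean(b).  With ``per_patient=True`` the mean of
    per-patient ratios 100·(a_i - b_i)/b_i is returned instead.
    """
    a = np.asarray(mu_a, dtype=float)
    b = np.asarray(mu_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("MU vectors must be 1D of equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("monitor units must be positive")
    if per_patient:
        return float(np.mean(100.0 * (a - b) / b))
    return float(100.0 * (a.mean() - b.mean()) / b.mean())


def plot_mean_dvh_overlay(
    dvhs_a: Mapping[str, Sequence[CumulativeDVH]],
    dvhs_b: Mapping[str, Sequence[CumulativeDVH]],
    path,
    label_a: str = "arm A",
    label_b: str = "arm B",
) -> None:
    """Overlay cohort-mean DVHs per structure: solid arm A, dashed arm B."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    structures = sorted(set(dvhs_a) & set(dvhs_b))
    if not structures:
        raise DomainError("no common structures between arms")
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = plt.cm.tab10(np.linspace(0, 1, len(structures)))
    for color, name in zip(colors, structures):
        mean_a = mean_dvh_curve(list(dvhs_a[name]))
        mean_b = mean_dvh_curve(list(dvhs_b[name]))
        ax.plot(mean_a.dose_axis, 100 * mean_a.rel_volume, "-", color=color, label=name)
        ax.plot(mean_b.dose_axis, 100 * mean_b.rel_volume, "--", color=color)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Relative volume (%)")
    ax.set_title(f"Mean DVH: {label_a} (solid) vs {label_b} (dashed)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
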