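"""Cohort-level statistics: paired arm comparisons, deviation counting tables,
relative-difference series, and the small/large PTV-volume stratification.

Arm comparisons use the classical two-sided paired t-test with no
multiple-testing correction; the volume stratification compares per-patient
relative differences between strata with an unpaired two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .guidelines import (
    VOLUME_INDEPENDENT_METRICS,
    VOLUME_SPECIFIC_METRICS,
    GuidelineSet,
    classify_plan,
)
from .plan import PlanMetrics

__all__ = [
    "PairedTResult",
    "paired_t",
    "compare_arms",
    "deviation_count_table",
    "relative_difference",
    "stratify_by_volume",
    "COMPARISON_METRICS",
]

COMPARISON_METRICS = (
    "d95_pct",
    "v100_pct",
    "dmin_pct",
    "v90_pct",
    "rx_over_dmax",
    "v105_pct",
    "ci",
    "d2cm_prime",
    "r50_prime",
    "mu_total",
)


@dataclass(frozen=True)
class PairedTResult:
    t: float | None
    df: int
    p: float | None
    n: int
    mean_difference: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test on aligned value series.

    Zero-variance differences are flagged as degenerate with no p-value
    rather than reported as infinitely significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"pairing error: lengths {x.size} and {y.size} differ")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = y - x
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTResult(
            t=None, df=n - 1, p=None, n=n, mean_difference=mean_diff, degenerate=True
        )
    res = stats.ttest_rel(y, x)
    return PairedTResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), n=n,
        mean_difference=mean_diff,
    )


def _aligned_arms(cohort: pd.DataFrame, arm_a: str, arm_b: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = cohort[cohort["arm"] == arm_a].set_index("patient_id").sort_index()
    b = cohort[cohort["arm"] == arm_b].set_index("patient_id").sort_index()
    common = a.index.intersection(b.index)
    missing = a.index.symmetric_difference(b.index)
    if len(missing) > 0:
        raise ValueError(f"unpaired patients between arms: {sorted(missing)}")
    return a.loc[common], b.loc[common]


def compare_arms(cohort: pd.DataFrame, arm_a: str = "plan", arm_b: str = "recalculated",
                 metrics: tuple[str, ...] = COMPARISON_METRICS) -> pd.DataFrame:
    """Per-metric arm means, mean difference, and paired t-test summary."""
    a, b = _aligned_arms(cohort, arm_a, arm_b)
    rows = []
    for metric in metrics:
        res = paired_t(a[metric], b[metric])
        rows.append(
            {
                "metric": metric,
                f"mean_{arm_a}": float(a[metric].mean()),
                f"mean_{arm_b}": float(b[metric].mean()),
                "mean_difference": res.mean_difference,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n": res.n,
                "significant": res.significant,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _metrics_from_row(row: pd.Series) -> PlanMetrics:
    return PlanMetrics(
        ptv_cc=row["ptv_cc"],
        d95_pct=row["d95_pct"],
        v100_pct=row["v100_pct"],
        v90_pct=row["v90_pct"],
        dmin_pct=row["dmin_pct"],
        dmax_pct=row["dmax_pct"],
        rx_over_dmax=row["rx_over_dmax"],
        v105_pct=row["v105_pct"],
        ci=row["ci"],
        r50=row["r50"],
        d2cm_pct=row["d2cm_pct"],
        d2cm_prime=row["d2cm_prime"],
        r50_prime=row["r50_prime"],
        mu_total=row["mu_total"],
        island=row.get("island"),
    )


def deviation_count_table(cohort: pd.DataFrame, gset: GuidelineSet,
                          include_volume_independent: bool = True) -> pd.DataFrame:
    """Minor/major deviation counts per metric, arm, and island subgroup.

    Volume-specific metrics contribute minor and major counts; volume-
    independent deviations are counted in the minor column (pass/fail
    criteria have no major grade). Percentages are per arm size.
    """
    rows = []
    subgroups = [("all", cohort)]
    if "island" in cohort.columns and cohort["island"].notna().any():
        subgroups.append(("island", cohort[cohort["island"] == True]))  # noqa: E712
    for subgroup, frame in subgroups:
        for arm, arm_frame in frame.groupby("arm", sort=False):
            counts: dict[str, dict[str, int]] = {}
            for _, row in arm_frame.iterrows():
                report = classify_plan(_metrics_from_row(row), gset)
                for metric, grade in report.volume_specific.items():
                    if grade != "none":
                        counts.setdefault(metric, {"minor": 0, "major": 0})
                        counts[metric][grade] += 1
                if include_volume_independent:
                    for metric, grade in report.volume_independent.items():
                        if grade == "deviation":
                            counts.setdefault(metric, {"minor": 0, "major": 0})
                            counts[metric]["minor"] += 1
                n = len(arm_frame)
            for metric, c in counts.items():
                for severity in ("minor", "major"):
                    if c[severity] > 0:
                        rows.append(
                            {
                                "subgroup": subgroup,
                                "arm": arm,
                                "metric": metric,
                                "severity": severity,
                                "count": c[severity],
                                "pct_of_arm": 100.0 * c[severity] / n,
                            }
                        )
    table = pd.DataFrame(
        rows, columns=["subgroup", "arm", "metric", "severity", "count", "pct_of_arm"]
    )
    return table


def deviation_totals(count_table: pd.DataFrame) -> pd.DataFrame:
    """Total (minor, major) deviation counts per subgroup and arm."""
    if count_table.empty:
        return pd.DataFrame(columns=["subgroup", "arm", "minor", "major"])
    pivot = (
        count_table.pivot_table(
            index=["subgroup", "arm"], columns="severity", values="count",
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=["minor", "major"], fill_value=0)
        .reset_index()
    )
    pivot.columns.name = None
    return pivot


def relative_difference(m_plan: float, m_recalc: float) -> float:
    """(recalculated - plan) / plan; the per-metric fractional shift."""
    if m_plan == 0:
        raise ZeroDivisionError("relative difference undefined for zero baseline")
    return (m_recalc - m_plan) / m_plan


def relative_difference_series(cohort: pd.DataFrame, metric: str,
                               arm_a: str = "plan", arm_b: str = "recalculated",
                               ) -> pd.DataFrame:
    """Per-patient relative difference of one metric vs PTV volume."""
    a, b = _aligned_arms(cohort, arm_a, arm_b)
    rel = (b[metric] - a[metric]) / a[metric]
    return pd.DataFrame(
        {"patient_id": a.index, "ptv_cc": a["ptv_cc"].to_numpy(), "relative_difference": rel.to_numpy()}
    )


def stratify_by_volume(cohort: pd.DataFrame, cutoff_cc: float = 20.0,
                       metrics: tuple[str, ...] = COMPARISON_METRICS,
                       arm_a: str = "plan", arm_b: str = "recalculated") -> pd.DataFrame:
    """Compare relative metric differences between small and large PTVs.

    Partitions patients at ``ptv_cc < cutoff_cc`` vs >= and runs an unpaired
    two-sided t-test on the per-patient relative differences per metric. An
    empty stratum is flagged and the tests are skipped.
    """
    a, b = _aligned_arms(cohort, arm_a, arm_b)
    small = a["ptv_cc"] < cutoff_cc
    rows = []
    for metric in metrics:
        rel = ((b[metric] - a[metric]) / a[metric]).to_numpy()
        rel_small, rel_large = rel[small.to_numpy()], rel[~small.to_numpy()]
        row = {
            "metric": metric,
            "n_small": rel_small.size,
            "n_large": rel_large.size,
            "mean_rel_small": float(rel_small.mean()) if rel_small.size else np.nan,
            "mean_rel_large": float(rel_large.mean()) if rel_large.size else np.nan,
            "t": np.nan,
            "p": np.nan,
            "empty_stratum": rel_small.size == 0 or rel_large.size == 0,
        }
        if not row["empty_stratum"] and rel_small.size > 1 and rel_large.size > 1:
            res = stats.ttest_ind(rel_small, rel_large)
            row["t"], row["p"] = float(res.statistic), float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
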