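"""Cohort statistics: paired tests, deviation tables, and volume stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from sbrtqa import (
    compare_arms,
    deviation_count_table,
    deviation_totals,
    load_guidelines,
    paired_t,
    relative_difference,
    stratify_by_volume,
)
from sbrtqa.cohort import relative_difference_series


def closed_form_paired_t(x, y):
    d = np.asarray(y, float) - np.asarray(x, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    from scipy.stats import t as tdist

    return t, 2.0 * tdist.sf(abs(t), n - 1)


def test_paired_t_examples():
    # symmetric differences [-1, 1, -1, 1] -> t = 0, p = 1
    res = paired_t([1, 1, 1, 1], [0, 2, 0, 2])
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    res = paired_t([0, 0, 0, 0], [1, 2, 3, 4])
    assert res.t == pytest.approx(3.873, abs=1e-3)
    assert res.df == 3
    assert res.p == pytest.approx(0.0305, abs=2e-3)


def test_paired_t_degenerate_and_errors():
    res = paired_t([1, 2, 3], [2, 3, 4])  # all differences equal and nonzero
    assert res.degenerate and res.p is None and res.t is None
    assert res.mean_difference == pytest.approx(1.0)
    with pytest.raises(ValueError, match="pairing"):
        paired_t([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        paired_t([1], [2])


def test_paired_t_matches_closed_form_small_samples():
    rng = np.random.default_rng(21)
    for _ in range(40):
        n = int(rng.integers(3, 11))
        x = rng.normal(size=n)
        y = x + rng.normal(0.3, 1.0, size=n)
        res = paired_t(x, y)
        t_ref, p_ref = closed_form_paired_t(x, y)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)


def test_relative_difference():
    assert relative_difference(95.0, 91.4) == pytest.approx(-0.0379, abs=1e-4)
    assert relative_difference(3.0, 3.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        relative_difference(0.0, 1.0)


def _metric_row(pid, arm, **overrides):
    row = dict(
        patient_id=pid, arm=arm, algorithm="AAA" if arm == "plan" else "AXB",
        ptv_cc=10.0, d95_pct=100.0, v100_pct=95.0, v90_pct=100.0, dmin_pct=92.0,
        dmax_pct=120.0, rx_over_dmax=100.0 / 120.0, v105_pct=6.0, ci=1.1, r50=4.2,
        d2cm_pct=48.0, d2cm_prime=0.96, r50_prime=0.84, mu_total=2000.0, island=False,
    )
    row.update(overrides)
    return row


def test_deviation_count_table_boundary_and_totals():
    gset = load_guidelines("current")
    rows = [
        _metric_row(0, "plan"),                      # fully compliant
        _metric_row(1, "plan", d2cm_pct=50.0),       # exactly at the none-limit: minor
        _metric_row(2, "plan", r50=6.5, ci=1.6),     # R50 major + CI major
    ]
    table = pd.DataFrame(rows)
    counts = deviation_count_table(table, gset)
    d2cm_minor = counts.query("metric == 'd2cm' and severity == 'minor'")["count"].sum()
    assert d2cm_minor == 1
    assert counts.query("metric == 'r50' and severity == 'major'")["count"].sum() == 1
    totals = deviation_totals(counts)
    row = totals[(totals.subgroup == "all") & (totals.arm == "plan")].iloc[0]
    assert row["minor"] == counts.query("severity == 'minor'")["count"].sum()
    assert row["major"] == 2
    # all-compliant cohort -> empty table, zero totals
    clean = pd.DataFrame([_metric_row(0, "plan")])
    assert deviation_count_table(clean, gset).empty


def test_compare_arms_and_relative_series():
    rng = np.random.default_rng(5)
    rows = []
    for pid in range(8):
        v = float(rng.uniform(8, 40))
        rows.append(_metric_row(pid, "plan", ptv_cc=v))
        rows.append(_metric_row(pid, "recalculated", ptv_cc=v,
                                d95_pct=100.0 * float(rng.normal(0.982, 0.01)),
                                ci=1.1 * float(rng.normal(0.93, 0.02))))
    table = pd.DataFrame(rows)
    summary = compare_arms(table)
    d95 = summary[summary.metric == "d95_pct"].iloc[0]
    assert d95["n"] == 8
    assert d95["mean_difference"] < 0
    assert 0.0 <= d95["p"] <= 1.0
    series = relative_difference_series(table, "ci")
    assert len(series) == 8
    assert (series["relative_difference"] < 0).all()


def test_stratify_by_volume():
    rows = []
    for pid, vol in enumerate([7.58, 10.0, 12.0, 74.06, 30.0, 25.0]):
        effect = 0.9 if vol < 20 else 0.99
        rows.append(_metric_row(pid, "plan", ptv_cc=vol))
        rows.append(_metric_row(pid, "recalculated", ptv_cc=vol, ci=1.1 * effect))
    table = pd.DataFrame(rows)
    strata = stratify_by_volume(table, cutoff_cc=20.0)
    ci_row = strata[strata.metric == "ci"].iloc[0]
    assert ci_row["n_small"] == 3 and ci_row["n_large"] == 3
    assert ci_row["mean_rel_small"] < ci_row["mean_rel_large"]
    assert not ci_row["empty_stratum"]
    # all volumes in one stratum: flagged, no test
    small_only = table[table.ptv_cc < 20].copy()
    strata2 = stratify_by_volume(small_only, cutoff_cc=100.0)
    assert strata2["empty_stratum"].all()
    assert strata2["p"].isna().all()


def test_stratify_no_effect_is_nonsignificant():
    rows = []
    for pid, vol in enumerate([5.0, 10.0, 15.0, 25.0, 30.0, 40.0]):
        rows.append(_metric_row(pid, "plan", ptv_cc=vol, ci=1.1))
        rows.append(_metric_row(pid, "recalculated", ptv_cc=vol, ci=1.1 * 0.95))
    strata = stratify_by_volume(pd.DataFrame(rows), cutoff_cc=20.0)
    ci_row = strata[strata.metric == "ci"].iloc[0]
    assert ci_row["mean_rel_small"] == pytest.approx(ci_row["mean_rel_large"])
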