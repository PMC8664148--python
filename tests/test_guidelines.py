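"""Guideline tables, volume interpolation, normalized metrics, and grading."""

import dataclasses

import numpy as np
import pytest

from sbrtqa import (
    PlanMetrics,
    classify_plan,
    d2cm_prime,
    interpolate_thresholds,
    load_guidelines,
    r50_prime,
)

# the published volume-specific threshold table (none-limit / minor-upper)
TABLE_ROWS = [
    (1.8, 1.2, 1.5, 6.0, 7.5, 50.0, 57.0),
    (3.8, 1.2, 1.5, 6.0, 6.5, 50.0, 57.0),
    (7.4, 1.2, 1.5, 5.0, 6.0, 50.0, 58.0),
    (13.2, 1.2, 1.5, 5.0, 5.8, 50.0, 58.0),
    (22.0, 1.2, 1.5, 5.0, 5.5, 54.0, 63.0),
    (34.0, 1.2, 1.5, 4.0, 5.3, 58.0, 68.0),
    (50.0, 1.2, 1.5, 4.0, 5.0, 62.0, 77.0),
    (70.0, 1.2, 1.5, 4.0, 4.8, 66.0, 86.0),
    (95.0, 1.2, 1.5, 3.0, 4.4, 70.0, 89.0),
    (126.0, 1.2, 1.5, 3.0, 4.0, 73.0, 91.0),
    (163.0, 1.2, 1.5, 3.0, 3.7, 77.0, 94.0),
]


@pytest.fixture(scope="module")
def gset():
    return load_guidelines("current")


@pytest.mark.parametrize("row", TABLE_ROWS, ids=lambda r: f"{r[0]}cc")
def test_interpolation_exact_at_tabulated_volumes(gset, row):
    thr = interpolate_thresholds(gset, row[0])
    assert thr.as_tuple() == pytest.approx(row)


def test_interpolation_between_and_outside_rows(gset):
    assert interpolate_thresholds(gset, 10.0).d2cm_none == 50.0
    assert interpolate_thresholds(gset, 28.0).r50_none == pytest.approx(4.5)
    assert interpolate_thresholds(gset, 28.0).d2cm_none == pytest.approx(56.0)
    # clamped outside the tabulated range
    assert interpolate_thresholds(gset, 0.5).as_tuple()[1:] == pytest.approx(TABLE_ROWS[0][1:])
    assert interpolate_thresholds(gset, 500.0).as_tuple()[1:] == pytest.approx(TABLE_ROWS[-1][1:])
    with pytest.raises(ValueError):
        interpolate_thresholds(gset, 0.0)


def test_normalized_metric_worked_example(gset):
    thr = interpolate_thresholds(gset, 10.0)
    assert d2cm_prime(48.0, thr.d2cm_none) == pytest.approx(0.96)
    assert d2cm_prime(50.0, 50.0) == 1.0
    assert d2cm_prime(57.0, 50.0) == pytest.approx(1.14)
    assert r50_prime(4.5, 5.0) == pytest.approx(0.90)
    assert r50_prime(4.66, 4.7) == pytest.approx(0.991489, abs=1e-6)
    with pytest.raises(ValueError):
        d2cm_prime(48.0, 0.0)


def metrics_with(**overrides) -> PlanMetrics:
    base = dict(
        ptv_cc=10.0, d95_pct=100.0, v100_pct=95.0, v90_pct=100.0, dmin_pct=92.0,
        dmax_pct=120.0, rx_over_dmax=100.0 / 120.0, v105_pct=6.0, ci=1.1, r50=4.2,
        d2cm_pct=48.0, d2cm_prime=0.96, r50_prime=0.84, mu_total=2000.0,
    )
    base.update(overrides)
    return PlanMetrics(**base)


def test_classification_boundaries(gset):
    assert classify_plan(metrics_with(d2cm_pct=48.0), gset).volume_specific["d2cm"] == "none"
    assert classify_plan(metrics_with(d2cm_pct=50.0), gset).volume_specific["d2cm"] == "minor"
    # minor band is closed at its upper end; above it is major
    thr = interpolate_thresholds(gset, 10.0)
    at_upper = classify_plan(metrics_with(d2cm_pct=thr.d2cm_minor_upper), gset)
    assert at_upper.volume_specific["d2cm"] == "minor"
    assert classify_plan(metrics_with(d2cm_pct=60.0), gset).volume_specific["d2cm"] == "major"
    assert classify_plan(metrics_with(ci=1.2), gset).volume_specific["ci"] == "minor"
    assert classify_plan(metrics_with(ci=1.51), gset).volume_specific["ci"] == "major"


def test_volume_independent_pass_fail_only(gset):
    report = classify_plan(metrics_with(v100_pct=94.0, v90_pct=98.0, v105_pct=16.0,
                                        rx_over_dmax=0.95), gset)
    assert set(report.volume_independent.values()) == {"deviation"}
    ok = classify_plan(metrics_with(), gset)
    assert set(ok.volume_independent.values()) == {"none"}
    # V105 limit is strict (<15): exactly 15 is a deviation
    assert classify_plan(metrics_with(v105_pct=15.0), gset).volume_independent["v105"] == "deviation"
    # Rx/Dmax bounds are inclusive
    assert classify_plan(metrics_with(rx_over_dmax=0.9), gset).volume_independent["rx_over_dmax"] == "none"
    assert classify_plan(metrics_with(rx_over_dmax=0.6), gset).volume_independent["rx_over_dmax"] == "none"


def test_class_sets_never_mix(gset):
    rng = np.random.default_rng(42)
    for _ in range(300):
        m = metrics_with(
            ptv_cc=float(rng.uniform(1.0, 200.0)),
            ci=float(rng.uniform(0.5, 2.0)),
            r50=float(rng.uniform(2.0, 9.0)),
            d2cm_pct=float(rng.uniform(30.0, 100.0)),
            v100_pct=float(rng.uniform(80, 100)),
            v90_pct=float(rng.uniform(90, 100)),
            v105_pct=float(rng.uniform(0, 30)),
            rx_over_dmax=float(rng.uniform(0.4, 1.0)),
        )
        report = classify_plan(m, gset)
        assert set(report.volume_specific.values()) <= {"none", "minor", "major"}
        assert set(report.volume_independent.values()) <= {"none", "deviation"}
        thr = report.thresholds
        # the normalized metrics and the grading agree: none <=> prime < 1
        assert (report.volume_specific["d2cm"] == "none") == (
            d2cm_prime(m.d2cm_pct, thr.d2cm_none) < 1.0
        )
        assert (report.volume_specific["r50"] == "none") == (
            r50_prime(m.r50, thr.r50_none) < 1.0
        )


def test_classification_monotone_in_metric_value(gset):
    order = {"none": 0, "minor": 1, "major": 2}
    for ptv_cc in (5.0, 18.0, 60.0):
        prev = -1
        for v in np.linspace(30, 110, 60):
            grade = classify_plan(metrics_with(ptv_cc=ptv_cc, d2cm_pct=float(v)), gset)
            cur = order[grade.volume_specific["d2cm"]]
            assert cur >= prev
            prev = cur


def test_guideline_set_roundtrip(tmp_path, gset):
    path = tmp_path / "gset.json"
    gset.to_json(path)
    back = load_guidelines(path)
    assert back.rows == gset.rows
    assert back.v105_max_pct == gset.v105_max_pct


def test_proposed_published_set_loads():
    proposed = load_guidelines("proposed")
    assert proposed.v105_max_pct == 12.9
    assert interpolate_thresholds(proposed, 22.0).ci_none == pytest.approx(1.12)
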