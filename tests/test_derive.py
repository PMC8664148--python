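"""Cohort-ratio guideline derivation against the published proposed tables."""

import numpy as np
import pandas as pd
import pytest

from sbrtqa import (
    cohort_ratios,
    derive_guidelines,
    scale_volume_independent,
    scale_volume_table,
    scaled_prescription,
)
from sbrtqa.derive import ScalingFactors, load_derivation_current
from sbrtqa.guidelines import load_guidelines

# published cohort means (baseline plan arm vs recalculated arm, n = 30)
MEANS_PLAN = {
    "d95_pct": 100.00, "v100_pct": 95.00, "v90_pct": 100.0, "rx_over_dmax": 0.830,
    "v105_pct": 6.3, "ci": 1.15, "d2cm_prime": 1.004, "r50_prime": 0.899,
}
MEANS_RECALC = {
    "d95_pct": 98.21, "v100_pct": 91.40, "v90_pct": 99.8, "rx_over_dmax": 0.823,
    "v105_pct": 5.4, "ci": 1.07, "d2cm_prime": 0.988, "r50_prime": 0.892,
}


@pytest.fixture(scope="module")
def published_factors() -> ScalingFactors:
    return ScalingFactors(
        ratios={k: MEANS_RECALC[k] / MEANS_PLAN[k] for k in MEANS_PLAN},
        means_plan=MEANS_PLAN,
        means_recalc=MEANS_RECALC,
        n=30,
    )


def test_cohort_ratios_from_table():
    rows = []
    for pid, (v105_p, v105_r, ci_p, ci_r) in enumerate(
        [(6.0, 5.0, 1.10, 1.02), (6.6, 5.8, 1.20, 1.12)]
    ):
        base = dict.fromkeys(MEANS_PLAN, 1.0)
        rows.append({"patient_id": pid, "arm": "plan", **base, "v105_pct": v105_p, "ci": ci_p})
        rows.append({"patient_id": pid, "arm": "recalculated", **base, "v105_pct": v105_r, "ci": ci_r})
    table = pd.DataFrame(rows)
    r = cohort_ratios(table)
    assert r["v105_pct"] == pytest.approx((5.0 + 5.8) / (6.0 + 6.6))
    assert r["ci"] == pytest.approx((1.02 + 1.12) / (1.10 + 1.20))
    assert r["d95_pct"] == 1.0


def test_cohort_ratios_table3_examples(published_factors):
    assert published_factors["v105_pct"] == pytest.approx(0.857, abs=1e-3)
    assert published_factors["ci"] == pytest.approx(0.9304, abs=1e-4)


def test_cohort_ratios_pairing_errors():
    table = pd.DataFrame(
        [
            {"patient_id": 0, "arm": "plan", **dict.fromkeys(MEANS_PLAN, 1.0)},
            {"patient_id": 1, "arm": "recalculated", **dict.fromkeys(MEANS_PLAN, 1.0)},
        ]
    )
    with pytest.raises(ValueError, match="unpaired"):
        cohort_ratios(table)


def test_volume_independent_limits_reproduced(published_factors):
    vi = scale_volume_independent(load_guidelines("current"), published_factors)
    assert vi["v105_max_pct"] == 12.9
    assert vi["v90_min_pct"] == 98.8
    assert vi["d95_target_pct"] == 98.2
    assert vi["v100_target_pct"] == 91.4
    assert vi["rx_over_dmax_min"] == 0.59
    assert vi["rx_over_dmax_max"] == 0.89
    assert vi["rx_over_dmax_min_pct"] == 59.5
    assert vi["rx_over_dmax_max_pct"] == 89.2


def test_volume_table_reproduced(published_factors):
    table = scale_volume_table(load_derivation_current(), published_factors)
    by_vol = table.set_index("ptv_cc")
    # CI columns
    assert (by_vol["ci_none_proposed"] == 1.12).all()
    assert (by_vol["ci_minor_upper_proposed"] == 1.40).all()
    # D2cm columns (nearest integer)
    assert by_vol.loc[13.2, ["d2cm_none_proposed", "d2cm_minor_upper_proposed"]].tolist() == [49, 57]
    assert by_vol.loc[22.0, ["d2cm_none_proposed", "d2cm_minor_upper_proposed"]].tolist() == [53, 62]
    assert by_vol.loc[34.0, ["d2cm_none_proposed", "d2cm_minor_upper_proposed"]].tolist() == [57, 67]
    assert by_vol.loc[50.0, ["d2cm_none_proposed", "d2cm_minor_upper_proposed"]].tolist() == [61, 76]
    # R50 columns (truncated at 2 decimals)
    assert by_vol.loc[13.2, ["r50_none_proposed", "r50_minor_upper_proposed"]].tolist() == [4.66, 5.75]
    assert by_vol.loc[22.0, ["r50_none_proposed", "r50_minor_upper_proposed"]].tolist() == [4.46, 5.45]
    assert by_vol.loc[34.0, ["r50_none_proposed", "r50_minor_upper_proposed"]].tolist() == [4.26, 5.25]
    assert by_vol.loc[50.0, ["r50_none_proposed", "r50_minor_upper_proposed"]].tolist() == [3.96, 4.96]


def test_identity_ratios_leave_limits_unchanged():
    r = ScalingFactors(
        ratios=dict.fromkeys(MEANS_PLAN, 1.0),
        means_plan=dict.fromkeys(MEANS_PLAN, 1.0),
        means_recalc=dict.fromkeys(MEANS_PLAN, 1.0),
        n=5,
    )
    table = scale_volume_table(load_derivation_current(), r)
    for metric in ("ci", "d2cm", "r50"):
        for bound in ("none", "minor_upper"):
            np.testing.assert_allclose(
                table[f"{metric}_{bound}_proposed"], table[f"{metric}_{bound}_current"]
            )


def test_smaller_ratio_never_raises_limit(published_factors):
    shrunk = ScalingFactors(
        ratios={k: v * 0.95 for k, v in published_factors.ratios.items()},
        means_plan=published_factors.means_plan,
        means_recalc=published_factors.means_recalc,
        n=30,
    )
    t1 = scale_volume_table(load_derivation_current(), published_factors)
    t2 = scale_volume_table(load_derivation_current(), shrunk)
    for col in t1.columns:
        if col.endswith("_proposed"):
            assert (t2[col] <= t1[col]).all()


def test_derive_guidelines_full(published_factors, tmp_path):
    proposed = derive_guidelines(published_factors)
    assert proposed.v105_max_pct == 12.9
    assert proposed.rx_over_dmax_range == (0.59, 0.89)
    assert proposed.rx_over_dmax_range_pct == (59.5, 89.2)
    assert len(proposed.volume_table) == 4
    assert any("1.41" in n for n in proposed.notes)
    gset = proposed.to_guideline_set()
    assert gset.v100_target_pct == 91.4
    proposed.write(tmp_path)
    assert (tmp_path / "proposed_guidelines.json").exists()
    assert (tmp_path / "proposed_volume_specific.csv").exists()


@pytest.mark.parametrize(
    "rx, d95, expected",
    [(60.0, 98.2, 58.92), (60.0, 100.0, 60.0), (60.0, 97.0, 58.20), (60.0, 97.03, 58.22)],
)
def test_scaled_prescription(rx, d95, expected):
    assert scaled_prescription(rx, d95) == pytest.approx(expected)
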