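"""Compute the full per-plan metric vector from a dose grid and structure masks."""

from __future__ import annotations

from .dvh import (
    DoseSample,
    dose_at_volume_pct,
    hot_volume_outside_pct,
    max_dose,
    near_min_dose,
    volume_pct_at_dose,
)
from .guidelines import GuidelineSet, d2cm_prime, interpolate_thresholds, load_guidelines, r50_prime
from .plan import Plan, PlanMetrics, structure_volume_cc
from .spatial import classify_island, conformality_index, d2cm, r50

__all__ = ["compute_plan_metrics"]


def compute_plan_metrics(plan: Plan, gset: GuidelineSet | None = None,
                         cold_cc: float = 0.03) -> PlanMetrics:
    """Evaluate coverage, conformality, and falloff metrics for one plan.

    Percent-dose metrics are relative to the prescription; the normalized
    falloff metrics D'2cm and R50' use the guideline set's none/minor
    boundary interpolated at the plan's PTV volume (the "current" RTOG/NRG
    table by default).
    """
    if gset is None:
        gset = load_guidelines("current")
    rx = plan.rx_gy
    ptv = plan.ptv
    body = plan.mask("body")
    sample = DoseSample.from_mask(plan.dose, ptv)

    ptv_cc = structure_volume_cc(ptv)
    d95_pct = 100.0 * dose_at_volume_pct(sample, 95.0) / rx
    v100_pct = volume_pct_at_dose(sample, rx)
    v90_pct = volume_pct_at_dose(sample, 0.9 * rx)
    dmin_pct = 100.0 * near_min_dose(sample, cold_cc) / rx
    dmax_pct = 100.0 * max_dose(plan.dose, body) / rx
    v105_pct = hot_volume_outside_pct(plan.dose, ptv, 1.05 * rx)
    ci = conformality_index(plan.dose, ptv, rx, body)
    r50_val = r50(plan.dose, ptv, rx, body)
    d2cm_pct = d2cm(plan.dose, ptv, rx, body=body)

    thr = interpolate_thresholds(gset, ptv_cc)
    return PlanMetrics(
        ptv_cc=ptv_cc,
        d95_pct=d95_pct,
        v100_pct=v100_pct,
        v90_pct=v90_pct,
        dmin_pct=dmin_pct,
        dmax_pct=dmax_pct,
        rx_over_dmax=100.0 / dmax_pct,
        v105_pct=v105_pct,
        ci=ci,
        r50=r50_val,
        d2cm_pct=d2cm_pct,
        d2cm_prime=d2cm_prime(d2cm_pct, thr.d2cm_none),
        r50_prime=r50_prime(r50_val, thr.r50_none),
        mu_total=plan.mu_total,
        island=classify_island(ptv, plan.mask("chestwall")),
    )
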