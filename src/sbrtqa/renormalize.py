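"""Global renormalization of a plan to a PTV coverage target.

A recalculated plan is rescaled by a single factor so the dose covering the
target fraction of the PTV (95% by default) equals the prescription again;
monitor units scale by exactly the same factor and the relative spatial dose
distribution is unchanged (beam weights are never touched).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .dvh import DoseSample, dose_at_volume_pct
from .plan import Plan

__all__ = ["RenormalizationResult", "renormalize", "CannotRenormalizeError"]


class CannotRenormalizeError(ValueError):
    """The plan delivers zero dose at the coverage quantile."""


@dataclass(frozen=True)
class RenormalizationResult:
    scale_factor: float
    mu_before: float
    mu_after: float
    d95_before_pct: float
    d95_after_pct: float


def renormalize(plan: Plan, coverage_target_pct: float = 95.0) -> tuple[Plan, RenormalizationResult]:
    """Rescale dose and MU so D(coverage_target) returns to the prescription.

    The scale factor is Rx divided by the current dose at the coverage
    quantile; on the exact voxel multiset the post-scaling coverage dose hits
    the prescription exactly.
    """
    sample = DoseSample.from_mask(plan.dose, plan.ptv)
    d_cov = dose_at_volume_pct(sample, coverage_target_pct)
    if d_cov <= 0:
        raise CannotRenormalizeError(
            f"dose at the {coverage_target_pct}% coverage quantile is zero"
        )
    scale = plan.rx_gy / d_cov
    scaled = replace(
        plan,
        dose=plan.dose.scaled(scale),
        mu_total=plan.mu_total * scale,
        arm="renormalized",
    )
    result = RenormalizationResult(
        scale_factor=scale,
        mu_before=plan.mu_total,
        mu_after=scaled.mu_total,
        d95_before_pct=100.0 * d_cov / plan.rx_gy,
        d95_after_pct=100.0,
    )
    return scaled, result
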