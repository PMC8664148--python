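"""Synthetic paired-plan cohort generator.

Emulates a conformal dynamic-conformal-arc lung SBRT cohort at the metric
level: each phantom patient gets an ellipsoidal PTV (either "island", at
least 1 cm clear of a chest-wall slab, or abutting it), a dose field with an
interior plateau and hotspot, a steep penumbra through the prescription
surface, and an anisotropic exponential falloff with one slow "beam channel"
direction; the plan is normalized so D95 equals the prescription exactly.

The dose-engine recalculation is modeled phenomenologically as a transform
of the dose field, not as radiation transport: a per-patient global output
factor (lower for island targets, which lack dose buildup), a deepened cold
rim at the PTV edge, a boosted interior peak (greater dose heterogeneity),
and a relaxation of the factor in the far field where charged-particle
equilibrium makes the dose robust to the algorithm change. Monitor units are
untouched by the recalculation; renormalization restores coverage and scales
MU by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .guidelines import GuidelineSet, load_guidelines
from .metrics import compute_plan_metrics
from .plan import DoseGrid, Plan, StructureMask
from .renormalize import renormalize

__all__ = [
    "ShiftParams",
    "CohortConfig",
    "generate_phantom_plan",
    "apply_algorithm_shift",
    "generate_cohort",
]


@dataclass(frozen=True)
class ShiftParams:
    """Parameters of the phenomenological dose-recalculation transform.

    ``d95_ratio_*`` are the per-patient mean global output factors (recalculated
    over plan D95); island targets sit fully in low-density lung and lose more
    buildup than targets near the chest wall. The bounds keep the implied MU
    change to restore coverage inside a realistic -2% to +7.5% window.
    """

    d95_ratio_mean: float = 0.9911     # non-island targets
    d95_ratio_island_mean: float = 0.9703
    d95_ratio_sd: float = 0.013
    d95_ratio_bounds: tuple[float, float] = (0.931, 1.021)
    dmax_boost_mean: float = 0.027     # extra relative boost at the dose peak
    dmax_boost_sd: float = 0.006
    cold_rim_deepening: float = 0.008  # extra fractional reduction at the coldest rim
    penumbra_tightening: float = 0.0   # extra out-of-field reduction (off by default)
    far_field_full_relax_pct: float = 75.0  # dose level (% Rx) below which the
    far_field_zero_pct: float = 4.0         # factor relaxes linearly back to 1


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 30
    island_fraction: float = 13.0 / 30.0
    ptv_volume_range_cc: tuple[float, float] = (7.58, 74.06)
    ptv_volume_log_mean: float = np.log(18.0)  # lognormal volume draw, clipped to range
    ptv_volume_log_sd: float = 0.45
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    rx_gy: float = 60.0
    n_fractions: int = 5
    seed: int = 20210915
    shift: ShiftParams = field(default_factory=ShiftParams)
    # dose-shape parameters (calibrated once against a conformal DCA cohort)
    rim_slope_pct_per_mm: float = 5.4      # interior dose rise at the Rx surface
    rim_zone_mm: float = 1.8
    peak_pct_mean: float = 120.5
    peak_pct_sd: float = 4.0
    peak_pct_bounds: tuple[float, float] = (112.0, 155.0)
    falloff_scale_mm: float = 12.4          # base exponential falloff length
    falloff_volume_exponent: float = 0.55   # falloff grows with target radius
    channel_amp_range: tuple[float, float] = (1.20, 1.60)
    channel_concentration: float = 12.0
    surface_cold_base_mm: float = 0.75      # shallow cold offset of the Rx surface
    n_hot_lobes: int = 5
    hot_lobe_amp_range_mm: tuple[float, float] = (1.5, 4.5)
    hot_lobe_concentration_range: tuple[float, float] = (4.5, 7.5)
    cold_lobe_amp_range_mm: tuple[float, float] = (1.5, 3.0)
    mu_mean: float = 1973.0
    mu_island_mean: float = 2301.0
    mu_sd: float = 250.0
    chestwall_thickness_vox: int = 4

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValueError("island_fraction must be in [0, 1]")
        lo, hi = self.ptv_volume_range_cc
        if not 0 < lo < hi:
            raise ValueError("invalid ptv_volume_range_cc")


def _patient_rng(config: CohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed) % (2**31), patient_index, stream))
    )


def _is_island(config: CohortConfig, patient_index: int) -> bool:
    n_island = int(round(config.island_fraction * config.n_patients))
    return patient_index < n_island


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _dose_percent_field(config: CohortConfig, rng: np.random.Generator,
                        center_mm: np.ndarray, semi_axes_mm: np.ndarray,
                        peak_pct: float) -> np.ndarray:
    """Dose (% of Rx, un-normalized) on the full grid for one phantom."""
    spacing = np.asarray(config.spacing_mm)
    axes = [np.arange(n) * s for n, s in zip(config.grid_shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    w = np.stack([xx - center_mm[0], yy - center_mm[1], zz - center_mm[2]])

    r = np.sqrt((w**2).sum(axis=0))
    r_safe = np.where(r < 1e-9, 1e-9, r)
    u = w / r_safe  # unit direction from PTV center
    r_e = np.sqrt(((w / semi_axes_mm[:, None, None, None]) ** 2).sum(axis=0))
    r_e_safe = np.where(r_e < 1e-9, 1e-9, r_e)
    local_radius = r_safe / r_e_safe  # PTV surface radius along this direction
    d_surf = (r_e - 1.0) * local_radius  # signed mm distance from PTV surface

    # angular offset of the Rx surface from the PTV surface: a shallow cold
    # baseline, one deeper cold lobe, and several hot lobes bulging outwards
    m = np.full(r.shape, -config.surface_cold_base_mm)
    hot_dirs = _random_unit(rng, config.n_hot_lobes)
    amps = rng.uniform(*config.hot_lobe_amp_range_mm, size=config.n_hot_lobes)
    kappas = rng.uniform(*config.hot_lobe_concentration_range, size=config.n_hot_lobes)
    for v, a, k in zip(hot_dirs, amps, kappas):
        c = np.einsum("i,ijkl->jkl", v, u)
        m += a * np.exp(k * (c - 1.0))
    cold_dir = _random_unit(rng)[0]
    cold_amp = rng.uniform(*config.cold_lobe_amp_range_mm)
    c = np.einsum("i,ijkl->jkl", cold_dir, u)
    m -= cold_amp * np.exp(5.0 * (c - 1.0))

    tau = d_surf - m  # signed mm distance from the (angularly modulated) Rx surface

    # anisotropic falloff length: slow along one "beam channel" axis
    r0 = float(np.cbrt(np.prod(semi_axes_mm)))
    lam0 = config.falloff_scale_mm * (r0 / 17.1) ** config.falloff_volume_exponent
    ch_dir = _random_unit(rng)[0]
    ch_amp = rng.uniform(*config.channel_amp_range)
    c_ch = np.abs(np.einsum("i,ijkl->jkl", ch_dir, u))
    lam = lam0 * (1.0 + ch_amp * np.exp(config.channel_concentration * (c_ch - 1.0)))

    pct = np.empty(r.shape)
    inside = tau <= 0
    depth = -tau
    k1, w1 = config.rim_slope_pct_per_mm, config.rim_zone_mm
    plateau_ref = max(0.6 * float(semi_axes_mm.min()), 2.0 * w1)
    core = np.clip((depth - w1) / plateau_ref, 0.0, 1.0) ** 1.3
    pct_in = 100.0 + k1 * np.minimum(depth, w1) + (peak_pct - 100.0 - k1 * w1) * core
    pct[inside] = pct_in[inside]
    outside = ~inside
    pct[outside] = 100.0 * np.exp(-tau[outside] / lam[outside])
    return pct


def generate_phantom_plan(config: CohortConfig, patient_index: int) -> Plan:
    """One synthetic baseline plan (arm "plan", algorithm AAA).

    Deterministic in (config.seed, patient_index); the dose is globally
    normalized so D95 equals the prescription exactly (V100 = 95%).
    """
    rng = _patient_rng(config, patient_index, stream=0)
    island = _is_island(config, patient_index)
    spacing = np.asarray(config.spacing_mm)
    shape = config.grid_shape

    vol_cc = float(
        np.clip(
            np.exp(rng.normal(config.ptv_volume_log_mean, config.ptv_volume_log_sd)),
            *config.ptv_volume_range_cc,
        )
    )
    r0 = np.cbrt(3.0 * vol_cc * 1000.0 / (4.0 * np.pi))  # mm
    logf = rng.uniform(-0.2, 0.2, size=3)
    semi_axes = r0 * np.exp(logf - logf.mean())

    # chest-wall slab on the low side of axis 0; island targets keep >= 1 cm
    # of clearance, the rest abut it
    slab_outer_mm = (config.chestwall_thickness_vox - 1) * spacing[0]
    gap = rng.uniform(12.0, 30.0) if island else rng.uniform(2.5, 7.0)
    extent = np.asarray(shape) * spacing
    cx = slab_outer_mm + gap + semi_axes[0]
    cy, cz = extent[1] / 2 + rng.uniform(-5, 5), extent[2] / 2 + rng.uniform(-5, 5)
    center = np.array([cx, cy, cz])
    if cx + semi_axes[0] + 25.0 > extent[0]:
        raise ValueError(
            f"PTV of {vol_cc:.1f} cc does not fit in the grid with margin"
        )

    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r_e = np.sqrt(
        ((xx - cx) / semi_axes[0]) ** 2
        + ((yy - cy) / semi_axes[1]) ** 2
        + ((zz - cz) / semi_axes[2]) ** 2
    )
    ptv_vox = r_e <= 1.0

    cw_vox = np.zeros(shape, dtype=bool)
    cw_vox[: config.chestwall_thickness_vox, :, :] = True

    peak = float(
        np.clip(rng.normal(config.peak_pct_mean, config.peak_pct_sd), *config.peak_pct_bounds)
    )
    pct = _dose_percent_field(config, rng, center, semi_axes, peak)
    dose_gy = config.rx_gy * pct / 100.0

    spacing_t = tuple(float(s) for s in spacing)
    masks = {
        "ptv": StructureMask(ptv_vox, "ptv", spacing_t),
        "chestwall": StructureMask(cw_vox, "chestwall", spacing_t),
        "body": StructureMask(np.ones(shape, dtype=bool), "body", spacing_t),
    }
    mu_mean = config.mu_island_mean if island else config.mu_mean
    mu = float(max(800.0, rng.normal(mu_mean, config.mu_sd)))
    plan = Plan(
        dose=DoseGrid(dose_gy, spacing_t),
        masks=masks,
        rx_gy=config.rx_gy,
        n_fractions=config.n_fractions,
        mu_total=mu,
        algorithm="AAA",
        arm="plan",
        patient_id=f"P{patient_index:03d}",
    )
    # normalize planning coverage: D95 = Rx exactly
    normalized, _ = renormalize(plan, coverage_target_pct=95.0)
    plan.dose = normalized.dose
    return plan


def apply_algorithm_shift(plan: Plan, shift: ShiftParams,
                          rng: np.random.Generator,
                          island: bool | None = None) -> Plan:
    """Recalculation transform: returns the AXB-recalculated arm.

    The dose field is multiplied by a spatially varying factor built from a
    per-patient global output factor, far-field relaxation toward unity,
    cold-rim deepening inside the PTV edge, an interior peak boost, and an
    optional extra out-of-field tightening. MU is kept at the original value.
    A zero-magnitude shift (ratio means 1, sd and perturbations 0) is the
    identity transform.
    """
    if plan.arm != "plan":
        raise ValueError(f"shift applies to baseline plans only, got arm={plan.arm!r}")
    if island is None:
        from .spatial import classify_island

        island = bool(classify_island(plan.ptv, plan.mask("chestwall")))
    mean = shift.d95_ratio_island_mean if island else shift.d95_ratio_mean
    g = float(np.clip(rng.normal(mean, shift.d95_ratio_sd), *shift.d95_ratio_bounds))

    pct = 100.0 * plan.dose.values / plan.rx_gy
    factor = np.full(pct.shape, g)

    # far field: charged-particle equilibrium makes low-dose regions robust
    hi, lo = shift.far_field_full_relax_pct, shift.far_field_zero_pct
    relax = np.clip((hi - pct) / (hi - lo), 0.0, 1.0)
    factor += (1.0 - g) * relax

    ptv_vox = plan.ptv.voxels
    if shift.cold_rim_deepening > 0:
        rim = ptv_vox & (pct < 99.0)
        ramp = np.clip((99.0 - pct) / 14.0, 0.0, 1.0)
        factor[rim] *= 1.0 - shift.cold_rim_deepening * ramp[rim]

    boost = float(max(0.0, rng.normal(shift.dmax_boost_mean, shift.dmax_boost_sd)))
    if boost > 0:
        peak_ref = float(pct.max())
        if peak_ref > 105.0:
            hot = pct > 105.0
            ramp = np.clip((pct - 105.0) / (peak_ref - 105.0), 0.0, 1.0)
            factor[hot] *= 1.0 + boost * ramp[hot]

    if shift.penumbra_tightening > 0:
        out = ~ptv_vox & (pct < 100.0)
        ramp = np.clip((100.0 - pct) / 50.0, 0.0, 1.0)
        factor[out] *= 1.0 - shift.penumbra_tightening * ramp[out]

    return replace(
        plan,
        dose=DoseGrid(plan.dose.values * factor, plan.dose.spacing, plan.dose.origin),
        algorithm="AXB",
        arm="recalculated",
    )


def generate_cohort(config: CohortConfig, gset: GuidelineSet | None = None,
                    include_renormalized: bool = True,
                    ) -> tuple[dict[str, dict[str, Plan]], pd.DataFrame]:
    """Generate the full paired cohort and its metrics table.

    Returns ``(plans, table)`` where ``plans[patient_id][arm]`` holds the Plan
    objects and ``table`` has one row per (patient, arm) with all metric
    columns, deterministic under the config seed.
    """
    if gset is None:
        gset = load_guidelines("current")
    plans: dict[str, dict[str, Plan]] = {}
    rows = []
    for i in range(config.n_patients):
        baseline = generate_phantom_plan(config, i)
        shift_rng = _patient_rng(config, i, stream=1)
        island = _is_island(config, i)
        recalc = apply_algorithm_shift(baseline, config.shift, shift_rng, island=island)
        arms = {"plan": baseline, "recalculated": recalc}
        if include_renormalized:
            arms["renormalized"], _ = renormalize(recalc)
        plans[baseline.patient_id] = arms
        for arm, p in arms.items():
            m = compute_plan_metrics(p, gset)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "arm": arm,
                    "algorithm": p.algorithm,
                    **m.as_dict(),
                }
            )
    table = pd.DataFrame(rows)
    return plans, table
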