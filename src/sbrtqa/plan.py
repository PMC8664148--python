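"""Core domain types for dose grids, structure masks, and treatment plans.

Geometric conventions shared by every other module:

* grids are axis-aligned; voxel (i, j, k) has physical position
  ``origin + index * spacing`` (voxel-center convention, 0-based indices);
* spacing is in millimetres per axis; dose values are in gray;
* volumes are computed by voxel counting at voxel centers, with no
  partial-volume interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DoseGrid",
    "StructureMask",
    "Plan",
    "PlanMetrics",
    "InvalidGeometryError",
    "voxel_volume_cc",
    "structure_volume_cc",
    "validate_plan",
]

#: structure labels with defined roles in the pipeline
KNOWN_LABELS = ("ptv", "chestwall", "lung_ipsi", "lung_contra", "body")

ALGORITHMS = ("AAA", "AXB")
ARMS = ("plan", "recalculated", "renormalized")


class InvalidGeometryError(ValueError):
    """Raised for non-positive spacing, mismatched shapes, or empty required masks."""


@dataclass(frozen=True)
class DoseGrid:
    """Axis-aligned 3D dose field.

    Parameters
    ----------
    values : ndarray, shape (ni, nj, nk)
        Dose in Gy per voxel; finite and non-negative.
    spacing : tuple of 3 floats
        Voxel pitch in mm per axis; strictly positive.
    origin : tuple of 3 floats
        Physical mm coordinates of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise InvalidGeometryError("dose grid must be a non-empty 3D array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("dose values must be finite and >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InvalidGeometryError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def scaled(self, factor: float) -> "DoseGrid":
        """Return a copy with all dose values multiplied by ``factor``."""
        return replace(self, values=self.values * float(factor))


@dataclass(frozen=True)
class StructureMask:
    """Binary voxel set sharing a DoseGrid's geometry."""

    voxels: np.ndarray
    label: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        voxels = np.asarray(self.voxels)
        if voxels.dtype != bool:
            uniq = np.unique(voxels)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask '{self.label}' contains non-binary values {uniq[:5]}")
            voxels = voxels.astype(bool)
        if voxels.ndim != 3 or voxels.size == 0:
            raise InvalidGeometryError("mask must be a non-empty 3D array")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise InvalidGeometryError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def matches(self, grid: DoseGrid) -> bool:
        return (
            self.shape == grid.shape
            and np.allclose(self.spacing, grid.spacing)
            and np.allclose(self.origin, grid.origin)
        )


@dataclass
class Plan:
    """A dose grid plus structure masks and prescription bookkeeping."""

    dose: DoseGrid
    masks: dict[str, StructureMask]
    rx_gy: float
    n_fractions: int = 5
    mu_total: float = 0.0
    algorithm: str = "AAA"
    arm: str = "plan"
    patient_id: str = ""

    @property
    def ptv(self) -> StructureMask:
        try:
            return self.masks["ptv"]
        except KeyError:
            raise KeyError("plan has no PTV mask") from None

    def mask(self, label: str) -> StructureMask | None:
        return self.masks.get(label)


@dataclass
class PlanMetrics:
    """Per-plan metric vector.

    Percent-dose metrics (d95, dmin, dmax, d2cm) are % of the prescription;
    percent-volume metrics (v100, v90, v105) are % of the PTV volume.
    """

    ptv_cc: float
    d95_pct: float
    v100_pct: float
    v90_pct: float
    dmin_pct: float
    dmax_pct: float
    rx_over_dmax: float
    v105_pct: float
    ci: float
    r50: float
    d2cm_pct: float
    d2cm_prime: float
    r50_prime: float
    mu_total: float
    island: bool | None = None  # None = unknown (no chest-wall mask)

    def as_dict(self) -> dict:
        return {
            "ptv_cc": self.ptv_cc,
            "d95_pct": self.d95_pct,
            "v100_pct": self.v100_pct,
            "v90_pct": self.v90_pct,
            "dmin_pct": self.dmin_pct,
            "dmax_pct": self.dmax_pct,
            "rx_over_dmax": self.rx_over_dmax,
            "v105_pct": self.v105_pct,
            "ci": self.ci,
            "r50": self.r50,
            "d2cm_pct": self.d2cm_pct,
            "d2cm_prime": self.d2cm_prime,
            "r50_prime": self.r50_prime,
            "mu_total": self.mu_total,
            "island": self.island,
        }


def voxel_volume_cc(grid: DoseGrid | StructureMask) -> float:
    """Volume of one voxel in cm^3 (product of mm spacings / 1000)."""
    sx, sy, sz = grid.spacing
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise InvalidGeometryError(f"non-positive spacing {grid.spacing}")
    return sx * sy * sz / 1000.0


def structure_volume_cc(mask: StructureMask) -> float:
    """Structure volume in cm^3 by voxel counting."""
    n = mask.count()
    if n == 0:
        warnings.warn(f"mask '{mask.label}' is empty; volume is 0 cc", stacklevel=2)
    return n * voxel_volume_cc(mask)


def validate_plan(plan: Plan) -> list[str]:
    """Report structural problems; an empty report means the plan is usable."""
    report: list[str] = []
    if "ptv" not in plan.masks:
        report.append("missing-ptv: no PTV mask present")
    for label, mask in plan.masks.items():
        if not mask.matches(plan.dose):
            report.append(
                f"geometry-mismatch: mask '{label}' shape/spacing/origin differs from dose grid"
            )
    ptv = plan.masks.get("ptv")
    if ptv is not None and ptv.count() == 0:
        report.append("empty-ptv: PTV mask has no voxels")
    if plan.rx_gy <= 0:
        report.append(f"invalid-prescription: rx_gy={plan.rx_gy} must be > 0")
    if plan.mu_total <= 0:
        report.append(f"invalid-mu: mu_total={plan.mu_total} must be > 0")
    if plan.algorithm not in ALGORITHMS:
        report.append(f"unknown-algorithm: {plan.algorithm!r} not in {ALGORITHMS}")
    if plan.arm not in ARMS:
        report.append(f"unknown-arm: {plan.arm!r} not in {ARMS}")
    return report
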