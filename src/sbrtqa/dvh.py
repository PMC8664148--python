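"""DVH-style scalar metrics on the exact voxel dose multiset of a structure.

All operations work on the un-binned multiset of per-voxel doses, so there is
no hidden histogram bin width. Dose thresholds in Vx-type quantities are
inclusive (>=); the hot-spill metric V105 uses a strict ``>`` following the
protocol wording (">105% of the prescription dose").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plan import DoseGrid, StructureMask, voxel_volume_cc

__all__ = [
    "DoseSample",
    "EmptyStructureError",
    "dose_at_volume_pct",
    "volume_pct_at_dose",
    "near_min_dose",
    "max_dose",
    "isodose_volume_cc",
    "hot_volume_outside_pct",
]


class EmptyStructureError(ValueError):
    """A DVH metric was requested on an empty structure."""


@dataclass(frozen=True)
class DoseSample:
    """Multiset of per-voxel doses (Gy) inside a structure."""

    doses: np.ndarray
    voxel_cc: float

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float).ravel()
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise ValueError("doses must be finite and >= 0")
        if self.voxel_cc <= 0:
            raise ValueError("voxel_cc must be > 0")
        object.__setattr__(self, "doses", doses)

    @classmethod
    def from_mask(cls, grid: DoseGrid, mask: StructureMask) -> "DoseSample":
        return cls(doses=grid.values[mask.voxels], voxel_cc=voxel_volume_cc(grid))

    @property
    def n(self) -> int:
        return self.doses.size

    @property
    def volume_cc(self) -> float:
        return self.n * self.voxel_cc


def _require_nonempty(sample: DoseSample):
    if sample.n == 0:
        raise EmptyStructureError("structure contains no voxels")


def dose_at_volume_pct(sample: DoseSample, x: float) -> float:
    """Dx: largest voxel dose d such that >= x% of the structure receives >= d.

    Computed on the exact voxel multiset without interpolation: with the doses
    sorted in descending order, Dx is the ceil(x/100 * n)-th hottest voxel.
    """
    _require_nonempty(sample)
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    desc = np.sort(sample.doses)[::-1]
    # smallest k with k/n >= x/100; epsilon guards float noise in x*n/100
    k = int(np.ceil(x * sample.n / 100.0 - 1e-9))
    return float(desc[max(k, 1) - 1])


def volume_pct_at_dose(sample: DoseSample, d: float) -> float:
    """Vd: percent of structure volume receiving at least ``d`` Gy (inclusive)."""
    _require_nonempty(sample)
    if d < 0:
        raise ValueError("dose threshold must be >= 0")
    return 100.0 * float(np.count_nonzero(sample.doses >= d)) / sample.n


def near_min_dose(sample: DoseSample, cold_cc: float = 0.03) -> float:
    """Near-minimum dose: the dose received by all but the coldest ``cold_cc`` cm^3.

    Defined as the maximum voxel dose d such that the volume strictly below d
    is <= cold_cc; reduces to the plain minimum at cold_cc = 0.
    """
    _require_nonempty(sample)
    if cold_cc < 0:
        raise ValueError("cold_cc must be >= 0")
    if cold_cc >= sample.volume_cc:
        raise ValueError(
            f"cold_cc={cold_cc} must be smaller than the structure volume {sample.volume_cc}"
        )
    asc = np.sort(sample.doses)
    m = int(np.floor(cold_cc / sample.voxel_cc + 1e-12))
    return float(asc[m])


def max_dose(grid: DoseGrid, region: StructureMask | None = None) -> float:
    """Maximum voxel dose over a region (whole grid when region is None)."""
    if region is None:
        return float(grid.values.max())
    if region.count() == 0:
        raise EmptyStructureError(f"region '{region.label}' is empty")
    return float(grid.values[region.voxels].max())


def isodose_volume_cc(grid: DoseGrid, level: float, region: StructureMask | None = None) -> float:
    """Volume (cc) of voxels with dose >= level, optionally within a region."""
    if level < 0:
        raise ValueError("isodose level must be >= 0")
    hot = grid.values >= level
    if region is not None:
        hot = hot & region.voxels
    return float(np.count_nonzero(hot)) * voxel_volume_cc(grid)


def hot_volume_outside_pct(grid: DoseGrid, ptv: StructureMask, level: float) -> float:
    """Volume outside the PTV with dose strictly > level, as % of PTV volume."""
    n_ptv = ptv.count()
    if n_ptv == 0:
        raise EmptyStructureError("PTV is empty")
    hot_outside = (grid.values > level) & ~ptv.voxels
    return 100.0 * float(np.count_nonzero(hot_outside)) / n_ptv
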