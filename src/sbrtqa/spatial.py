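"""Geometry-dependent plan metrics.

Conformality index (CI), dose-falloff ratio R50, the D2cm dose-spill metric,
and island-type target classification. Distances are exact Euclidean
distances between voxel centers with anisotropic spacing honored, via the
exact Euclidean distance transform.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .dvh import EmptyStructureError, isodose_volume_cc
from .plan import DoseGrid, StructureMask, structure_volume_cc

__all__ = [
    "GridTooSmallError",
    "distance_from_mask",
    "conformality_index",
    "r50",
    "d2cm",
    "classify_island",
]


class GridTooSmallError(ValueError):
    """No voxel lies beyond the requested margin from the reference mask."""


def distance_from_mask(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the nearest mask voxel center.

    Zero on the mask itself; exact for anisotropic spacing.
    """
    if mask.count() == 0:
        raise EmptyStructureError(f"mask '{mask.label}' is empty")
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)


def conformality_index(grid: DoseGrid, ptv: StructureMask, rx_gy: float,
                       body: StructureMask | None = None) -> float:
    """Prescription isodose volume divided by PTV volume."""
    if ptv.count() == 0:
        raise EmptyStructureError("PTV is empty")
    if rx_gy <= 0:
        raise ValueError("rx_gy must be > 0")
    return isodose_volume_cc(grid, rx_gy, body) / structure_volume_cc(ptv)


def r50(grid: DoseGrid, ptv: StructureMask, rx_gy: float,
        body: StructureMask | None = None) -> float:
    """50%-of-prescription isodose volume divided by PTV volume (dose falloff)."""
    if ptv.count() == 0:
        raise EmptyStructureError("PTV is empty")
    if rx_gy <= 0:
        raise ValueError("rx_gy must be > 0")
    return isodose_volume_cc(grid, 0.5 * rx_gy, body) / structure_volume_cc(ptv)


def d2cm(grid: DoseGrid, ptv: StructureMask, rx_gy: float,
         margin_mm: float = 20.0, body: StructureMask | None = None) -> float:
    """Maximum dose (% of Rx) at voxels strictly more than ``margin_mm`` from the PTV.

    The search region is intersected with the body mask when one is supplied
    (the protocol phrasing is "anywhere in the patient"); otherwise the whole
    grid is used with a warning.
    """
    if rx_gy <= 0:
        raise ValueError("rx_gy must be > 0")
    far = distance_from_mask(ptv) > margin_mm
    if body is not None:
        far &= body.voxels
    else:
        warnings.warn(
            "no body mask supplied; D2cm searched over the whole grid", stacklevel=2
        )
    if not far.any():
        raise GridTooSmallError(
            f"no voxel lies more than {margin_mm} mm from the PTV"
            + (" inside the body" if body is not None else "")
        )
    return 100.0 * float(grid.values[far].max()) / rx_gy


def classify_island(ptv: StructureMask, chestwall: StructureMask | None,
                    threshold_mm: float = 10.0) -> bool | None:
    """True when the PTV is at least ``threshold_mm`` from the chest wall (inclusive).

    Returns None ("unknown") when no chest-wall mask is available.
    """
    if chestwall is None:
        return None
    if ptv.count() == 0:
        raise EmptyStructureError("PTV is empty")
    if chestwall.count() == 0:
        raise EmptyStructureError("chest wall mask is empty")
    dist_to_cw = distance_from_mask(chestwall)
    min_gap = float(dist_to_cw[ptv.voxels].min())
    return min_gap >= threshold_mm
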