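"""File formats: NRRD grids/masks, JSON plan manifests, and cohort CSV tables.

NRRD is the required volumetric format (header-complete and simple); a DICOM
RT-Dose reader is provided as an optional adapter. Grids must be axis-aligned;
oblique orientations are rejected at read time rather than resampled.

Array axis convention: the in-memory axis order is (i, j, k) with spacing per
axis in the same order; on disk the NRRD carries the matching spacings, so a
write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .plan import ARMS, DoseGrid, Plan, StructureMask

__all__ = [
    "PlanManifest",
    "read_dose_nrrd",
    "read_mask_nrrd",
    "write_grid_nrrd",
    "read_plan",
    "write_plan",
    "read_dicom_rtdose",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id",
    "arm",
    "algorithm",
    "ptv_cc",
    "d95_pct",
    "v100_pct",
    "v90_pct",
    "dmin_pct",
    "dmax_pct",
    "rx_over_dmax",
    "v105_pct",
    "ci",
    "r50",
    "d2cm_pct",
    "d2cm_prime",
    "r50_prime",
    "mu_total",
    "island",
]


class UnsupportedOrientationError(ValueError):
    """The volume is not axis-aligned with the identity direction matrix."""


def _check_axis_aligned(img: sitk.Image, path) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedOrientationError(
            f"{path}: oblique orientation {direction.tolist()} is not supported"
        )


def _read_volume(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = sitk.ReadImage(str(path))
    _check_axis_aligned(img, path)
    # SimpleITK arrays come back as (z, y, x); spacing/origin as (x, y, z).
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return values, spacing, origin


def read_dose_nrrd(path: str | Path) -> DoseGrid:
    values, spacing, origin = _read_volume(path)
    return DoseGrid(values.astype(float), spacing, origin)


def read_mask_nrrd(path: str | Path, label: str) -> StructureMask:
    values, spacing, origin = _read_volume(path)
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path}: mask contains non-binary values {uniq[:5].tolist()}")
    return StructureMask(values.astype(bool), label, spacing, origin)


def write_grid_nrrd(obj: DoseGrid | StructureMask, path: str | Path) -> None:
    if isinstance(obj, StructureMask):
        array = obj.voxels.astype(np.uint8)
    else:
        array = np.asarray(obj.values, dtype=float)
    img = sitk.GetImageFromArray(array)
    img.SetSpacing(tuple(reversed(obj.spacing)))
    img.SetOrigin(tuple(reversed(obj.origin)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_dicom_rtdose(path: str | Path) -> DoseGrid:
    """Optional adapter: read a DICOM RT-Dose file into a DoseGrid."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
    dz = float(ds.GridFrameOffsetVector[1] - ds.GridFrameOffsetVector[0])
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in reversed(ds.ImagePositionPatient))
    orientation = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    if not (np.allclose(orientation[:3], (1, 0, 0)) and np.allclose(orientation[3:], (0, 1, 0))):
        raise UnsupportedOrientationError(f"{path}: non-axial RT-Dose orientation")
    return DoseGrid(values, (dz, dy, dx), origin)


@dataclass
class PlanManifest:
    """Paths and prescription bookkeeping for one plan on disk."""

    dose_path: str
    mask_paths: dict[str, str]  # label -> path
    rx_gy: float
    n_fractions: int
    mu_total: float
    algorithm: str = "AAA"
    arm: str = "plan"
    patient_id: str = ""

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanManifest":
        payload = json.loads(Path(path).read_text())
        required = ("dose_path", "mask_paths", "rx_gy", "n_fractions", "mu_total")
        missing = [k for k in required if k not in payload]
        if missing:
            raise ValueError(f"{path}: manifest missing required fields {missing}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def read_plan(manifest: PlanManifest | str | Path) -> Plan:
    """Load a full plan (dose + masks) described by a manifest."""
    if not isinstance(manifest, PlanManifest):
        manifest = PlanManifest.from_json(manifest)
    base = Path(getattr(manifest, "_base_dir", "."))
    dose = read_dose_nrrd(base / manifest.dose_path)
    masks = {
        label: read_mask_nrrd(base / p, label) for label, p in manifest.mask_paths.items()
    }
    return Plan(
        dose=dose,
        masks=masks,
        rx_gy=manifest.rx_gy,
        n_fractions=manifest.n_fractions,
        mu_total=manifest.mu_total,
        algorithm=manifest.algorithm,
        arm=manifest.arm,
        patient_id=manifest.patient_id,
    )


def load_plan(manifest_path: str | Path) -> Plan:
    """Load a plan resolving relative paths against the manifest's directory."""
    manifest_path = Path(manifest_path)
    manifest = PlanManifest.from_json(manifest_path)
    manifest._base_dir = str(manifest_path.parent)  # type: ignore[attr-defined]
    return read_plan(manifest)


def write_plan(plan: Plan, directory: str | Path) -> Path:
    """Write dose, masks, and manifest under a directory; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_grid_nrrd(plan.dose, directory / "dose.nrrd")
    mask_paths = {}
    for label, mask in plan.masks.items():
        name = f"mask_{label}.nrrd"
        write_grid_nrrd(mask, directory / name)
        mask_paths[label] = name
    manifest = PlanManifest(
        dose_path="dose.nrrd",
        mask_paths=mask_paths,
        rx_gy=plan.rx_gy,
        n_fractions=plan.n_fractions,
        mu_total=plan.mu_total,
        algorithm=plan.algorithm,
        arm=plan.arm,
        patient_id=plan.patient_id,
    )
    path = directory / "manifest.json"
    manifest.to_json(path)
    return path


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    table.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    bad_arms = set(table["arm"]) - set(ARMS)
    if bad_arms:
        raise ValueError(f"{path}: unknown arm labels {sorted(bad_arms)}")
    dup = table.duplicated(subset=["patient_id", "arm"])
    if dup.any():
        pairs = table.loc[dup, ["patient_id", "arm"]].to_records(index=False).tolist()
        raise ValueError(f"{path}: duplicate (patient, arm) rows {pairs}")
    # islands round-trip through CSV as booleans or NaN (unknown)
    if table["island"].dtype == object:
        table["island"] = table["island"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return table
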