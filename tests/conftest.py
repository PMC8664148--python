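import numpy as np
import pytest

from sbrtqa import DoseGrid, Plan, StructureMask


def make_grid(values, spacing=(2.5, 2.5, 2.5), origin=(0.0, 0.0, 0.0)) -> DoseGrid:
    return DoseGrid(np.asarray(values, dtype=float), spacing, origin)


def make_mask(voxels, label="ptv", spacing=(2.5, 2.5, 2.5), origin=(0.0, 0.0, 0.0)) -> StructureMask:
    return StructureMask(np.asarray(voxels, dtype=bool), label, spacing, origin)


def sphere_mask(shape, center_vox, radius_vox) -> np.ndarray:
    idx = np.indices(shape)
    d2 = sum((idx[a] - center_vox[a]) ** 2 for a in range(3))
    return d2 <= radius_vox**2


@pytest.fixture
def worked_example_plan() -> Plan:
    """A ~10 cc spherical PTV receiving exactly Rx, with a uniform 48%-of-Rx
    dose bath everywhere else, on a grid large enough to have voxels beyond
    the 2 cm margin. D2cm is exactly 48% of Rx by construction; the voxelized
    sphere (9.67 cc) sits inside the flat 50%-threshold band of 7.4-13.2 cc."""
    shape = (32, 32, 32)
    spacing = (2.5, 2.5, 2.5)
    ptv = sphere_mask(shape, (16, 16, 16), 5.35)
    rx = 60.0
    dose = np.full(shape, 0.48 * rx)
    dose[ptv] = rx
    masks = {
        "ptv": StructureMask(ptv, "ptv", spacing),
        "body": StructureMask(np.ones(shape, dtype=bool), "body", spacing),
    }
    return Plan(
        dose=DoseGrid(dose, spacing),
        masks=masks,
        rx_gy=rx,
        mu_total=2000.0,
        patient_id="EX01",
    )
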