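# sbrtqa

Plan-quality evaluation and guideline derivation for lung stereotactic body
radiation therapy (SBRT), for medical physicists and planning-study authors.

Lung SBRT delivers few-fraction, high-dose, highly conformal treatments
through low-density lung tissue. Plan quality is judged against RTOG/NRG
protocol metrics, but those thresholds were developed with
convolution-superposition dose engines (e.g., AAA). More accurate linear
Boltzmann transport engines (Acuros XB) calculate systematically lower target
coverage for the same monitor units, especially for "island" targets
surrounded by lung, so a plan graded against the historical thresholds is not
judged on the dose it actually delivers. `sbrtqa` implements the full metric
pipeline, the deviation grading, the coverage renormalization workflow, and
the cohort-ratio method that rescales the historical thresholds into
algorithm-adapted ("AXB-equivalent") guidelines.

## What it computes

Per plan (3D dose grid + binary structure masks on the same grid):

- **Coverage**: V100% and V90% (percent of PTV receiving >= 100% / 90% of the
  prescription Rx), D95% (dose covering 95% of the PTV, % of Rx), and the
  near-minimum dose D_min to 0.03 cc — all on the exact voxel multiset, with
  no DVH binning.
- **Heterogeneity**: 3D maximum dose and the ratio Rx/D_max (protocol window
  0.60–0.90), and V105% — volume *outside* the PTV above 105% of Rx, as % of
  PTV volume (limit < 15%).
- **Conformality and falloff**: CI = V_100%Rx / V_PTV, R50 = V_50%Rx / V_PTV,
  and D_2cm — the maximum dose (% of Rx) anywhere in the patient more than
  2 cm from the PTV, via an exact anisotropic Euclidean distance transform.
- **Normalized falloff**: D'_2cm and R50' divide the measured value by the
  PTV-volume-interpolated threshold at which a minor deviation begins; a
  value below 1.0 meets the guideline at any target size.
- **Deviation grading**: CI/R50/D_2cm -> none / minor / major against
  thresholds linearly interpolated in PTV volume between the tabulated
  protocol rows; coverage metrics -> pass / deviation.
- **Island classification**: a target is island-type when its PTV is at
  least 1 cm from the chest wall.

Per cohort (paired plan/recalculated/renormalized arms):

- two-sided paired t-tests per metric, deviation count tables, per-patient
  relative differences (M_AXB − M_AAA)/M_AAA vs PTV volume, and the
  small/large stratification at 20 cm³;
- **guideline derivation**: each current limit is multiplied by the ratio of
  cohort means (recalculated / baseline) of its metric — coverage limits by
  the coverage ratios, CI by the CI ratio, D_2cm and R50 columns by the
  normalized D'_2cm and R50' ratios — with explicit per-column rounding;
- **renormalization**: global rescaling of dose and MU by Rx/D95 so 95% PTV
  coverage is restored (beam weights untouched).

A synthetic paired-cohort generator (`sbrtqa.synthetic`) emulates the
statistical structure of such a planning study — ellipsoidal PTVs abutting or
clear of a chest-wall slab, conformal dose with penumbra and anisotropic
falloff, and a phenomenological recalculation shift — so the entire pipeline
runs and is tested without any clinical data. See `docs/methods.md` for the
model and its limitations.

## Worked example

A 9.7 cc spherical PTV receiving exactly Rx = 60 Gy inside a uniform dose
bath at 48% of Rx:

```python
import numpy as np
from sbrtqa import (DoseGrid, StructureMask, Plan, load_guidelines,
                    compute_plan_metrics, classify_plan)

shape, spacing = (32, 32, 32), (2.5, 2.5, 2.5)
idx = np.indices(shape)
ptv = sum((idx[a] - 16) ** 2 for a in range(3)) <= 5.35**2
dose = np.full(shape, 0.48 * 60.0)
dose[ptv] = 60.0
plan = Plan(
    dose=DoseGrid(dose, spacing),
    masks={"ptv": StructureMask(ptv, "ptv", spacing),
           "body": StructureMask(np.ones(shape, bool), "body", spacing)},
    rx_gy=60.0, mu_total=2000.0,
)
gset = load_guidelines("current")
m = compute_plan_metrics(plan, gset)
print(m.ptv_cc, m.d2cm_pct, m.d2cm_prime)
print(classify_plan(m, gset).volume_specific)
```

prints

```
9.671875 48.0 0.96
{'ci': 'none', 'r50': 'none', 'd2cm': 'none'}
```

The PTV is 9.67 cc, so the interpolated D_2cm none/minor boundary is 50% of
Rx; the measured 48% gives D'_2cm = 48/50 = 0.96 < 1, i.e., the falloff
meets the guideline with 4% of margin. (This plan's perfectly uniform target
dose also puts Rx/D_max = 1.0 above the 0.90 protocol ceiling — grading it
flags that as the one deviation.)

The same pipeline drives a CLI: `sbrtqa simulate-cohort`, `sbrtqa metrics`,
`sbrtqa evaluate`, `sbrtqa renormalize`, `sbrtqa derive-guidelines`, and
`sbrtqa compare` (see `sbrtqa --help`).

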