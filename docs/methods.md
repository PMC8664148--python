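# Methods

## Geometry and volume conventions

Dose grids are axis-aligned scalar fields with per-axis spacing in mm; voxel
(i, j, k) sits at `origin + index * spacing` (voxel-center convention).
Structure volumes are voxel counts times the voxel volume, with no
partial-volume interpolation: the counting rule is exact, additive over
disjoint masks, and directly checkable against enumeration, whereas any
sub-voxel surface model would introduce an unverifiable convention. Oblique
volumes are rejected at read time rather than resampled.

## DVH metrics on the exact voxel multiset

All dose-volume quantities are computed on the un-binned multiset of
per-voxel doses inside a structure, so there is no histogram bin width to
tune and every operation has a brute-force sort/scan oracle:

- `Dx` is the largest voxel dose d with at least x% of the structure at or
  above d (inclusive `>=`); `Vd` is the percent of voxels at or above d.
  By construction `V(Dx) >= x`, with equality at achievable volume fractions.
- The near-minimum dose to a cold volume c is the largest voxel dose whose
  strictly-colder volume does not exceed c; at c = 0 it reduces to the plain
  minimum. With 0.03 cc on typical grids this excludes one or two voxels.
- The hot-spill metric V105 counts voxels **strictly above** 105% of Rx and
  **outside** the PTV, following the protocol wording; all other thresholds
  are inclusive.

## Spatial metrics

CI and R50 are prescription and half-prescription isodose volumes over the
whole grid (or the body mask when given) divided by PTV volume; by
monotonicity of isodose volumes, R50 >= CI always. D_2cm takes the exact
Euclidean distance transform of the PTV (anisotropic spacing honored,
voxel-center to voxel-center) and reports the maximum dose, as % of Rx, over
voxels strictly beyond 20 mm, intersected with the body mask when available.
Island classification thresholds the minimum PTV-to-chest-wall distance at
10 mm, inclusive ("at least 1 cm").

## Deviation grading and normalized falloff metrics

The volume-specific thresholds (CI, R50, D_2cm) are stored as the published
table rows and linearly interpolated in PTV volume between rows, clamped
outside the 1.8–163 cc range; the interpolation form is a package choice —
the protocols state only that intermediate volumes are interpolated. Grading
follows the printed notation: below the none-limit is no deviation (strict
`<`), the minor band is closed on both ends, above it is major. Coverage
metrics (V100, V90, V105, Rx/D_max) are pass/fail only. The normalized
metrics D'_2cm and R50' divide the measured value by the interpolated
none/minor boundary, so "none" is exactly equivalent to a normalized value
below 1.0 — a property the test suite asserts on random plans.

One tension in the source tables is worth recording: the volume-specific
R50 "variation" column used as the basis of the guideline derivation
(4.7/4.5/4.3/4.0 at 13.2/22/34/50 cc, RTOG-0915-style) differs at 13.2 and
22 cc from the integerized R50 none-column of the classification table
(5/5/4/4). The package keeps both: classification uses the classification
table; derivation scales the derivation table (`data/derivation_current.json`),
which is the only basis that reproduces the published proposed values.

## Renormalization

Recalculated plans are rescaled by the single factor Rx / D95 so that 95% of
the PTV receives the prescription again; MU scales by exactly the same
factor and relative beam weights are untouched. On the exact voxel multiset
the post-scaling D95 hits Rx exactly, so renormalization is idempotent and
V100 returns to at least 95%. No re-optimization is modeled.

## Guideline derivation

For each metric M, the scaling ratio is mean(M, recalculated arm) /
mean(M, baseline arm) over paired patients. Proposed limits are current
limits times the ratio of their metric; the coverage recommendations (D95,
V100) are the recalculated-arm means themselves; D_2cm and R50 columns use
the normalized D'_2cm and R50' ratios, the only forms comparable across
target sizes. Rounding is explicit per-column configuration, chosen to match
the published tables and logged with every derivation: percent limits to one
decimal, CI to two decimals, D_2cm to the nearest integer, R50 truncated at
two decimals (truncation, not rounding, is required to reproduce the
published 4.46/4.26/5.45/5.25 values). The derived CI major limit comes out
at 1.40 while the published table prints 1.41, which is not reproducible
from the printed means; the derivation emits 1.40 and attaches a note. By
default the volume-specific output covers 13.2–50 cc, the range supported by
the underlying cohort's target sizes; a full-range derivation is available
behind a flag with a warning. A coverage-equivalent prescription reduction
is provided as `scaled_prescription` (e.g., 60 Gy at a 98.2% D95 target ->
58.92 Gy, rounded to 0.01 Gy).

## Cohort statistics

Arm comparisons use the classical two-sided paired t-test (df = n − 1) with
no multiple-testing correction, flagging zero-variance differences as
degenerate instead of reporting a p-value. Deviation tables count minor/major
per metric, arm, and island subgroup; pass/fail metrics contribute to the
minor column. The size stratification splits at 20 cm³ and compares
per-patient relative differences (M_recalc − M_plan)/M_plan between strata
with an unpaired two-sided t-test; the choice of the unpaired t for the
between-strata comparison is the package's own, as no specific test is
prescribed for it. The mean MU increase needed to restore coverage is
reported both as the ratio of arm MU means and as the inverse coverage ratio
(100/D95 − 1); the two differ in the second decimal on skewed cohorts.

## Synthetic cohort model

Each phantom patient has an ellipsoidal PTV with log-normally distributed
volume (median 18 cc, log-sd 0.45, clipped to 7.58–74.06 cc — the spread of
a typical early-stage lung SBRT cohort) and random axis ratios, placed
either at least 12 mm from a 1 cm chest-wall slab (island, 13/30 of patients
by default) or 2.5–7 mm from it. The dose, in % of Rx, is a monotone
function of the signed distance from an angularly modulated prescription
surface: inside, a linear rim (5.4 %/mm over 1.8 mm) blending into a plateau
with a hotspot peaking near 120.5%; outside, an exponential falloff whose
length grows with target radius and with one slow "beam channel" direction,
giving R50 and D_2cm values in the protocol's working range. The angular
modulation (a shallow cold baseline, one deeper cold lobe, several outward
hot lobes) creates both the cold rim inside the PTV and the conformality
spill outside it, so V100 ≈ 95 and CI ≈ 1.1–1.2 coexist as they do in real
conformal arc plans. Every baseline plan is normalized so D95 = Rx exactly.

The recalculation shift is phenomenological, not transport physics: a
per-patient global output factor (mean 0.9911 for chest-wall-adjacent
targets, 0.9703 for islands, sd 0.013, bounded so the implied MU correction
spans about −2% to +7.5%), relaxed linearly back to 1 below 75% of Rx
(charged-particle-equilibrium far field), an extra deepening of the cold rim
(0.8% at the coldest edge), and a peak boost (mean +2.7%) reproducing the
greater dose heterogeneity of Boltzmann-transport calculations. The dose-
shape and shift defaults were calibrated once, jointly, against the cohort
means of a published AAA-vs-AXB planning study (recalculated V100 ≈ 91.4%,
CI ratio ≈ 0.93, D'_2cm ≈ 1.0, Rx/D_max ≈ 0.83) and then frozen; the
calibration lives in the defaults of `CohortConfig`/`ShiftParams`.

What the generator does **not** emulate: CT texture and real heterogeneity
corrections, beam/arc geometry and MLC apertures, motion, or any physics of
the dose engines. Consequently, passing tests demonstrate that the analysis
pipeline is correct and that the derivation recovers configured effect
sizes — they do not validate the clinical magnitude of algorithm differences,
and cohort-specific deviation counts of any real study are not reproducible
from synthetic data (only their internal consistency and the direction of
the renormalization-induced minor-to-major R50 shift are asserted).

## Numerical choices and problem sizes

DVH quantiles guard the `ceil` index against float noise (1e-9); rounding
helpers use half-up at the stated precision rather than banker's rounding.
Synthetic grids default to 64³ voxels at 2.5 mm — large enough that every
PTV keeps a > 2 cm margin inside the body — and the calibration-level tests
average three 30-patient cohorts, which keeps the full suite around a
minute on one CPU. Degenerate inputs (empty masks, zero prescriptions,
oblique volumes, unpaired cohorts, zero-variance tests) raise typed errors
or flagged report entries rather than propagating NaNs.

## Known limitations

- Voxel-exact DVHs differ from TPS values that interpolate between voxels;
  at 2.5 mm grids the difference is below the grading granularity but it is
  a convention, not ground truth.
- Threshold interpolation is linear because no functional form is published.
- The published cohort-mean R50' of ~0.9 coexists uneasily with a high
  reported count of R50 minor deviations; the normalized-metric convention
  implemented here follows the published worked example (48/50 -> 0.96),
  and the tension is inherited from the source tables, not resolved.
- The chest-wall/lung organ-at-risk limits are carried in the guideline set
  but OAR dose evaluation beyond those two checks is out of scope.
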