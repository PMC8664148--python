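"""Derive algorithm-adapted guideline limits by cohort-ratio scaling.

The derivation takes the ratio of cohort means (recalculated arm over
baseline plan arm) for each metric and applies it to the corresponding
current limit. The falloff columns are scaled with the ratios of the
normalized metrics D'2cm and R50' (the forms that are comparable across PTV
volumes); coverage limits use the coverage-metric ratios directly.

Per-column rounding of the proposed values is explicit configuration:
percent-scale limits round to 1 decimal, CI to 2 decimals, D2cm to the
nearest integer, and R50 truncates at 2 decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .guidelines import GuidelineRow, GuidelineSet, load_guidelines

__all__ = [
    "ScalingFactors",
    "ProposedGuidelines",
    "RATIO_METRICS",
    "DEFAULT_ROUNDING",
    "cohort_ratios",
    "scale_volume_independent",
    "scale_volume_table",
    "derive_guidelines",
    "scaled_prescription",
    "load_derivation_current",
]

#: cohort-table columns for which arm-mean ratios are formed
RATIO_METRICS = (
    "d95_pct",
    "v100_pct",
    "v90_pct",
    "rx_over_dmax",
    "v105_pct",
    "ci",
    "d2cm_prime",
    "r50_prime",
)

DEFAULT_ROUNDING = {"ci": "round2", "d2cm": "int", "r50": "trunc2", "percent": "round1"}


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def _apply_rounding(x: float, rule: str) -> float:
    if rule == "round1":
        return _round_half_up(x, 1)
    if rule == "round2":
        return _round_half_up(x, 2)
    if rule == "int":
        return float(math.floor(x + 0.5))
    if rule == "trunc2":
        return math.floor(x * 100.0 + 1e-9) / 100.0
    raise ValueError(f"unknown rounding rule {rule!r}")


@dataclass(frozen=True)
class ScalingFactors:
    """Per-metric ratios of cohort means, recalculated arm over plan arm."""

    ratios: dict[str, float]
    means_plan: dict[str, float]
    means_recalc: dict[str, float]
    n: int

    def __getitem__(self, metric: str) -> float:
        return self.ratios[metric]


def load_derivation_current() -> GuidelineSet:
    """Current volume-specific limits used as the scaling basis (13.2-50 cc)."""
    text = (resources.files("sbrtqa") / "data" / "derivation_current.json").read_text()
    payload = json.loads(text)
    rows = tuple(GuidelineRow(*row) for row in payload["volume_rows"])
    return GuidelineSet(rows=rows, name=payload.get("name", "derivation-current"))


def cohort_ratios(cohort: pd.DataFrame, plan_arm: str = "plan",
                  recalc_arm: str = "recalculated",
                  metrics: tuple[str, ...] = RATIO_METRICS) -> ScalingFactors:
    """Ratio of arm means per metric between paired cohort arms.

    Every patient must contribute exactly one row per arm; unpaired patients
    raise a pairing error naming the offenders.
    """
    plan = cohort[cohort["arm"] == plan_arm]
    recalc = cohort[cohort["arm"] == recalc_arm]
    ids_plan, ids_recalc = set(plan["patient_id"]), set(recalc["patient_id"])
    unpaired = sorted(ids_plan ^ ids_recalc)
    if unpaired:
        raise ValueError(f"unpaired patients between arms: {unpaired}")
    for arm_name, frame in ((plan_arm, plan), (recalc_arm, recalc)):
        if frame["patient_id"].duplicated().any():
            dup = sorted(frame.loc[frame["patient_id"].duplicated(), "patient_id"])
            raise ValueError(f"duplicate patients in arm {arm_name!r}: {dup}")
    if len(plan) == 0:
        raise ValueError("empty cohort")
    means_plan = {m: float(plan[m].mean()) for m in metrics}
    means_recalc = {m: float(recalc[m].mean()) for m in metrics}
    ratios = {m: means_recalc[m] / means_plan[m] for m in metrics}
    return ScalingFactors(
        ratios=ratios, means_plan=means_plan, means_recalc=means_recalc, n=len(plan)
    )


@dataclass
class ProposedGuidelines:
    """Algorithm-adapted limits: volume-independent plus a volume-specific table."""

    d95_target_pct: float
    v100_target_pct: float
    v90_min_pct: float
    v105_max_pct: float
    rx_over_dmax_range: tuple[float, float]
    rx_over_dmax_range_pct: tuple[float, float]
    volume_table: pd.DataFrame  # columns: ptv_cc, current/proposed per metric
    ratios: ScalingFactors
    rounding: dict[str, str]
    notes: list[str] = field(default_factory=list)

    def to_guideline_set(self) -> GuidelineSet:
        rows = tuple(
            GuidelineRow(
                ptv_cc=row["ptv_cc"],
                ci_none=row["ci_none_proposed"],
                ci_minor_upper=row["ci_minor_upper_proposed"],
                r50_none=row["r50_none_proposed"],
                r50_minor_upper=row["r50_minor_upper_proposed"],
                d2cm_none=row["d2cm_none_proposed"],
                d2cm_minor_upper=row["d2cm_minor_upper_proposed"],
            )
            for _, row in self.volume_table.iterrows()
        )
        return GuidelineSet(
            rows=rows,
            d95_target_pct=self.d95_target_pct,
            v100_target_pct=self.v100_target_pct,
            v90_min_pct=self.v90_min_pct,
            v105_max_pct=self.v105_max_pct,
            rx_over_dmax_range=self.rx_over_dmax_range,
            name="axb-proposed-derived",
        )

    def volume_independent_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("D95%", 100.0, self.d95_target_pct),
                ("V100%", 95.0, self.v100_target_pct),
                ("V90%", 99.0, self.v90_min_pct),
                ("V105%", 15.0, self.v105_max_pct),
                ("Rx/Dmax (min)", 0.60, self.rx_over_dmax_range[0]),
                ("Rx/Dmax (max)", 0.90, self.rx_over_dmax_range[1]),
            ],
            columns=["guideline", "current", "proposed"],
        )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.volume_independent_table().to_csv(
            directory / "proposed_volume_independent.csv", index=False
        )
        self.volume_table.to_csv(directory / "proposed_volume_specific.csv", index=False)
        payload = {
            "d95_target_pct": self.d95_target_pct,
            "v100_target_pct": self.v100_target_pct,
            "v90_min_pct": self.v90_min_pct,
            "v105_max_pct": self.v105_max_pct,
            "rx_over_dmax_range": list(self.rx_over_dmax_range),
            "rx_over_dmax_range_pct": list(self.rx_over_dmax_range_pct),
            "ratios": self.ratios.ratios,
            "rounding": self.rounding,
            "notes": self.notes,
            "volume_table": self.volume_table.to_dict(orient="records"),
        }
        (directory / "proposed_guidelines.json").write_text(json.dumps(payload, indent=2))


def scale_volume_independent(current: GuidelineSet, r: ScalingFactors,
                             rounding: dict[str, str] | None = None) -> dict[str, float]:
    """Scale the volume-independent limits by the cohort ratios.

    The coverage recommendations (D95, V100) are the recalculated-arm means
    themselves; V90/V105/Rx-Dmax limits are the current limits times their
    metric ratios.
    """
    rounding = {**DEFAULT_ROUNDING, **(rounding or {})}
    for m in ("v90_pct", "v105_pct", "rx_over_dmax"):
        if m not in r.ratios:
            raise ValueError(f"missing ratio for {m}")
    pct = rounding["percent"]
    lo, hi = current.rx_over_dmax_range
    return {
        "d95_target_pct": _apply_rounding(r.means_recalc["d95_pct"], pct),
        "v100_target_pct": _apply_rounding(r.means_recalc["v100_pct"], pct),
        "v90_min_pct": _apply_rounding(current.v90_min_pct * r["v90_pct"], pct),
        "v105_max_pct": _apply_rounding(current.v105_max_pct * r["v105_pct"], pct),
        "rx_over_dmax_min": _apply_rounding(lo * r["rx_over_dmax"], "round2"),
        "rx_over_dmax_max": _apply_rounding(hi * r["rx_over_dmax"], "round2"),
        "rx_over_dmax_min_pct": _apply_rounding(100.0 * lo * r["rx_over_dmax"], pct),
        "rx_over_dmax_max_pct": _apply_rounding(100.0 * hi * r["rx_over_dmax"], pct),
    }


def scale_volume_table(current: GuidelineSet, r: ScalingFactors,
                       rounding: dict[str, str] | None = None,
                       volume_range_cc: tuple[float, float] | None = (13.2, 50.0),
                       ) -> pd.DataFrame:
    """Scale each volume-specific threshold by its metric ratio.

    CI limits scale by the CI-mean ratio, D2cm by the D'2cm ratio, and R50 by
    the R50' ratio. Rows outside ``volume_range_cc`` are dropped (pass None to
    derive for every tabulated volume).
    """
    rounding = {**DEFAULT_ROUNDING, **(rounding or {})}
    ratio_of = {"ci": "ci", "d2cm": "d2cm_prime", "r50": "r50_prime"}
    records = []
    for row in current.rows:
        if volume_range_cc is not None and not (
            volume_range_cc[0] <= row.ptv_cc <= volume_range_cc[1]
        ):
            continue
        rec: dict[str, float] = {"ptv_cc": row.ptv_cc}
        for metric in ("ci", "d2cm", "r50"):
            ratio = r[ratio_of[metric]]
            rule = rounding[metric]
            for bound in ("none", "minor_upper"):
                cur = getattr(row, f"{metric}_{bound}")
                rec[f"{metric}_{bound}_current"] = cur
                rec[f"{metric}_{bound}_proposed"] = _apply_rounding(cur * ratio, rule)
        records.append(rec)
    if not records:
        raise ValueError("no guideline rows inside the requested volume range")
    return pd.DataFrame.from_records(records)


def derive_guidelines(r: ScalingFactors,
                      current: GuidelineSet | None = None,
                      current_volume_table: GuidelineSet | None = None,
                      rounding: dict[str, str] | None = None,
                      volume_range_cc: tuple[float, float] | None = (13.2, 50.0),
                      ) -> ProposedGuidelines:
    """Full derivation: volume-independent limits plus the volume-specific table."""
    if current is None:
        current = load_guidelines("current")
    if current_volume_table is None:
        current_volume_table = load_derivation_current()
    vi = scale_volume_independent(current, r, rounding)
    table = scale_volume_table(current_volume_table, r, rounding, volume_range_cc)
    notes = [
        "volume-specific table derived over the supported PTV volume range only; "
        "other volumes are expected to show similar trends",
    ]
    published_ci_major = 1.41
    derived_ci_major = float(table["ci_minor_upper_proposed"].iloc[0])
    if abs(derived_ci_major - published_ci_major) > 1e-9:
        notes.append(
            f"derived CI major threshold {derived_ci_major:.2f} differs from the "
            f"published {published_ci_major:.2f}, which is not reproducible from the "
            "printed cohort means"
        )
    return ProposedGuidelines(
        d95_target_pct=vi["d95_target_pct"],
        v100_target_pct=vi["v100_target_pct"],
        v90_min_pct=vi["v90_min_pct"],
        v105_max_pct=vi["v105_max_pct"],
        rx_over_dmax_range=(vi["rx_over_dmax_min"], vi["rx_over_dmax_max"]),
        rx_over_dmax_range_pct=(vi["rx_over_dmax_min_pct"], vi["rx_over_dmax_max_pct"]),
        volume_table=table,
        ratios=r,
        rounding={**DEFAULT_ROUNDING, **(rounding or {})},
        notes=notes,
    )


def scaled_prescription(rx_gy: float, d95_proposed_pct: float) -> float:
    """Prescription after the coverage-equivalent dose reduction, to 0.01 Gy."""
    if rx_gy <= 0:
        raise ValueError("rx_gy must be > 0")
    if not 0 < d95_proposed_pct <= 100:
        raise ValueError("d95_proposed_pct must be in (0, 100]")
    return _round_half_up(rx_gy * d95_proposed_pct / 100.0, 2)
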