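"""RTOG/NRG guideline tables, volume-interpolated thresholds, and deviation grading.

The volume-specific metrics (CI, R50, D2cm) are graded none / minor / major
against thresholds linearly interpolated in PTV volume between the tabulated
rows; the volume-independent metrics (V100, V90, V105, Rx/Dmax) are pass /
deviation only. Boundary convention follows the printed table notation:
"None <50" is strict, the minor band "50-57" is closed on both ends, and
anything above the minor upper bound is a major deviation.

The normalized metrics D'2cm and R50' divide the measured value by the
interpolated dose/ratio at which a minor deviation begins (the none/minor
boundary), so a value below 1.0 meets the guideline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .plan import PlanMetrics

__all__ = [
    "GuidelineRow",
    "GuidelineSet",
    "DeviationReport",
    "load_guidelines",
    "interpolate_thresholds",
    "d2cm_prime",
    "r50_prime",
    "classify_plan",
    "VOLUME_SPECIFIC_METRICS",
    "VOLUME_INDEPENDENT_METRICS",
]

VOLUME_SPECIFIC_METRICS = ("ci", "r50", "d2cm")
VOLUME_INDEPENDENT_METRICS = ("v100", "v90", "v105", "rx_over_dmax")

_ROW_COLUMNS = (
    "ptv_cc",
    "ci_none",
    "ci_minor_upper",
    "r50_none",
    "r50_minor_upper",
    "d2cm_none",
    "d2cm_minor_upper",
)


@dataclass(frozen=True)
class GuidelineRow:
    """Thresholds at (or interpolated to) one PTV volume.

    ``*_none`` is the upper limit of the no-deviation band (exclusive);
    ``*_minor_upper`` is the upper end of the minor-deviation band (inclusive).
    """

    ptv_cc: float
    ci_none: float
    ci_minor_upper: float
    r50_none: float
    r50_minor_upper: float
    d2cm_none: float
    d2cm_minor_upper: float

    def __post_init__(self):
        for metric in VOLUME_SPECIFIC_METRICS:
            none = getattr(self, f"{metric}_none")
            upper = getattr(self, f"{metric}_minor_upper")
            if not none < upper:
                raise ValueError(
                    f"{metric}: none-limit {none} must be < minor-upper {upper}"
                )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in _ROW_COLUMNS)


@dataclass(frozen=True)
class GuidelineSet:
    """An ordered volume-specific threshold table plus volume-independent limits."""

    rows: tuple[GuidelineRow, ...]
    d95_target_pct: float = 100.0
    v100_target_pct: float = 95.0
    v90_min_pct: float = 99.0
    v105_max_pct: float = 15.0
    rx_over_dmax_range: tuple[float, float] = (0.6, 0.9)
    oar: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        vols = [r.ptv_cc for r in self.rows]
        if len(vols) < 1 or any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("rows must be nonempty and strictly increasing in ptv_cc")
        lo, hi = self.rx_over_dmax_range
        if not 0 < lo < hi:
            raise ValueError("rx_over_dmax_range must satisfy 0 < min < max")
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def volumes_cc(self) -> np.ndarray:
        return np.array([r.ptv_cc for r in self.rows])

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.rows])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "volume_rows": [list(r.as_tuple()) for r in self.rows],
            "d95_target_pct": self.d95_target_pct,
            "v100_target_pct": self.v100_target_pct,
            "v90_min_pct": self.v90_min_pct,
            "v105_max_pct": self.v105_max_pct,
            "rx_over_dmax_range": list(self.rx_over_dmax_range),
            "oar": self.oar,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_mapping(cls, payload: dict) -> "GuidelineSet":
        rows = tuple(GuidelineRow(*row) for row in payload["volume_rows"])
        return cls(
            rows=rows,
            d95_target_pct=payload.get("d95_target_pct", 100.0),
            v100_target_pct=payload.get("v100_target_pct", 95.0),
            v90_min_pct=payload.get("v90_min_pct", 99.0),
            v105_max_pct=payload.get("v105_max_pct", 15.0),
            rx_over_dmax_range=tuple(payload.get("rx_over_dmax_range", (0.6, 0.9))),
            oar=payload.get("oar", {}),
            name=payload.get("name", ""),
        )


def load_guidelines(source: str | Path = "current") -> GuidelineSet:
    """Load a guideline set: "current", "proposed" (published), or a JSON file path."""
    packaged = {
        "current": "guidelines_current.json",
        "proposed": "guidelines_proposed_published.json",
    }
    if str(source) in packaged:
        text = (resources.files("sbrtqa") / "data" / packaged[str(source)]).read_text()
    else:
        text = Path(source).read_text()
    return GuidelineSet.from_mapping(json.loads(text))


def interpolate_thresholds(gset: GuidelineSet, ptv_cc: float) -> GuidelineRow:
    """Piecewise-linear interpolation of every threshold column in PTV volume.

    Volumes outside the tabulated range are clamped to the first/last row.
    """
    if ptv_cc <= 0:
        raise ValueError("ptv_cc must be > 0")
    vols = gset.volumes_cc
    values = {
        c: float(np.interp(ptv_cc, vols, gset.column(c))) for c in _ROW_COLUMNS[1:]
    }
    return GuidelineRow(ptv_cc=float(ptv_cc), **values)


def d2cm_prime(d2cm_measured: float, d2cm_none_threshold: float) -> float:
    """Measured D2cm (% of Rx) divided by the none/minor boundary; < 1 passes."""
    if d2cm_none_threshold <= 0:
        raise ValueError("threshold must be > 0")
    return d2cm_measured / d2cm_none_threshold


def r50_prime(r50_measured: float, r50_none_threshold: float) -> float:
    """Measured R50 divided by the none/minor boundary; < 1 passes."""
    if r50_none_threshold <= 0:
        raise ValueError("threshold must be > 0")
    return r50_measured / r50_none_threshold


def _grade(value: float, none_limit: float, minor_upper: float) -> str:
    if value < none_limit:
        return "none"
    if value <= minor_upper:
        return "minor"
    return "major"


@dataclass
class DeviationReport:
    """Per-metric deviation grades for one plan.

    ``volume_specific`` maps ci/r50/d2cm to none/minor/major;
    ``volume_independent`` maps v100/v90/v105/rx_over_dmax to none/deviation.
    """

    ptv_cc: float
    volume_specific: dict[str, str]
    volume_independent: dict[str, str]
    thresholds: GuidelineRow
    missing: list[str] = field(default_factory=list)

    @property
    def grades(self) -> dict[str, str]:
        return {**self.volume_specific, **self.volume_independent}

    def as_dict(self) -> dict:
        return {
            "ptv_cc": self.ptv_cc,
            "volume_specific": dict(self.volume_specific),
            "volume_independent": dict(self.volume_independent),
            "thresholds": dict(zip(_ROW_COLUMNS, self.thresholds.as_tuple())),
            "missing": list(self.missing),
        }


def classify_plan(metrics: PlanMetrics, gset: GuidelineSet) -> DeviationReport:
    """Grade one plan's metrics against a guideline set.

    CI, R50 and D2cm are graded none/minor/major against thresholds
    interpolated at the plan's PTV volume; the coverage and hot-spill metrics
    are pass ("none") or "deviation" against the fixed limits.
    """
    thr = interpolate_thresholds(gset, metrics.ptv_cc)
    missing: list[str] = []

    vs: dict[str, str] = {}
    for metric, value in (("ci", metrics.ci), ("r50", metrics.r50), ("d2cm", metrics.d2cm_pct)):
        if value is None or not np.isfinite(value):
            missing.append(metric)
            continue
        vs[metric] = _grade(
            value, getattr(thr, f"{metric}_none"), getattr(thr, f"{metric}_minor_upper")
        )

    vi: dict[str, str] = {}
    checks = {
        "v100": metrics.v100_pct >= gset.v100_target_pct,
        "v90": metrics.v90_pct >= gset.v90_min_pct,
        "v105": metrics.v105_pct < gset.v105_max_pct,
        "rx_over_dmax": (
            gset.rx_over_dmax_range[0] <= metrics.rx_over_dmax <= gset.rx_over_dmax_range[1]
        ),
    }
    for metric, ok in checks.items():
        vi[metric] = "none" if ok else "deviation"

    return DeviationReport(
        ptv_cc=metrics.ptv_cc,
        volume_specific=vs,
        volume_independent=vi,
        thresholds=thr,
        missing=missing,
    )
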