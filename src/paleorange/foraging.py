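"""Bioavailable-Sr baselines and local/extra-local foraging classification.

Builds per-geological-unit 87Sr/86Sr baselines from plant samples,
classifies fossil specimens against the local units (host limestone first,
then the broader formation), ranks candidate source units for extra-local
specimens by distance in ratio space, and carries the one-way ANOVA used to
compare U-Th ages across stratigraphic units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BaselineUnit",
    "SpecimenSignature",
    "MobilityClassification",
    "build_baseline",
    "interval_overlap",
    "classify_specimen",
    "anova_oneway",
    "range_geometry",
]


@dataclass
class BaselineUnit:
    """Per-geological-unit bioavailable 87Sr/86Sr baseline (plants)."""

    unit: str
    mean: float
    two_se: float
    n: int
    local: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.two_se, self.mean + self.two_se)


@dataclass
class SpecimenSignature:
    """Per-specimen enamel 87Sr/86Sr summary."""

    tooth: str
    unit: str  # stratigraphic unit of recovery
    mean: float
    two_se: float
    transects: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.two_se, self.mean + self.two_se)


@dataclass
class MobilityClassification:
    tooth: str
    verdict: Literal["local-limestone", "local-formation", "extra-local"]
    candidates: pd.DataFrame  # ranked by |Δ| with overlap flags

    def to_dict(self) -> dict:
        return {
            "tooth": self.tooth,
            "verdict": self.verdict,
            "candidates": self.candidates.to_dict(orient="records"),
        }


def build_baseline(
    samples: Sequence[tuple[str, float]], local_units: Sequence[str] = ()
) -> list[BaselineUnit]:
    """Per-unit mean and 2SE from (unit, 87Sr/86Sr) plant samples.

    Units with a single sample get 2SE = 0 and a ``range_unknown`` flag.
    """
    df = pd.DataFrame(samples, columns=["unit", "ratio"])
    out = []
    for unit, grp in df.groupby("unit", sort=False):
        vals = grp["ratio"].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            continue
        mean = float(np.mean(vals))
        two_se = 2.0 * float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        flags = ["range_unknown"] if n == 1 else []
        out.append(
            BaselineUnit(str(unit), mean, two_se, n,
                         local=str(unit) in set(local_units), flags=flags)
        )
    return out


def interval_overlap(
    a: tuple[float, float],
    b: tuple[float, float],
    mode: Literal["overlap", "containment"] = "overlap",
) -> bool:
    """Whether mean±2SE intervals a and b intersect (``overlap``) or a's
    interval lies entirely inside b's (``containment``). Each argument is
    (mean, 2SE)."""
    a_lo, a_hi = a[0] - a[1], a[0] + a[1]
    b_lo, b_hi = b[0] - b[1], b[0] + b[1]
    if mode == "containment":
        return b_lo <= a_lo and a_hi <= b_hi
    return a_lo <= b_hi and b_lo <= a_hi


def _matches(spec: SpecimenSignature, unit: BaselineUnit,
             mode: str, point_tolerance: float) -> bool:
    if unit.two_se <= 1e-10:
        # degenerate (zero-width) baselines are compared by distance of means
        return abs(spec.mean - unit.mean) <= point_tolerance
    return interval_overlap((spec.mean, spec.two_se),
                            (unit.mean, unit.two_se), mode=mode)


def classify_specimen(
    spec: SpecimenSignature,
    baseline: Sequence[BaselineUnit],
    local_priority: Sequence[str] | None = None,
    mode: Literal["overlap", "containment"] = "containment",
    point_tolerance: float = 0.0003,
) -> MobilityClassification:
    """Classify a specimen as local or extra-local against the baseline.

    Local units are tested in priority order (host limestone first, then the
    broader formation); if neither matches, the verdict is extra-local and
    all units are ranked by |specimen mean − unit mean|. Units with n = 1
    (2SE unknown) match when the means differ by less than
    ``point_tolerance``.
    """
    units = {u.unit: u for u in baseline}
    if local_priority is None:
        # most specific (narrowest-interval) local unit first; stable under
        # permutation of the baseline rows
        local_priority = [
            u.unit for u in sorted(
                (u for u in baseline if u.local),
                key=lambda u: (u.two_se, u.unit),
            )
        ]
    missing = [u for u in local_priority if u not in units]
    if missing:
        raise ValueError(f"local units not in baseline: {missing}")
    rows = []
    for u in sorted(baseline, key=lambda u: abs(spec.mean - u.mean)):
        rows.append(
            {
                "unit": u.unit,
                "mean": u.mean,
                "two_se": u.two_se,
                "n": u.n,
                "abs_delta": abs(spec.mean - u.mean),
                "matches": _matches(spec, u, mode, point_tolerance),
                "local": u.unit in local_priority,
            }
        )
    table = pd.DataFrame(rows)
    verdict: str = "extra-local"
    for i, name in enumerate(local_priority):
        if _matches(spec, units[name], mode, point_tolerance):
            verdict = "local-limestone" if i == 0 else "local-formation"
            break
    return MobilityClassification(tooth=spec.tooth, verdict=verdict,  # type: ignore[arg-type]
                                  candidates=table)


def anova_oneway(groups: dict[str, Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA across labelled groups: returns (F, (df1, df2), p)."""
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(v) for v in vals)
    df1, df2 = len(vals) - 1, n_total - len(vals)
    if df2 < 1:
        raise ValueError("not enough observations for a one-way ANOVA")
    grand = np.mean(np.concatenate(vals))
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in vals)
    ss_within = sum(np.sum((v - np.mean(v)) ** 2) for v in vals)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, (df1, df2), 1.0
        return float("inf"), (df1, df2), 0.0
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def range_geometry(area_km2: float) -> float:
    """Radius (km) of the circle with the given area, for map comparison."""
    if area_km2 <= 0:
        raise ValueError("area must be > 0")
    return math.sqrt(area_km2 / math.pi)
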