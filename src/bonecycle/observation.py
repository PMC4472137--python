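"""Map remodeling cycles onto the trial visit schedule.

The simulation advances in remodeling cycles; the trial measured bone
turnover markers (serum P1NP, urinary NTX) at weeks 0, 1, 4, 12, 24, 48
and 72 and lumbar BMD at weeks 0, 24, 48 and 72.  With the assumed
4-week remodeling cycle, a visit week maps to cycle w / 4 when that is
an integer; week 1 cannot be represented and is never fitted.  Baseline
marker visits are also excluded from fitting by default because the
model emits markers only under the treatment rates (cycle >= 1), while
BMD is defined at baseline (cycle 0).

Model output is dimensionless volume; per-outcome multiplicative scale
factors convert it to measurement units for comparison with data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PlenaryTrajectory

__all__ = [
    "OUTCOMES",
    "MARKER_OUTCOMES",
    "VisitSchedule",
    "OutcomeScales",
    "CycleMapping",
    "PredictedObservations",
    "weeks_to_cycles",
    "predict_observations",
]

MARKER_OUTCOMES = ("P1NP", "NTX")
OUTCOMES = ("P1NP", "NTX", "BMD")


@dataclass(frozen=True)
class VisitSchedule:
    """Visit weeks per outcome group and the cycle length in weeks."""

    marker_weeks: tuple = (0, 1, 4, 12, 24, 48, 72)
    bmd_weeks: tuple = (0, 24, 48, 72)
    cycle_length_weeks: float = 4.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cycle_length_weeks) and self.cycle_length_weeks > 0):
            raise ValueError(
                f"cycle_length_weeks={self.cycle_length_weeks!r} must be > 0"
            )
        object.__setattr__(self, "marker_weeks", tuple(sorted(self.marker_weeks)))
        object.__setattr__(self, "bmd_weeks", tuple(sorted(self.bmd_weeks)))


@dataclass(frozen=True)
class OutcomeScales:
    """Measurement units per model volume unit, one factor per outcome."""

    s_P1NP: float = 1.0
    s_NTX: float = 1.0
    s_BMD: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_P1NP", "s_NTX", "s_BMD"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name}={v!r} must be a finite positive number")

    def for_outcome(self, outcome: str) -> float:
        return {"P1NP": self.s_P1NP, "NTX": self.s_NTX, "BMD": self.s_BMD}[outcome]


@dataclass(frozen=True)
class CycleMapping:
    """Result of mapping visit weeks to remodeling-cycle indices.

    ``marker_cycles`` / ``bmd_cycles`` hold the fittable week -> cycle
    maps; ``unmappable`` lists (group, week) pairs whose week is not an
    integer number of cycles; ``excluded`` lists mappable weeks dropped
    by policy, with the reason.
    """

    marker_cycles: dict
    bmd_cycles: dict
    unmappable: tuple
    excluded: tuple

    @property
    def max_cycle(self) -> int:
        cycles = list(self.marker_cycles.values()) + list(self.bmd_cycles.values())
        return max(cycles) if cycles else 0


def weeks_to_cycles(
    schedule: VisitSchedule, include_baseline_markers: bool = False
) -> CycleMapping:
    """Map each scheduled week to its remodeling-cycle index.

    Weeks that are not integer multiples of the cycle length are
    reported as unmappable, never silently rounded.  Marker weeks at
    cycle 0 are excluded (markers exist from cycle 1) unless
    ``include_baseline_markers`` is set, which maps them anyway for
    callers that handle baseline values themselves.
    """
    L = schedule.cycle_length_weeks
    marker_cycles: dict = {}
    bmd_cycles: dict = {}
    unmappable = []
    excluded = []
    for w in schedule.marker_weeks:
        c = w / L
        if abs(c - round(c)) > 1e-9:
            unmappable.append(("marker", w))
            continue
        c = int(round(c))
        if c == 0 and not include_baseline_markers:
            excluded.append(("marker", w, "baseline precedes the first on-treatment cycle"))
        else:
            marker_cycles[w] = c
    for w in schedule.bmd_weeks:
        c = w / L
        if abs(c - round(c)) > 1e-9:
            unmappable.append(("BMD", w))
        else:
            bmd_cycles[w] = int(round(c))
    return CycleMapping(marker_cycles, bmd_cycles, tuple(unmappable), tuple(excluded))


@dataclass(frozen=True)
class PredictedObservations:
    """Model predictions restricted to the fittable visit schedule.

    ``frame`` has one row per (outcome, week) with columns
    (outcome, week, cycle, predicted_value) in measurement units;
    ``dropped`` records the weeks no prediction was emitted for.
    """

    frame: pd.DataFrame
    dropped: tuple

    @property
    def n_predictions(self) -> int:
        return len(self.frame)

    def value(self, outcome: str, week: float) -> float:
        rows = self.frame[(self.frame["outcome"] == outcome) & (self.frame["week"] == week)]
        if rows.empty:
            raise KeyError(f"no prediction for {outcome} at week {week}")
        return float(rows["predicted_value"].iloc[0])


def predict_observations(
    traj: PlenaryTrajectory,
    schedule: VisitSchedule | None = None,
    scales: OutcomeScales | None = None,
) -> PredictedObservations:
    """Scale and subset a simulated trajectory to the visit schedule.

    Predictions are homogeneous of degree 1 in each scale factor and in
    the total initial volume jointly, which is why the scales are
    nuisance parameters during fitting.
    """
    schedule = schedule or VisitSchedule()
    scales = scales or OutcomeScales()
    mapping = weeks_to_cycles(schedule)
    if mapping.max_cycle > traj.n_cycles:
        missing = mapping.max_cycle
        raise ValueError(
            f"trajectory covers {traj.n_cycles} cycles but the schedule "
            f"requires cycle {missing}; simulate at least {missing} cycles"
        )
    rows = []
    for w, c in sorted(mapping.marker_cycles.items()):
        rows.append(("P1NP", w, c, scales.s_P1NP * traj.p1np[c - 1]))
        rows.append(("NTX", w, c, scales.s_NTX * traj.ntx[c - 1]))
    for w, c in sorted(mapping.bmd_cycles.items()):
        rows.append(("BMD", w, c, scales.s_BMD * traj.bmd[c]))
    frame = pd.DataFrame(rows, columns=["outcome", "week", "cycle", "predicted_value"])
    frame = frame.sort_values(["outcome", "week"], ignore_index=True)
    dropped = tuple(mapping.unmappable) + tuple(mapping.excluded)
    return PredictedObservations(frame, dropped)
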