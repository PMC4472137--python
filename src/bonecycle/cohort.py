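"""Synthetic cohorts with the statistical structure the fitter assumes.

The generator emulates a once-weekly-teriparatide trial arm: every
subject follows the same two-compartment mean trajectory sampled on the
trial visit schedule (markers at weeks 0, 1, 4, 12, 24, 48, 72; lumbar
BMD at weeks 0, 24, 48, 72), scaled into measurement units, with
multiplicative log-normal noise at the assay coefficients of variation
and a subject-level shared error component giving within-subject
correlation.  It writes the same long-format table the fitter reads, so
parameter-recovery experiments need no external data.

Marker values at weeks 0 and 1 cannot be produced by a 4-week-cycle
model under treatment rates; when requested they are generated from
synthetic pre-treatment turnover levels (the on-treatment peak divided
by a configurable percent change) purely so percent-change summaries
have a realistic shape.  They are excluded from fitting by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PlenaryParams, WEEKLY_TERIPARATIDE_FIT, simulate_plenary
from .gridfit import CohortDataset
from .observation import OUTCOMES, OutcomeScales, VisitSchedule, weeks_to_cycles

__all__ = ["DEFAULT_UNITS", "CohortConfig", "generate_cohort", "summarize_cohort"]

DEFAULT_UNITS = {"P1NP": "ug/L", "NTX": "nmolBCE/mmolCr", "BMD": "g/cm^2"}


def _default_assay_cv() -> dict:
    # Assay CVs: P1NP and NTX at the midpoints of the reported
    # inter-assay ranges (2.7-5.0% and 6.9-11.1%); BMD at typical
    # lumbar DXA precision (not assay-derived).
    return {"P1NP": 0.0385, "NTX": 0.090, "BMD": 0.015}


def _default_bio_cv() -> dict:
    return {"P1NP": 0.0, "NTX": 0.0, "BMD": 0.0}


def _default_rho() -> dict:
    # Modest subject-level shared error component.
    return {"P1NP": 0.2, "NTX": 0.2, "BMD": 0.2}


def _default_baseline_change() -> dict:
    # Percent change from baseline to the on-treatment marker peak used
    # to back out synthetic pre-treatment levels: formation markers
    # rise ~20%, resorption markers fall ~20%.
    return {"P1NP": 20.0, "NTX": -20.0}


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, seed included.

    ``assay_cv`` and ``biological_cv`` combine on the log scale
    (independent multiplicative components); ``rho`` is the
    within-subject correlation of the combined log error.  With
    ``include_unfitted_marker_weeks`` the week-0/week-1 marker visits of
    the real schedule are emitted too (from synthetic pre-treatment
    levels); they are not fittable and exist only for summaries.
    """

    n_subjects: int
    true_params: PlenaryParams = WEEKLY_TERIPARATIDE_FIT
    true_scales: OutcomeScales = field(
        default_factory=lambda: OutcomeScales(s_P1NP=250.0, s_NTX=220.0, s_BMD=0.88)
    )
    schedule: VisitSchedule = field(default_factory=VisitSchedule)
    assay_cv: dict = field(default_factory=_default_assay_cv)
    biological_cv: dict = field(default_factory=_default_bio_cv)
    rho: dict = field(default_factory=_default_rho)
    missing_rate: float = 0.0
    include_unfitted_marker_weeks: bool = False
    baseline_change_pct: dict = field(default_factory=_default_baseline_change)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects >= 1):
            raise ValueError(f"n_subjects={self.n_subjects!r} must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate={self.missing_rate!r} must be in [0, 1)")
        for name, table in (("assay_cv", self.assay_cv), ("biological_cv", self.biological_cv)):
            for o, cv in table.items():
                if cv < 0 or not math.isfinite(cv):
                    raise ValueError(f"{name}[{o!r}]={cv!r} must be >= 0")
        for o, r in self.rho.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"rho[{o!r}]={r!r} must be in [0, 1)")

    def log_sd(self, outcome: str) -> float:
        """Combined log-scale standard deviation for one outcome."""
        var = 0.0
        for table in (self.assay_cv, self.biological_cv):
            cv = table.get(outcome, 0.0)
            var += math.log1p(cv * cv)
        return math.sqrt(var)


def _mean_schedule(config: CohortConfig, outcome: str):
    """(weeks, mean values in measurement units) for one outcome."""
    mapping = weeks_to_cycles(config.schedule)
    n_cycles = max(1, mapping.max_cycle)
    traj = simulate_plenary(config.true_params, n_cycles)
    s = config.true_scales.for_outcome(outcome)
    if outcome == "BMD":
        weeks = sorted(mapping.bmd_cycles)
        means = [s * traj.bmd[mapping.bmd_cycles[w]] for w in weeks]
        return np.array(weeks, float), np.array(means)
    weeks = sorted(mapping.marker_cycles)
    means = [s * traj.marker(outcome, mapping.marker_cycles[w]) for w in weeks]
    if config.include_unfitted_marker_weeks:
        pct = config.baseline_change_pct.get(outcome, 0.0)
        baseline = s * traj.marker(outcome, 1) / (1.0 + pct / 100.0)
        pre_weeks = [w for (_, w) in mapping.unmappable] + [w for (_, w, _) in mapping.excluded]
        pre_weeks = sorted(set(pre_weeks))
        weeks = pre_weeks + weeks
        means = [baseline] * len(pre_weeks) + means
    return np.array(weeks, float), np.array(means)


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw one cohort; the seed fully determines the output.

    Log errors for outcome o are σ_o (√ρ_o g_i + √(1−ρ_o) h_{iw}) with
    independent standard normals g (per subject) and h (per visit),
    shifted by −σ_o²/2 so each observation's expectation equals the
    scaled model prediction.  Missingness is completely at random.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(1, n + 1)]
    rows = []
    for outcome in OUTCOMES:
        weeks, means = _mean_schedule(config, outcome)
        m = len(weeks)
        sd = config.log_sd(outcome)
        rho = config.rho.get(outcome, 0.0)
        g = rng.standard_normal(n)
        h = rng.standard_normal((n, m))
        eps = sd * (math.sqrt(rho) * g[:, None] + math.sqrt(1.0 - rho) * h)
        values = means[None, :] * np.exp(eps - 0.5 * sd * sd)
        keep = rng.random((n, m)) >= config.missing_rate
        unit = DEFAULT_UNITS.get(outcome, "")
        for i, subj in enumerate(subjects):
            for j, w in enumerate(weeks):
                if keep[i, j]:
                    rows.append((subj, outcome, w, values[i, j], unit))
    frame = pd.DataFrame(rows, columns=["subject_id", "outcome", "week", "value", "unit"])
    frame = frame.sort_values(["subject_id", "outcome", "week"], ignore_index=True)
    return CohortDataset(frame)


def summarize_cohort(data: CohortDataset) -> pd.DataFrame:
    """Per-outcome, per-week mean, percent change from baseline and 95% CI.

    The baseline for each outcome is its earliest observed week (week 0
    when present); percent change is computed per subject and the CI is
    mean ± 1.96 SE across subjects on the percent-change scale.  Cells
    with no observations are reported as missing, and CIs require at
    least two subjects.
    """
    out = []
    for outcome in OUTCOMES:
        sub = data.data[data.data["outcome"] == outcome]
        if sub.empty:
            continue
        wide = sub.pivot(index="subject_id", columns="week", values="value")
        base_week = wide.columns.min()
        base = wide[base_week]
        pct = 100.0 * (wide.div(base, axis=0) - 1.0)
        for w in wide.columns:
            vals = wide[w]
            pc = pct[w].dropna()
            n_obs = int(vals.notna().sum())
            mean_pc = float(pc.mean()) if len(pc) else np.nan
            if len(pc) >= 2:
                se = float(pc.std(ddof=1)) / math.sqrt(len(pc))
                lo, hi = mean_pc - 1.96 * se, mean_pc + 1.96 * se
            else:
                lo = hi = np.nan
            out.append(
                (
                    outcome,
                    float(w),
                    n_obs,
                    float(vals.mean()) if n_obs else np.nan,
                    mean_pc,
                    lo,
                    hi,
                )
            )
    return pd.DataFrame(
        out,
        columns=["outcome", "week", "n", "mean_value", "pct_change_mean", "ci_low", "ci_high"],
    )
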