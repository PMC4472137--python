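"""Delimited-text and configuration round-tripping.

One tabular dialect everywhere: comma-separated UTF-8 with a header
row.  Run configurations are YAML mappings; every CLI run echoes its
resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .gridfit import PARAM_NAMES, CohortDataset, FitResult, profile_table

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_trajectory",
    "write_fit_result",
    "load_config",
    "dump_config",
]


def read_cohort(path) -> CohortDataset:
    """Read a long-format cohort CSV, validating as it loads."""
    return CohortDataset.from_csv(path)


def write_cohort(data: CohortDataset, path) -> None:
    data.to_csv(path)


def write_trajectory(traj, path, cycle_length_weeks: float = 4.0) -> None:
    """Write any trajectory's tidy (cycle, week, quantity, value) table."""
    traj.to_frame(cycle_length_weeks=cycle_length_weeks).to_csv(path, index=False)


def write_fit_result(result: FitResult, out_dir) -> dict:
    """Write surface, best fit, ties and per-parameter profiles.

    Returns a mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    surface_path = out_dir / "surface.csv"
    result.surface.to_csv(surface_path, index=False)
    paths["surface"] = surface_path
    best = {
        "params": {name: getattr(result.best, name) for name in PARAM_NAMES},
        "neg2loglik": result.neg2loglik,
        "scales": {
            "s_P1NP": result.scales.s_P1NP,
            "s_NTX": result.scales.s_NTX,
            "s_BMD": result.scales.s_BMD,
        },
        "n_evaluated": result.n_evaluated,
        "n_ties": len(result.ties),
    }
    best_path = out_dir / "best_fit.json"
    best_path.write_text(json.dumps(best, indent=2))
    paths["best_fit"] = best_path
    ties_path = out_dir / "ties.csv"
    result.ties.to_csv(ties_path, index=False)
    paths["ties"] = ties_path
    for name in PARAM_NAMES:
        p = out_dir / f"profile_{name}.csv"
        profile_table(result, name).to_csv(p, index=False)
        paths[f"profile_{name}"] = p
    return paths


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def dump_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
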