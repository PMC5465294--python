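"""CSV and JSON import/export for simulation and gait-analysis results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .gait import DutyFactorTable, GaitDiagram, GaitLabel
from .legs import LEGS, Rank
from .simulate import TrialSeries

__all__ = [
    "series_to_frame",
    "write_series_csv",
    "read_force_csv",
    "diagram_to_frame",
    "gait_report",
    "write_json",
]

FORCE_COLUMNS = [f"N_{leg.label}" for leg in LEGS]


def series_to_frame(series: TrialSeries) -> pd.DataFrame:
    """Time series as a tidy frame: t, phi_*, f_*, N_*, omega, fall."""
    data = {"t": series.t}
    for i, leg in enumerate(LEGS):
        data[f"phi_{leg.label}"] = series.phases[:, i]
    for i, leg in enumerate(LEGS):
        data[f"f_{leg.label}"] = series.feedback[:, i]
    for i, leg in enumerate(LEGS):
        data[FORCE_COLUMNS[i]] = series.forces[:, i]
    if series.horizontal is not None:
        for i, leg in enumerate(LEGS):
            data[f"NH_{leg.label}"] = series.horizontal[:, i]
    data["omega"] = series.omega
    data["fall"] = series.fall.astype(int)
    return pd.DataFrame(data)


def write_series_csv(series: TrialSeries, path: Union[str, Path]) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_force_csv(path: Union[str, Path]):
    """Read a standalone per-leg force CSV (columns t, N_L1 ... N_R3).

    Returns ``(forces, sample_dt, t0)`` for :func:`tegotae.gait.detect_stance`.
    """
    df = pd.read_csv(path)
    missing = [c for c in ["t", *FORCE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"force CSV is missing columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("force CSV needs at least two samples")
    dt = float(np.median(np.diff(t)))
    forces = df[FORCE_COLUMNS].to_numpy(dtype=float)
    return forces, dt, float(t[0])


def diagram_to_frame(diagram: GaitDiagram) -> pd.DataFrame:
    data = {"t": diagram.times}
    for i, leg in enumerate(LEGS):
        data[f"stance_{leg.label}"] = diagram.stance[:, i]
    return pd.DataFrame(data)


def gait_report(label: GaitLabel, duty: DutyFactorTable) -> Dict:
    """JSON-serializable record of a gait classification and duty factors."""
    return {
        "label": label.label,
        "sub_label": label.sub_label,
        "mean_duty": None if np.isnan(label.mean_duty) else round(label.mean_duty, 4),
        "touchdown_order": list(label.touchdown_order),
        "note": label.note,
        "duty_per_leg": {
            leg.label: (None if np.isnan(duty.per_leg[leg.index])
                        else round(float(duty.per_leg[leg.index]), 4))
            for leg in LEGS
        },
        "duty_per_rank": {
            rank.name.lower(): (None if np.isnan(duty.per_rank[rank])
                                else round(float(duty.per_rank[rank]), 4))
            for rank in Rank
        },
    }


def write_json(obj, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
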