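"""Conventional per-trial trajectory measures and per-option summaries.

Motion time (MT) is the duration from leaving the start location to
entering the response area, i.e. the duration of the trimmed trajectory.
Max-d is the largest perpendicular deviation of the path from the straight
line between its endpoints, signed positive when the deviating point lies
toward the non-chosen option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTrajectoryError, EmptyInputError, PreconditionError
from .trajectories import Trajectory

__all__ = ["TrajectoryMeasures", "MeasureSummary", "motion_time", "max_deviation", "summarize", "measure"]


@dataclass
class TrajectoryMeasures:
    trial_id: str
    choice: int
    motion_time: float
    max_d: float


@dataclass
class MeasureSummary:
    """Per-option trial counts, mean measures and choice percentages."""

    group_label: str
    table: pd.DataFrame  # columns: option, N, motion_time, max_d, percent

    def to_csv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False, na_rep="—")


def motion_time(traj: Trajectory) -> float:
    """Duration of the trimmed trajectory (last time minus first time)."""
    if traj.n_samples < 2:
        raise PreconditionError("motion time requires a trimmed trajectory with >= 2 samples")
    dur = traj.duration
    if dur <= 0:
        raise PreconditionError("motion time requires positive duration")
    return dur


def max_deviation(traj: Trajectory, reference: str = "chord") -> float:
    """Signed maximum perpendicular deviation from the ideal straight path.

    ``reference="chord"`` (default) measures from the line through the
    trajectory's own first and last samples; ``reference="diagonal"`` uses
    the idealized (0,0) -> (choice, 1) diagonal instead.  Positive values
    indicate deflection toward the non-chosen option.
    """
    if reference == "chord":
        sxy = np.array([traj.xs[0], traj.ys[0]])
        exy = np.array([traj.xs[-1], traj.ys[-1]])
    elif reference == "diagonal":
        sxy = np.array([0.0, 0.0])
        exy = np.array([float(traj.choice), 1.0])
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d = exy - sxy
    norm = float(np.hypot(*d))
    if norm == 0:
        raise DegenerateTrajectoryError("coincident endpoints; deviation undefined")
    # z-component of the 2D cross product: positive when the sample lies to
    # the left of the start->end direction
    cross = d[0] * (traj.ys - sxy[1]) - d[1] * (traj.xs - sxy[0])
    signed = traj.choice * cross / norm
    return float(signed[np.argmax(np.abs(signed))])


def measure(traj: Trajectory, reference: str = "chord") -> TrajectoryMeasures:
    return TrajectoryMeasures(
        trial_id=traj.trial_id,
        choice=traj.choice,
        motion_time=motion_time(traj),
        max_d=max_deviation(traj, reference=reference),
    )


def summarize(measures: list[TrajectoryMeasures], group_label: str = "") -> MeasureSummary:
    """Per-option counts, mean motion time / max-d, and choice percentages.

    Options never chosen are reported with N = 0 and undefined (NaN) means.
    """
    if not measures:
        raise EmptyInputError("no measures to summarize")
    rows = []
    total = len(measures)
    for option in (1, -1):
        sel = [m for m in measures if m.choice == option]
        n = len(sel)
        rows.append(
            {
                "option": option,
                "N": n,
                "motion_time": float(np.mean([m.motion_time for m in sel])) if n else np.nan,
                "max_d": float(np.mean([m.max_d for m in sel])) if n else np.nan,
                "percent": 100.0 * n / total,
            }
        )
    return MeasureSummary(group_label=group_label, table=pd.DataFrame(rows))
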