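"""Reading and preprocessing of two-choice cursor trajectories.

Raw logs are long-format delimited text, one row per cursor sample, with
columns ``participant``, ``trial``, ``t``, ``x``, ``y`` and optionally
``outcome``.  Preprocessing follows the standard mouse-tracking chain:

1. spatial rescaling so the start maps to (0, 0) and the two response
   targets to (-1, 1) / (1, 1);
2. trimming of the static head (movement-initiation dwell) and static tail
   (post-response dwell), with the time origin reset to the first retained
   sample;
3. resampling to a fixed number of points (default 101) on a uniform time
   grid preserving total duration;
4. velocity estimation by Savitzky-Golay filtering (default) or central
   finite differences;
5. optional mirroring so a designated reference option sits at x = +1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

from .errors import (
    AlignmentError,
    DegenerateTrajectoryError,
    EmptyInputError,
    FormatError,
    GeometryError,
    ParameterError,
    PreconditionError,
)

__all__ = [
    "RawTrajectory",
    "ScreenGeometry",
    "Trajectory",
    "VelocityProfile",
    "read_trajectories",
    "write_trajectories",
    "rescale",
    "trim",
    "resample",
    "estimate_velocity",
    "mirror_to_canonical",
    "preprocess",
]

REQUIRED_COLUMNS = ("participant", "trial", "t", "x", "y")
DEFAULT_N_POINTS = 101
DEFAULT_TRIM_EPSILON = 0.01


@dataclass
class RawTrajectory:
    """One trial's cursor samples in device (pixel) coordinates."""

    participant_id: str
    trial_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    outcome_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = len(self.times)
        if not (len(self.xs) == len(self.ys) == n) or n < 2:
            raise ParameterError("times, xs, ys must have equal length >= 2")
        if not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")


@dataclass
class ScreenGeometry:
    """Start and target locations of the experiment layout, in device coordinates.

    ``y_up`` is True when the device vertical axis increases upward; screen
    pixel coordinates usually grow downward (y_up=False), in which case the
    vertical axis is flipped during rescaling.
    """

    start: tuple[float, float]
    left_target: tuple[float, float]
    right_target: tuple[float, float]
    y_up: bool = False

    def __post_init__(self) -> None:
        if self.left_target[0] == self.right_target[0]:
            raise GeometryError("left and right targets must differ in horizontal coordinate")
        for name, tgt in (("left", self.left_target), ("right", self.right_target)):
            if tgt[1] == self.start[1]:
                raise GeometryError(f"{name} target must differ from start in vertical coordinate")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ScreenGeometry":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            start=tuple(cfg["start"]),
            left_target=tuple(cfg["left_target"]),
            right_target=tuple(cfg["right_target"]),
            y_up=bool(cfg.get("y_up", False)),
        )


@dataclass
class Trajectory:
    """A spatially normalized trial path; after full preprocessing the start
    is near (0, 0), the endpoint near (choice, 1), and times are uniform."""

    participant_id: str
    trial_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    choice: int
    outcome_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if not (len(self.xs) == len(self.ys) == len(self.times)):
            raise ParameterError("times, xs, ys must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dts = np.diff(self.times)
        return bool(len(dts) == 0 or np.allclose(dts, dts[0], rtol=rtol, atol=1e-12))


@dataclass
class VelocityProfile:
    """Per-sample cursor velocities (normalized units / second)."""

    vxs: np.ndarray
    vys: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.vxs = np.asarray(self.vxs, dtype=float)
        self.vys = np.asarray(self.vys, dtype=float)
        if len(self.vxs) != len(self.vys):
            raise AlignmentError("vxs and vys must have equal length")

    def __len__(self) -> int:
        return len(self.vxs)


# ---------------------------------------------------------------------------
# I/O


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data in {path}") from None
    return df


def read_trajectories(path: str | os.PathLike) -> list[RawTrajectory]:
    """Read a long-format delimited log into one :class:`RawTrajectory` per trial.

    CSV/TSV is auto-detected from the extension.  Rows with non-finite
    coordinates or timestamps are dropped; samples are ordered by time
    within each (participant, trial) group.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"no rows in {path}")
    finite = np.isfinite(df["t"]) & np.isfinite(df["x"]) & np.isfinite(df["y"])
    df = df[finite]
    out = []
    for (pid, tid), g in df.groupby(["participant", "trial"], sort=True):
        g = g.sort_values("t", kind="stable")
        label = None
        if "outcome" in g.columns and g["outcome"].notna().any():
            label = str(g["outcome"].dropna().iloc[0])
        out.append(
            RawTrajectory(
                participant_id=str(pid),
                trial_id=str(tid),
                times=g["t"].to_numpy(),
                xs=g["x"].to_numpy(),
                ys=g["y"].to_numpy(),
                outcome_label=label,
            )
        )
    if not out:
        raise EmptyInputError(f"no finite samples in {path}")
    return out


def write_trajectories(
    path: str | os.PathLike,
    trajs: list[Trajectory],
    vels: list[VelocityProfile] | None = None,
) -> None:
    """Write preprocessed trajectories back out in the reader schema, with
    ``vx``/``vy`` columns when velocity profiles are supplied."""
    if vels is not None and len(vels) != len(trajs):
        raise AlignmentError("one velocity profile per trajectory required")
    frames = []
    for k, tr in enumerate(trajs):
        d = {
            "participant": tr.participant_id,
            "trial": tr.trial_id,
            "t": tr.times,
            "x": tr.xs,
            "y": tr.ys,
            "outcome": tr.outcome_label if tr.outcome_label is not None else tr.choice,
        }
        if vels is not None:
            if len(vels[k]) != tr.n_samples:
                raise AlignmentError(f"velocity profile {k} misaligned with its trajectory")
            d["vx"] = vels[k].vxs
            d["vy"] = vels[k].vys
        frames.append(pd.DataFrame(d))
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Preprocessing steps


def _sign_choice(final_x: float) -> int:
    if final_x == 0:
        raise DegenerateTrajectoryError("final x is exactly 0; choice is undefined")
    return 1 if final_x > 0 else -1


def rescale(raw: RawTrajectory, geom: ScreenGeometry) -> Trajectory:
    """Affine-map device coordinates so the start is (0, 0) and the targets (+-1, 1).

    Horizontal: (x - start_x) / half-distance between targets along x.
    Vertical: (y - start_y) / (target_row_y - start_y); when the device axis
    points down (y_up=False) this denominator is negative, flipping the axis.
    """
    sx, sy = geom.start
    h_span = geom.right_target[0] - sx
    target_row_y = (geom.left_target[1] + geom.right_target[1]) / 2.0
    v_span = target_row_y - sy
    if h_span == 0 or v_span == 0:
        raise GeometryError("degenerate geometry: zero horizontal or vertical span")
    xs = (raw.xs - sx) / h_span
    ys = (raw.ys - sy) / v_span
    return Trajectory(
        participant_id=raw.participant_id,
        trial_id=raw.trial_id,
        times=raw.times.copy(),
        xs=xs,
        ys=ys,
        choice=_sign_choice(xs[-1]),
        outcome_label=raw.outcome_label,
    )


def trim(traj: Trajectory, epsilon: float = DEFAULT_TRIM_EPSILON) -> Trajectory:
    """Drop the static head and tail of a trajectory.

    Leading samples closer than ``epsilon`` to the first sample are removed
    except the last of them (so motion starts at the retained origin);
    trailing samples closer than ``epsilon`` to the final sample are removed
    except the first of them.  Times are shifted so the first retained
    sample is at t = 0.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    xs, ys, ts = traj.xs, traj.ys, traj.times
    n = len(xs)
    path_len = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
    if path_len < epsilon:
        raise DegenerateTrajectoryError(
            f"trajectory {traj.trial_id}: total path length {path_len:.4g} < epsilon"
        )
    d_head = np.hypot(xs - xs[0], ys - ys[0])
    i0 = 0
    while i0 + 1 < n and d_head[i0 + 1] < epsilon:
        i0 += 1
    d_tail = np.hypot(xs - xs[-1], ys - ys[-1])
    i1 = n - 1
    while i1 - 1 > i0 and d_tail[i1 - 1] < epsilon:
        i1 -= 1
    if i1 - i0 < 1:
        raise DegenerateTrajectoryError(f"trajectory {traj.trial_id}: nothing left after trim")
    return replace(
        traj,
        times=ts[i0 : i1 + 1] - ts[i0],
        xs=xs[i0 : i1 + 1].copy(),
        ys=ys[i0 : i1 + 1].copy(),
    )


def resample(traj: Trajectory, n_points: int = DEFAULT_N_POINTS) -> Trajectory:
    """Linearly interpolate onto a uniform time grid of exactly ``n_points``
    samples spanning the input's duration; endpoints are preserved."""
    if int(n_points) != n_points or n_points < 2:
        raise ParameterError(f"n_points must be an integer >= 2, got {n_points!r}")
    if traj.duration <= 0:
        raise DegenerateTrajectoryError("trajectory duration must be positive")
    grid = np.linspace(traj.times[0], traj.times[-1], int(n_points))
    xs = np.interp(grid, traj.times, traj.xs)
    ys = np.interp(grid, traj.times, traj.ys)
    # guard endpoint identity against interpolation round-off
    xs[0], ys[0] = traj.xs[0], traj.ys[0]
    xs[-1], ys[-1] = traj.xs[-1], traj.ys[-1]
    return replace(traj, times=grid, xs=xs, ys=ys)


def estimate_velocity(
    traj: Trajectory,
    method: str = "savgol",
    window: int = 7,
    polyorder: int = 2,
) -> VelocityProfile:
    """Estimate per-sample velocities on a uniform time grid.

    ``method="savgol"`` uses a Savitzky-Golay derivative filter (default
    window 7, polynomial order 2); ``method="finite_difference"`` uses
    central differences with one-sided endpoints.  Requires a uniformly
    resampled trajectory.
    """
    if traj.n_samples < 2:
        raise DegenerateTrajectoryError("need at least 2 samples to estimate velocity")
    if not traj.is_uniform():
        raise PreconditionError("velocity estimation requires a uniform time grid; resample first")
    dt = float(traj.times[1] - traj.times[0])
    if method == "finite_difference":
        vx = np.gradient(traj.xs, dt)
        vy = np.gradient(traj.ys, dt)
        tag = "finite_difference"
    elif method == "savgol":
        if window % 2 == 0 or window <= polyorder:
            raise ParameterError("savgol window must be odd and > polyorder")
        w = min(window, traj.n_samples if traj.n_samples % 2 == 1 else traj.n_samples - 1)
        if w <= polyorder:
            raise ParameterError("trajectory too short for the requested polyorder")
        vx = savgol_filter(traj.xs, w, polyorder, deriv=1, delta=dt, mode="interp")
        vy = savgol_filter(traj.ys, w, polyorder, deriv=1, delta=dt, mode="interp")
        tag = f"savgol(window={w},polyorder={polyorder})"
    else:
        raise ParameterError(f"unknown velocity method {method!r}")
    return VelocityProfile(vxs=vx, vys=vy, method_tag=tag)


def mirror_to_canonical(traj: Trajectory, reference_side: int) -> Trajectory:
    """Map the designated reference option to x = +1.

    ``reference_side`` is the side (-1 left, +1 right) on which the
    reference option (e.g. the high-reward option) currently sits.  When it
    is on the left, x is negated and the choice flipped; otherwise the
    trajectory is returned unchanged.
    """
    if reference_side not in (-1, 1):
        raise ParameterError("reference_side must be -1 or +1")
    if reference_side == 1:
        return traj
    return replace(traj, xs=-traj.xs, choice=-traj.choice)


def preprocess(
    raw: RawTrajectory,
    geom: ScreenGeometry,
    epsilon: float = DEFAULT_TRIM_EPSILON,
    n_points: int = DEFAULT_N_POINTS,
    velocity_method: str = "savgol",
    window: int = 7,
    polyorder: int = 2,
    reference_side: int = 1,
) -> tuple[Trajectory, VelocityProfile]:
    """Full chain: rescale, trim, resample, mirror, estimate velocity."""
    traj = rescale(raw, geom)
    traj = trim(traj, epsilon=epsilon)
    traj = resample(traj, n_points=n_points)
    traj = mirror_to_canonical(traj, reference_side)
    vel = estimate_velocity(traj, method=velocity_method, window=window, polyorder=polyorder)
    return traj, vel
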