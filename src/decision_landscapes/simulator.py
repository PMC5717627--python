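"""Forward simulation of the gradient system — the package's synthetic-data
generator and parameter-recovery test harness.

The deterministic model  tau * (dx/dt, dy/dt) = -grad V  is integrated with
a fixed-step classical Runge-Kutta (RK4) scheme.  An optional additive
velocity perturbation (fresh Gaussian draw each step) mimics motor noise;
the underlying model itself is deterministic.  Integration stops as soon as
the state enters ``stop_radius`` of either response target (-1, 1) or
(1, 1), or when ``t_max`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationError
from .landscape import LandscapeParams, gradient
from .trajectories import Trajectory

__all__ = ["SimulationConfig", "simulate_trajectory", "generate_dataset"]

TARGETS = ((-1.0, 1.0), (1.0, 1.0))

# The cubic vertical baseline makes V unbounded below past the arena edge, so
# escaped states blow up in finite time; detect escape before floats overflow.
ESCAPE_RADIUS = 3.0


@dataclass
class SimulationConfig:
    """Integration settings.

    Defaults (dt = 1 ms, stop radius 0.05, start offsets of scale 0.02)
    produce baseline arrival times of order 0.1-1 s at tau around 0.05,
    the scale of motion times seen in real cursor data.
    """

    dt: float = 0.001
    t_max: float = 5.0
    stop_radius: float = 0.05
    start_offset_scale: float = 0.02
    velocity_noise_scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= self.dt or self.stop_radius <= 0:
            raise ValueError("require dt > 0, t_max > dt, stop_radius > 0")


def _rk4_step(params: LandscapeParams, x: float, y: float, dt: float) -> tuple[float, float]:
    def f(px, py):
        gx, gy = gradient(params, px, py)
        return -gx / params.tau, -gy / params.tau

    k1 = f(x, y)
    k2 = f(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1])
    k3 = f(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1])
    k4 = f(x + dt * k3[0], y + dt * k3[1])
    nx = x + dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
    ny = y + dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
    return nx, ny


def simulate_trajectory(
    params: LandscapeParams,
    x0: float,
    y0: float,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "sim",
    participant_id: str = "sim",
) -> Trajectory:
    """Integrate one path from (x0, y0) until target arrival or t_max.

    With zero noise the output is fully determined by (params, x0, y0,
    config).  Noise, when enabled, is drawn from ``rng`` (or a generator
    seeded from ``config.seed``).
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x, y = float(x0), float(y0)
    xs, ys, ts = [x], [y], [0.0]
    n_steps = int(round(config.t_max / config.dt))
    arrived = False
    for step in range(1, n_steps + 1):
        x, y = _rk4_step(params, x, y, config.dt)
        if config.velocity_noise_scale > 0:
            x += config.velocity_noise_scale * config.dt * rng.standard_normal()
            y += config.velocity_noise_scale * config.dt * rng.standard_normal()
        if not (np.isfinite(x) and np.isfinite(y)) or np.hypot(x, y) > ESCAPE_RADIUS:
            raise SimulationError(
                f"trajectory diverged out of the arena at step {step} (t={step * config.dt:.4g} s)"
            )
        xs.append(x)
        ys.append(y)
        ts.append(step * config.dt)
        if any(np.hypot(x - tx, y - ty) <= config.stop_radius for tx, ty in TARGETS):
            arrived = True
            break
    if not arrived:
        moved = np.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
        if moved < config.stop_radius:
            raise SimulationError(
                f"trajectory stalled: no motion after t_max={config.t_max} s "
                "(start may be a critical point with zero noise)"
            )
    choice = 1 if x > 0 else -1
    if x == 0:
        raise SimulationError("final x is exactly 0; choice attribution undefined")
    return Trajectory(
        participant_id=participant_id,
        trial_id=trial_id,
        times=np.array(ts),
        xs=np.array(xs),
        ys=np.array(ys),
        choice=choice,
    )


def generate_dataset(
    params: LandscapeParams,
    n_trials: int,
    config: SimulationConfig | None = None,
    symmetric_starts: bool = False,
) -> list[Trajectory]:
    """Simulate ``n_trials`` independent trajectories with seeded random
    start offsets of scale ``start_offset_scale`` around (0, 0).

    With ``symmetric_starts`` the offsets come in mirrored pairs
    (x negated), removing start-position asymmetry from the sample.
    Reproducible for a fixed ``config.seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    offsets = []
    if symmetric_starts:
        for _ in range((n_trials + 1) // 2):
            ox, oy = rng.normal(scale=config.start_offset_scale, size=2)
            offsets.append((ox, abs(oy)))
            offsets.append((-ox, abs(oy)))
        offsets = offsets[:n_trials]
    else:
        for _ in range(n_trials):
            ox, oy = rng.normal(scale=config.start_offset_scale, size=2)
            offsets.append((ox, abs(oy)))
    trajs = []
    n_stalled = 0
    for k, (ox, oy) in enumerate(offsets):
        try:
            trajs.append(
                simulate_trajectory(
                    params, ox, oy, config, rng=rng, trial_id=str(k), participant_id="sim"
                )
            )
        except SimulationError:
            n_stalled += 1
    if not trajs:
        raise SimulationError(f"all {n_stalled} trials stalled; check parameters and starts")
    return trajs
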