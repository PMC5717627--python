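"""Velocity-matching estimation of landscape parameters.

The fitting error for one trajectory is the mean squared difference between
the model velocity field evaluated at the observed positions and the
numerically estimated data velocities,

    H = (1/m) * sum_i (vx_model(x_i, y_i) - vx_data(t_i))^2
                    + (vy_model(x_i, y_i) - vy_data(t_i))^2,

and for a set of N trajectories the objective is the plain average of the
per-trajectory errors.  Because the model velocities are closed-form
polynomials in the positions, no differential equation is solved inside the
loss, and the Jacobian with respect to (tau, c_ij) is analytic.

Optimization runs over (log tau, c_ij) — the log keeps tau positive while
leaving the problem smooth and unconstrained for quasi-Newton methods — and
starts from the baseline landscape (tau = 0.05, all c_ij = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import AlignmentError, EmptyInputError
from .landscape import LandscapeParams, coeff_index_pairs, param_vector_names
from .trajectories import Trajectory, VelocityProfile

__all__ = ["FitResult", "velocity_error", "multi_error", "error_jacobian", "fit"]

DEFAULT_TAU0 = 0.05
LOG_TAU_BOUNDS = (-8.0, 4.0)


@dataclass
class FitResult:
    """Fitted parameters plus diagnostics of the optimization run."""

    params: LandscapeParams
    error: float
    per_trajectory_errors: list[float]
    converged: bool
    n_evaluations: int
    initial_error: float
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "error": self.error,
            "per_trajectory_errors": list(self.per_trajectory_errors),
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "initial_error": self.initial_error,
            "message": self.message,
        }


def _check_aligned(trajs: list[Trajectory], vels: list[VelocityProfile]) -> None:
    if len(trajs) != len(vels):
        raise AlignmentError(f"{len(trajs)} trajectories but {len(vels)} velocity profiles")
    for k, (tr, v) in enumerate(zip(trajs, vels)):
        if tr.n_samples != len(v):
            raise AlignmentError(f"trajectory {k}: {tr.n_samples} samples vs {len(v)} velocities")


def _coupling_basis(alpha: int, xs: np.ndarray, ys: np.ndarray):
    """Per-pair contributions (bx, by) to the potential gradient, so that
    grad V = baseline + sum_p c_p * (bx_p, by_p)."""
    pairs = coeff_index_pairs(alpha)
    bx = np.empty((len(pairs), len(xs)))
    by = np.empty((len(pairs), len(xs)))
    for p, (i, j) in enumerate(pairs):
        s = 1.0 / (i + j - 1)
        bx[p] = s * i * xs ** (i - 1) * ys**j
        by[p] = s * j * xs**i * ys ** (j - 1)
    return bx, by


def _residuals(params: LandscapeParams, traj: Trajectory, vel: VelocityProfile):
    xs, ys = traj.xs, traj.ys
    gx = xs**3 - xs
    gy = ys**2 - ys
    bx, by = _coupling_basis(params.alpha, xs, ys)
    c = np.array([params.coeffs[p] for p in coeff_index_pairs(params.alpha)])
    if c.size:
        gx = gx + c @ bx
        gy = gy + c @ by
    rx = -gx / params.tau - vel.vxs
    ry = -gy / params.tau - vel.vys
    return rx, ry, gx, gy, bx, by


def velocity_error(params: LandscapeParams, traj: Trajectory, vel: VelocityProfile) -> float:
    """Mean squared velocity mismatch for one trajectory (H)."""
    if traj.n_samples != len(vel):
        raise AlignmentError("trajectory and velocity profile have different lengths")
    rx, ry, *_ = _residuals(params, traj, vel)
    return float(np.mean(rx**2 + ry**2))


def multi_error(
    params: LandscapeParams, trajs: list[Trajectory], vels: list[VelocityProfile]
) -> float:
    """Average of velocity_error over N trajectories (H-hat)."""
    if not trajs:
        raise EmptyInputError("no trajectories to evaluate")
    _check_aligned(trajs, vels)
    return float(np.mean([velocity_error(params, t, v) for t, v in zip(trajs, vels)]))


def error_jacobian(
    params: LandscapeParams, trajs: list[Trajectory], vels: list[VelocityProfile]
) -> np.ndarray:
    """Analytic partials of multi_error with respect to (tau, c_ij),
    ordered as :func:`param_vector_names`."""
    if not trajs:
        raise EmptyInputError("no trajectories to evaluate")
    _check_aligned(trajs, vels)
    tau = params.tau
    n_pairs = len(coeff_index_pairs(params.alpha))
    grad = np.zeros(1 + n_pairs)
    for traj, vel in zip(trajs, vels):
        rx, ry, gx, gy, bx, by = _residuals(params, traj, vel)
        m = traj.n_samples
        # d(vx_model)/d tau = gx / tau^2
        grad[0] += (2.0 / m) * np.sum(rx * gx + ry * gy) / tau**2
        if n_pairs:
            grad[1:] += (2.0 / m) * (bx @ rx + by @ ry) * (-1.0 / tau)
    return grad / len(trajs)


def fit(
    trajs: list[Trajectory],
    vels: list[VelocityProfile],
    alpha: int = 3,
    tau0: float = DEFAULT_TAU0,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit (tau, c_ij) to a set of trajectories by quasi-Newton descent.

    Starts at the baseline landscape (tau = tau0, all c_ij = 0); tau is
    optimized on a log scale, capped at log tau in [-8, 4] to keep
    degenerate fits (near-zero data velocities pushing tau to infinity)
    finite.  Non-convergence is reported via ``converged=False``, never an
    exception.
    """
    if not trajs:
        raise EmptyInputError("no trajectories to fit")
    _check_aligned(trajs, vels)
    pairs = coeff_index_pairs(alpha)  # validates alpha

    def unpack(z: np.ndarray) -> LandscapeParams:
        return LandscapeParams(alpha=alpha, tau=float(np.exp(z[0])), coeffs=dict(zip(pairs, z[1:])))

    def objective(z: np.ndarray):
        p = unpack(z)
        h = multi_error(p, trajs, vels)
        jac = error_jacobian(p, trajs, vels)
        jac[0] *= p.tau  # chain rule: d/d(log tau) = tau * d/d(tau)
        return h, jac

    z0 = np.zeros(1 + len(pairs))
    z0[0] = np.log(tau0)
    h0 = multi_error(unpack(z0), trajs, vels)
    bounds = [LOG_TAU_BOUNDS] + [(None, None)] * len(pairs)
    res = minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"gtol": gtol, "maxiter": max_iter},
    )
    best = unpack(res.x)
    per = [velocity_error(best, t, v) for t, v in zip(trajs, vels)]
    return FitResult(
        params=best,
        error=float(np.mean(per)),
        per_trajectory_errors=per,
        converged=bool(res.success),
        n_evaluations=int(res.nfev),
        initial_error=h0,
        message=str(res.message),
    )
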