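"""Two-attractor decision-landscape potential and its induced velocity field.

The model describes a two-choice cursor trajectory as overdamped gradient
descent on a scalar potential ``V(x, y)`` over normalized screen coordinates:

    tau * dx/dt = -dV/dx,    tau * dy/dt = -dV/dy,    tau > 0.

``V`` decomposes into a fixed baseline ``V_x(x) + V_y(y)`` whose critical
points put attractors at the two response locations (-1, 1) and (1, 1) and a
repellor at the start (0, 0), plus a fitted polynomial coupling term

    V_xy(x, y) = sum_{k=2}^{alpha} sum_{i+j=k, i,j>=1} c_ij x^i y^j / (k - 1)

whose coefficients ``c_ij`` encode asymmetry and finer structure.  ``c_11``
is the primary left/right asymmetry parameter; ``tau`` sets the time scale
(larger tau, slower motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "LandscapeParams",
    "coeff_index_pairs",
    "param_vector_names",
    "baseline_potential",
    "coupling_potential",
    "potential",
    "gradient",
    "model_velocity",
]

DEFAULT_TAU = 0.05


def coeff_index_pairs(alpha: int) -> list[tuple[int, int]]:
    """Ordered (i, j) exponent pairs of the coupling polynomial for order ``alpha``.

    Pairs are sorted by total degree k = i + j ascending, then by i
    descending, giving [(1,1), (2,1), (1,2), (3,1), (2,2), (1,3), ...].
    """
    if int(alpha) != alpha or alpha < 2:
        raise ParameterError(f"model order alpha must be an integer >= 2, got {alpha!r}")
    pairs = []
    for k in range(2, alpha + 1):
        for i in range(k - 1, 0, -1):
            pairs.append((i, k - i))
    return pairs


def param_vector_names(alpha: int) -> list[str]:
    """Canonical parameter ordering: ``tau`` first, then ``c_ij`` by degree.

    Length is 2 for alpha=2, 4 for alpha=3, 7 for alpha=4.
    """
    return ["tau"] + [f"c{i}{j}" for i, j in coeff_index_pairs(alpha)]


@dataclass
class LandscapeParams:
    """Model order, time scale and coupling coefficients of one landscape.

    Parameters
    ----------
    alpha
        Maximum total degree of the coupling polynomial (>= 2).
    tau
        Time-scale in seconds (> 0); divides the negative gradient.
    coeffs
        Mapping (i, j) -> c_ij for every i, j >= 1 with i + j <= alpha.
        Missing entries default to 0; extra entries are rejected.
    """

    alpha: int
    tau: float = DEFAULT_TAU
    coeffs: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(coeff_index_pairs(self.alpha))
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        extra = set(self.coeffs) - expected
        if extra:
            raise ParameterError(f"coefficients {sorted(extra)} invalid for alpha={self.alpha}")
        self.coeffs = {pair: float(self.coeffs.get(pair, 0.0)) for pair in coeff_index_pairs(self.alpha)}

    @classmethod
    def baseline(cls, alpha: int = 2, tau: float = DEFAULT_TAU) -> "LandscapeParams":
        """All-zero coupling: the symmetric double-well landscape."""
        return cls(alpha=alpha, tau=tau)

    # -- flat-vector view used by the optimizer -------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([self.tau] + [self.coeffs[p] for p in coeff_index_pairs(self.alpha)])

    @classmethod
    def from_vector(cls, alpha: int, vec: np.ndarray) -> "LandscapeParams":
        pairs = coeff_index_pairs(alpha)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(pairs) + 1,):
            raise ParameterError(
                f"parameter vector for alpha={alpha} must have length {len(pairs) + 1}, got {vec.shape}"
            )
        return cls(alpha=alpha, tau=float(vec[0]), coeffs=dict(zip(pairs, vec[1:])))

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"alpha": int(self.alpha), "tau": float(self.tau)}
        for (i, j), c in self.coeffs.items():
            d[f"c{i}{j}"] = float(c)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeParams":
        alpha = int(d["alpha"])
        coeffs = {}
        for key, val in d.items():
            if key.startswith("c") and len(key) == 3 and key[1:].isdigit():
                coeffs[(int(key[1]), int(key[2]))] = float(val)
        return cls(alpha=alpha, tau=float(d.get("tau", DEFAULT_TAU)), coeffs=coeffs)


def baseline_potential(x, y):
    """Fixed double-well baseline ``x^4/4 - x^2/2 + y^3/3 - y^2/2``.

    Its gradient vanishes exactly on {-1, 0, 1} x {0, 1}; the response
    corners (+-1, 1) are attractors and the start (0, 0) a repellor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x**4 / 4 - x**2 / 2 + y**3 / 3 - y**2 / 2


def coupling_potential(params: LandscapeParams, x, y):
    """Fitted polynomial component sum c_ij x^i y^j / (i + j - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.zeros(np.broadcast(x, y).shape)
    for (i, j), c in params.coeffs.items():
        if c != 0.0:
            out += c * x**i * y**j / (i + j - 1)
    return out if out.shape else float(out)


def potential(params: LandscapeParams, x, y):
    """Full decision landscape: baseline plus coupling."""
    return baseline_potential(x, y) + coupling_potential(params, x, y)


def gradient(params: LandscapeParams, x, y):
    """Analytic partials (dV/dx, dV/dy) of the full potential."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gx = x**3 - x
    gy = y**2 - y
    gx, gy = np.broadcast_arrays(gx, gy)
    gx, gy = gx.copy(), gy.copy()
    for (i, j), c in params.coeffs.items():
        if c != 0.0:
            scale = c / (i + j - 1)
            gx += scale * i * x ** (i - 1) * y**j
            gy += scale * j * x**i * y ** (j - 1)
    if gx.shape:
        return gx, gy
    return float(gx), float(gy)


def model_velocity(params: LandscapeParams, x, y):
    """Velocity field ( -dV/dx / tau, -dV/dy / tau ) of the gradient system."""
    gx, gy = gradient(params, x, y)
    return -np.asarray(gx) / params.tau, -np.asarray(gy) / params.tau
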