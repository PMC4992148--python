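"""Stress-dependent generalized Lotka-Volterra community dynamics.

The community model is

    dN_i/dt = mu_i(c) * N_i * (1 - sum_j A_ij(c) * N_j)

where N_i is the biovolume density of species i, mu_i(c) its intrinsic
growth rate (1/d) and A_ij(c) the absolute per-capita competition
coefficient at stressor concentration c.  The diagonal is tied to the
carrying capacity, A_ii(c) = 1/K_i(c); the dimensionless relative
coefficients are alpha_ij(c) = A_ij(c) * K_i(c), so alpha_ii = 1.

Growth rate and carrying capacity depend on stress through a two-level
lookup: parameters exist for the control (0 ug/l) and the high-stress
level; intermediate concentrations reuse the control parameters (the
low-stress treatment was statistically indistinguishable from the
control in the underlying experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

#: densities below this are considered extinct and held at the floor
EXTINCTION_FLOOR = 1.0


class GLVIntegrationError(RuntimeError):
    """Raised when the ODE integration fails; carries parameter context."""


def to_absolute(alpha: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Convert relative interaction coefficients to absolute: A_ij = alpha_ij / K_i."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("carrying capacities must be positive")
    return np.asarray(alpha, dtype=float) / K[:, None]


def to_relative(A: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Convert absolute interaction coefficients to relative: alpha_ij = A_ij * K_i."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("carrying capacities must be positive")
    return np.asarray(A, dtype=float) * K[:, None]


@dataclass
class LevelParams:
    """Growth rates, carrying capacities and interactions at one stress level."""

    mu: np.ndarray
    K: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = self.mu.size
        if self.K.size != n or self.A.shape != (n, n):
            raise ValueError("inconsistent parameter dimensions")
        if np.any(self.mu < 0):
            raise ValueError("growth rates must be non-negative")
        if np.any(self.K <= 0):
            raise ValueError("carrying capacities must be positive")
        if np.any(self.A < 0):
            raise ValueError("competition coefficients must be non-negative")
        # tie the diagonal to the carrying capacity
        self.A[np.diag_indices(n)] = 1.0 / self.K

    @classmethod
    def from_relative(cls, mu, K, alpha) -> "LevelParams":
        return cls(mu=np.asarray(mu, float), K=np.asarray(K, float),
                   A=to_absolute(alpha, K))

    @property
    def alpha(self) -> np.ndarray:
        return to_relative(self.A, self.K)

    @property
    def n_species(self) -> int:
        return self.mu.size


@dataclass
class GLVParams:
    """Community parameters at each fitted stress level.

    ``levels`` maps stressor concentration (ug/l) to :class:`LevelParams`;
    concentrations without their own entry fall back to the control (0).
    """

    species: list[str]
    levels: dict[float, LevelParams] = field(default_factory=dict)

    def at(self, stress: float) -> LevelParams:
        stress = float(stress)
        if stress in self.levels:
            return self.levels[stress]
        return self.levels[0.0]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "levels": {
                str(c): {"mu": p.mu.tolist(), "K": p.K.tolist(), "A": p.A.tolist()}
                for c, p in self.levels.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLVParams":
        levels = {
            float(c): LevelParams(np.array(v["mu"]), np.array(v["K"]), np.array(v["A"]))
            for c, v in d["levels"].items()
        }
        return cls(species=list(d["species"]), levels=levels)


def simulate(
    params: GLVParams,
    stress: float,
    N0: np.ndarray,
    days,
    rtol: float = 1e-8,
    atol: float = 1e-2,
    floor: float = EXTINCTION_FLOOR,
) -> np.ndarray:
    """Integrate the community ODE and sample it at the requested days.

    Parameters
    ----------
    params, stress
        Community parameters and the stress level to simulate at.
    N0 : array
        Initial biovolume densities (>= 0); species starting at zero
        remain absent.
    days : sequence of float
        Sorted, non-negative sampling times (days since inoculation).

    Returns
    -------
    ndarray of shape (n_species, n_days)
        Densities at the requested days, clipped below at the extinction
        floor for species that were inoculated.
    """
    lvl = params.at(stress)
    N0 = np.asarray(N0, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(N0 < 0):
        raise ValueError("initial densities must be non-negative")
    if np.any(np.diff(days) < 0) or np.any(days < 0):
        raise ValueError("days must be sorted and non-negative")
    mu, A = lvl.mu, lvl.A
    present = N0 > 0

    def rhs(t, N):
        N = np.maximum(N, 0.0)
        return mu * N * (1.0 - A @ N)

    t_end = float(days[-1]) if days.size else 0.0
    if t_end == 0.0:
        traj = np.tile(N0[:, None], (1, days.size))
    else:
        sol = solve_ivp(
            rhs, (0.0, t_end), N0, t_eval=days, method="LSODA",
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise GLVIntegrationError(
                f"integration failed at stress {stress}: {sol.message}; "
                f"mu={mu.tolist()}, K={lvl.K.tolist()}"
            )
        traj = sol.y
    traj = np.where(present[:, None], np.maximum(traj, floor), 0.0)
    return traj
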