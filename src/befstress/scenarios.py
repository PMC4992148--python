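"""Five nested scenarios of stress effects on per-capita interactions.

Each scenario is a constraint set on how the interaction coefficients
may differ between the control and high-stress level, encoded as a
bijection between a free-parameter vector and full community parameters:

- S1: no interspecific interactions (alpha_ij = A_ij = 0, i != j);
  densities change under stress only through demographic rates.
- S2: inter- and intraspecific per-capita interactions equal
  (alpha_ij = 1, i.e. A_ij = A_ii = 1/K_i).
- S3: the ratio of inter- to intraspecific interaction strength is
  stress-invariant: alpha_ij shared across levels, A_ij(c) =
  alpha_ij / K_i(c) — per-capita interactions strengthen when stress
  lowers K.
- S4: absolute per-capita interaction strength is stress-invariant:
  A_ij(0) = A_ij(250).
- S5: interactions free at each stress level.

In every scenario the growth rates and carrying capacities at both
levels are free within 10% of their monoculture estimates (growth-rate
upper bounds relaxed to 0.15/d when the monoculture estimate is below
0.1/d), and relative coefficients are bounded in [0, 200].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glv import GLVParams, LevelParams

SCENARIO_LABELS = ("S1", "S2", "S3", "S4", "S5")
FITTED_LEVELS = (0.0, 250.0)
ALPHA_MAX = 200.0
MU_LOW = 0.1
MU_RELAXED_UB = 0.15
MONO_BOUND_FRAC = 0.10


@dataclass
class MonocultureEstimates:
    """Per-species logistic (mu, K) estimates at each fitted stress level."""

    species: list[str]
    mu: dict[float, np.ndarray]
    K: dict[float, np.ndarray]

    def __post_init__(self):
        for c in FITTED_LEVELS:
            if c not in self.mu or c not in self.K:
                raise ValueError(f"missing monoculture estimate for stress level {c}")
            self.mu[c] = np.asarray(self.mu[c], dtype=float)
            self.K[c] = np.asarray(self.K[c], dtype=float)


def _offdiag_indices(n: int):
    idx = [(i, j) for i in range(n) for j in range(n) if i != j]
    rows = np.array([i for i, _ in idx], dtype=int)
    cols = np.array([j for _, j in idx], dtype=int)
    return rows, cols


@dataclass
class ScenarioSpec:
    """Bijection between a bounded free vector and two-level gLV parameters."""

    label: str
    species: list[str]
    mono: MonocultureEstimates
    lower: np.ndarray = field(init=False)
    upper: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        n = self.n_species
        self._rows, self._cols = _offdiag_indices(n)
        lb, ub = [], []
        for c in FITTED_LEVELS:
            for m in self.mono.mu[c]:
                lb.append(max(0.0, (1 - MONO_BOUND_FRAC) * m))
                ub.append(MU_RELAXED_UB if m < MU_LOW else (1 + MONO_BOUND_FRAC) * m)
        for c in FITTED_LEVELS:
            for k in self.mono.K[c]:
                lb.append((1 - MONO_BOUND_FRAC) * k)
                ub.append((1 + MONO_BOUND_FRAC) * k)
        n_pairs = n * (n - 1)
        if self.label == "S3":
            lb += [0.0] * n_pairs
            ub += [ALPHA_MAX] * n_pairs
        elif self.label == "S4":
            k_max = np.maximum(self.mono.K[0.0], self.mono.K[250.0])
            for i in self._rows:
                lb.append(0.0)
                ub.append(ALPHA_MAX / k_max[i])
        elif self.label == "S5":
            for c in FITTED_LEVELS:
                for i in self._rows:
                    lb.append(0.0)
                    ub.append(ALPHA_MAX / self.mono.K[c][i])
        self.lower = np.array(lb)
        self.upper = np.array(ub)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_free(self) -> int:
        return self.lower.size

    # free-vector layout: mu(0), mu(250), K(0), K(250), interaction block
    def _split(self, theta: np.ndarray):
        n = self.n_species
        mu = {c: theta[k * n:(k + 1) * n] for k, c in enumerate(FITTED_LEVELS)}
        K = {c: theta[(2 + k) * n:(3 + k) * n] for k, c in enumerate(FITTED_LEVELS)}
        extra = theta[4 * n:]
        return mu, K, extra

    def unpack(self, theta: np.ndarray) -> GLVParams:
        """Map a free vector onto full parameters at both stress levels."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_free:
            raise ValueError(f"expected free vector of length {self.n_free}")
        n = self.n_species
        mu, K, extra = self._split(theta)
        n_pairs = n * (n - 1)
        levels = {}
        for k, c in enumerate(FITTED_LEVELS):
            A = np.zeros((n, n))
            if self.label == "S2":
                A[:] = (1.0 / K[c])[:, None]
            elif self.label == "S3":
                A[self._rows, self._cols] = extra / K[c][self._rows]
            elif self.label == "S4":
                A[self._rows, self._cols] = extra
            elif self.label == "S5":
                A[self._rows, self._cols] = extra[k * n_pairs:(k + 1) * n_pairs]
            levels[c] = LevelParams(mu=mu[c].copy(), K=K[c].copy(), A=A)
        return GLVParams(species=list(self.species), levels=levels)

    def pack(self, params: GLVParams) -> np.ndarray:
        """Inverse of :meth:`unpack` for parameters satisfying the constraint."""
        n = self.n_species
        parts = [params.levels[c].mu for c in FITTED_LEVELS]
        parts += [params.levels[c].K for c in FITTED_LEVELS]
        if self.label == "S3":
            lvl = params.levels[0.0]
            parts.append(lvl.A[self._rows, self._cols] * lvl.K[self._rows])
        elif self.label == "S4":
            parts.append(params.levels[0.0].A[self._rows, self._cols])
        elif self.label == "S5":
            for c in FITTED_LEVELS:
                parts.append(params.levels[c].A[self._rows, self._cols])
        return np.concatenate(parts)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform random free vector within the bounds."""
        return rng.uniform(self.lower, self.upper)


def make_scenario(label: str, monoculture_estimates: MonocultureEstimates,
                  n: int | None = None) -> ScenarioSpec:
    """Build the :class:`ScenarioSpec` for one scenario label.

    Bounds on mu and K derive from the monoculture estimates; `n`
    defaults to the number of species in those estimates.
    """
    species = list(monoculture_estimates.species)
    if n is not None and n != len(species):
        raise ValueError("n must match the monoculture estimates")
    return ScenarioSpec(label=label, species=species, mono=monoculture_estimates)


def constraint_residual(spec: ScenarioSpec, params: GLVParams) -> float:
    """Max deviation of `params` from the scenario's constraint (0 iff satisfied)."""
    rows, cols = spec._rows, spec._cols
    lv0, lv1 = params.levels[FITTED_LEVELS[0]], params.levels[FITTED_LEVELS[1]]
    if spec.label == "S1":
        return float(
            max(np.abs(lv0.A[rows, cols]).max(initial=0.0),
                np.abs(lv1.A[rows, cols]).max(initial=0.0))
        )
    if spec.label == "S2":
        r = 0.0
        for lv in (lv0, lv1):
            diag = np.diag(lv.A)
            r = max(r, float(np.abs(lv.A - diag[:, None]).max()))
        return r
    if spec.label == "S3":
        a0 = lv0.alpha[rows, cols]
        a1 = lv1.alpha[rows, cols]
        return float(np.abs(a0 - a1).max(initial=0.0))
    if spec.label == "S4":
        return float(np.abs(lv0.A[rows, cols] - lv1.A[rows, cols]).max(initial=0.0))
    return 0.0  # S5: unconstrained
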