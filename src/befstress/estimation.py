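"""Scenario fitting by simulated annealing on a weighted-MAPE objective.

The fit quality of a parameter set for one community is the time- and
abundance-weighted mean absolute percentage error (MAPE) between
observed and predicted biovolumes,

    S = sum_t w_t [ sum_i p_it |N_it,o - N_it,e| / N_it,o ] / sum_t w_t,

with p_it the observed relative abundance of species i at day t.  The
MAPE scales deviations per species (biovolumes differ by orders of
magnitude between species), the abundance weighting keeps the total
community biovolume well predicted in uneven communities, and the day
weights down-weight the noisier early samples.

Parameter sets whose trajectories blow up, extinguish more than one
species, or exceed 100% MAPE are replaced by a penalty
``penalty_base + d(beta, beta0)`` where d is the Euclidean distance of
the (bound-normalised) free vector from the restart's starting point:
the annealer is steered back towards its initial parameters when it
wanders into irrelevant regions.  A soft interaction cut-off penalises
parameter sets in which a species' mean interaction effect exceeds
1,000 times the mean species abundance of the community, which favours
density reductions through carrying capacity or competition with
abundant species over implausibly strong effects of rare species.

Estimation is organised as a statsmodels-style model:
``CommunityGLVModel(data, design, scenario).fit()`` returns a
:class:`GLVFitResults` carrying the per-restart optima, the 2.5/97.5
percentile envelope used for Monte-Carlo uncertainty propagation, and
the best-fit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import dual_annealing, least_squares, minimize

from . import _kernels
from .design import Design
from .glv import GLVParams
from .scenarios import (
    FITTED_LEVELS,
    MonocultureEstimates,
    ScenarioSpec,
    make_scenario,
)

DEFAULT_DAY_WEIGHTS = {7: 0.5, 14: 0.5, 21: 1.0, 28: 1.0}


@dataclass(frozen=True)
class ObjectiveConfig:
    """Tunables of the weighted-MAPE objective and its penalties."""

    day_weights: dict = field(default_factory=lambda: dict(DEFAULT_DAY_WEIGHTS))
    penalty_base: float = 10.0
    mape_cap: float = 1.0
    blowup_multiplier: float = 1e3
    max_extinctions: int = 1
    interaction_cutoff_multiplier: float = 1000.0
    extinction_floor: float = 1.0
    obs_floor: float = 1.0
    dt: float = 0.1

    def __post_init__(self):
        if any(w <= 0 for w in self.day_weights.values()):
            raise ValueError("day weights must be positive")
        if self.mape_cap <= 0:
            raise ValueError("mape_cap must be positive")


def mape_objective(obs: np.ndarray, pred: np.ndarray, day_weights=None,
                   obs_floor: float = 1.0) -> float:
    """Weighted MAPE between observed and predicted (n_days, n_species) arrays.

    `day_weights` is a vector of per-day weights (default: equal); the
    normalisation by their sum makes the score invariant to rescaling
    all weights.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if day_weights is None:
        w = np.ones(obs.shape[0])
    else:
        w = np.asarray(day_weights, dtype=float)
    return float(_kernels.weighted_mape(obs, pred, w, obs_floor))


def logistic(t, N0, mu, K):
    """Closed-form logistic growth curve."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        return K / (1.0 + (K - N0) / N0 * np.exp(-mu * t))


def fit_monocultures(
    data: pd.DataFrame,
    design: Design,
    levels=FITTED_LEVELS,
) -> MonocultureEstimates:
    """Per-species logistic (mu, K) fits to monoculture time series.

    Replicate-mean biovolumes of each richness-1 assemblage are fitted
    with the logistic solution by least squares on log densities (the
    trajectories span orders of magnitude).  The initial density is the
    known inoculation biovolume.  These estimates seed the scenario
    bounds for community fitting.
    """
    species = list(design.species_pool)
    n0 = design.initial_total_biovolume
    mu_hat = {c: np.zeros(len(species)) for c in levels}
    k_hat = {c: np.zeros(len(species)) for c in levels}
    for si, sp in enumerate(species):
        aid = design.monoculture_id(sp)
        if aid is None:
            raise ValueError(f"no monoculture assemblage for species {sp!r}")
        sub = data[(data["assemblage"] == aid) & (data["species"] == sp)]
        for c in levels:
            grp = sub[sub["stress"] == c].groupby("day")["biovolume"].mean()
            if grp.empty:
                raise ValueError(f"no monoculture data for {sp!r} at stress {c}")
            days = grp.index.to_numpy(dtype=float)
            obs = np.maximum(grp.to_numpy(dtype=float), 1.0)

            def resid(x):
                mu, logk = x
                pred = np.maximum(logistic(days, n0, mu, np.exp(logk)), 1.0)
                return np.log(pred) - np.log(obs)

            mu0 = np.clip(np.log(max(obs[0], 1.0) / n0) / days[0], 0.01, 3.0)
            k0 = max(obs.max(), n0 * 1.05)
            sol = least_squares(
                resid,
                x0=[mu0, np.log(k0)],
                bounds=([0.0, np.log(n0 * 1e-3)], [5.0, np.log(n0 * 1e6)]),
            )
            mu_hat[c][si] = sol.x[0]
            k_hat[c][si] = np.exp(sol.x[1])
    return MonocultureEstimates(species=species, mu=mu_hat, K=k_hat)


@dataclass
class _Community:
    """Pre-extracted arrays for one (assemblage, stress level) fit unit."""

    assemblage: str
    stress: float
    level_idx: int
    member_idx: np.ndarray
    n0: np.ndarray
    days: np.ndarray
    obs: np.ndarray  # (n_days, n_members) replicate means
    weights: np.ndarray
    mean_abundance: float


def _prepare_communities(data, design, config) -> list[_Community]:
    means = (
        data[data["stress"].isin(FITTED_LEVELS)]
        .groupby(["assemblage", "stress", "day", "species"])["biovolume"]
        .mean()
        .reset_index()
    )
    sp_index = {sp: i for i, sp in enumerate(design.species_pool)}
    comms = []
    for (aid, stress), grp in means.groupby(["assemblage", "stress"]):
        members = design.assemblages[aid]
        idx = np.array([sp_index[sp] for sp in members], dtype=int)
        days = np.array(sorted(grp["day"].unique()), dtype=float)
        piv = grp.pivot_table(index="day", columns="species", values="biovolume")
        piv = piv.reindex(index=days, columns=list(members))
        obs = piv.to_numpy(dtype=float)
        if np.isnan(obs).any():
            raise ValueError(f"incomplete observations for {aid} at stress {stress}")
        n0 = np.array([design.initial_densities(aid)[sp] for sp in members])
        w = np.array([config.day_weights.get(int(d), 1.0) for d in days])
        comms.append(
            _Community(
                assemblage=aid,
                stress=float(stress),
                level_idx=FITTED_LEVELS.index(float(stress)),
                member_idx=idx,
                n0=n0,
                days=days,
                obs=obs,
                weights=w,
                mean_abundance=float(obs.mean()),
            )
        )
    return comms


class CommunityGLVModel:
    """Stress-dependent gLV community model fitted under a scenario constraint.

    Parameters
    ----------
    data : DataFrame
        Canonical density table (only the fitted stress levels are used).
    design : Design
        The experimental design the data follow.
    scenario : str
        One of "S1".."S5".
    config : ObjectiveConfig, optional
    monoculture_estimates : MonocultureEstimates, optional
        Pre-computed logistic monoculture fits; computed from the data
        when omitted.
    """

    def __init__(self, data, design, scenario="S4", config=None,
                 monoculture_estimates=None):
        self.data = data
        self.design = design
        self.config = config or ObjectiveConfig()
        if monoculture_estimates is None:
            monoculture_estimates = fit_monocultures(data, design)
        self.mono = monoculture_estimates
        self.spec: ScenarioSpec = make_scenario(scenario, monoculture_estimates)
        self.communities = _prepare_communities(data, design, self.config)
        totals = (
            data[data["stress"].isin(FITTED_LEVELS)]
            .groupby(["assemblage", "replicate", "stress", "day"])["biovolume"]
            .sum()
        )
        self.blowup_threshold = self.config.blowup_multiplier * float(totals.max())
        span = self.spec.upper - self.spec.lower
        self._norm_span = np.where(span > 0, span, 1.0)
        self._pack_arrays()

    def _pack_arrays(self):
        """Flatten community data into the arrays the numba kernel consumes."""
        comms = self.communities
        days0 = comms[0].days
        for com in comms:
            if not np.array_equal(com.days, days0):
                raise ValueError("all communities must share the sampling days")
        moff = np.zeros(len(comms) + 1, dtype=np.int64)
        for i, com in enumerate(comms):
            moff[i + 1] = moff[i] + com.member_idx.size
        total = int(moff[-1])
        midx = np.empty(total, dtype=np.int64)
        n0_flat = np.empty(total)
        obs2d = np.empty((days0.size, total))
        for i, com in enumerate(comms):
            sl = slice(moff[i], moff[i + 1])
            midx[sl] = com.member_idx
            n0_flat[sl] = com.n0
            obs2d[:, sl] = com.obs
        self._packed = {
            "level": np.array([c.level_idx for c in comms], dtype=np.int64),
            "moff": moff,
            "midx": midx,
            "n0_flat": n0_flat,
            "obs2d": obs2d,
            "mean_abund": np.array([c.mean_abundance for c in comms]),
            "days": days0,
            "w": comms[0].weights.astype(float),
        }

    def _kernel_terms(self, params: GLVParams):
        n = len(self.design.species_pool)
        mu_levels = np.empty((2, n))
        A_levels = np.empty((2, n, n))
        K_levels = np.empty((2, n))
        for k, c in enumerate(FITTED_LEVELS):
            lvl = params.levels[c]
            mu_levels[k] = lvl.mu
            A_levels[k] = lvl.A
            K_levels[k] = lvl.K
        p = self._packed
        cfg = self.config
        return _kernels.dataset_terms(
            mu_levels, A_levels, K_levels, p["level"], p["moff"], p["midx"],
            p["n0_flat"], p["obs2d"], p["mean_abund"], p["days"], p["w"],
            cfg.dt, cfg.extinction_floor, self.blowup_threshold, cfg.obs_floor,
            cfg.interaction_cutoff_multiplier,
        )

    # -- objective -----------------------------------------------------

    def _eval_communities(self, params: GLVParams):
        """Per-community (mape, status, n_extinct, traj) under `params`."""
        cfg = self.config
        out = []
        level_cache = {c: params.levels[c] for c in FITTED_LEVELS}
        for com in self.communities:
            lvl = level_cache[com.stress]
            idx = com.member_idx
            mu = np.ascontiguousarray(lvl.mu[idx])
            A = np.ascontiguousarray(lvl.A[np.ix_(idx, idx)])
            s, status, n_ext, traj = _kernels.community_fit_terms(
                mu, A, com.n0, com.days, cfg.dt, cfg.extinction_floor,
                self.blowup_threshold, com.obs, com.weights, cfg.obs_floor,
            )
            out.append((s, status, n_ext, traj))
        return out

    def objective(self, params: GLVParams) -> float:
        """Mean weighted MAPE over all fit units (no penalties)."""
        s_mean, n_blow, _, _ = self._kernel_terms(params)
        if n_blow:
            return float("inf")
        return float(s_mean)

    def penalized_objective(self, theta: np.ndarray, theta0: np.ndarray) -> float:
        """Annealing objective for free vector `theta` started from `theta0`."""
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite free vector")
        params = self.spec.unpack(theta)
        s_mean, n_blow, max_ext, excess = self._kernel_terms(params)
        cfg = self.config
        if n_blow > 0 or max_ext > cfg.max_extinctions or s_mean > cfg.mape_cap:
            d = np.linalg.norm((theta - theta0) / self._norm_span)
            return cfg.penalty_base + d
        return float(s_mean + excess)

    # -- fitting -------------------------------------------------------

    def _feasible_start(self, rng, n_inter, max_attempts: int = 60) -> np.ndarray:
        """Random feasible (non-penalized) start in unit coordinates.

        Uniform draws over the full interaction bounds are almost surely
        penalized (interspecific coefficients up to the bound crash the
        community), so the interaction block is progressively shrunk
        towards zero over the attempts; growth rates and capacities stay
        uniform within their (narrow) bounds.
        """
        spec = self.spec
        lo = spec.lower
        hi = np.where(spec.upper <= spec.lower, spec.lower + 1e-12, spec.upper)
        span = hi - lo
        z = None
        for attempt in range(max_attempts):
            z = rng.uniform(0.0, 1.0, size=spec.n_free)
            if n_inter > 0 and attempt > 0:
                z[-n_inter:] *= 0.5 ** attempt
            theta = lo + z * span
            if self.penalized_objective(theta, theta) < self.config.penalty_base:
                return z
        if n_inter > 0:
            z[-n_inter:] = 0.0
            theta = lo + z * span
            if self.penalized_objective(theta, theta) < self.config.penalty_base:
                return z
        raise RuntimeError(
            f"no feasible start found after {max_attempts} attempts "
            f"(scenario {spec.label})"
        )

    def fit(self, n_restarts: int = 100, maxfun: int = 20000, seed: int = 0,
            initial: np.ndarray | None = None) -> "GLVFitResults":
        """Estimate parameters by repeated simulated annealing.

        Each restart draws a random feasible starting vector within the
        scenario bounds (or uses `initial` for the first restart), runs
        generalized simulated annealing on roughly half the `maxfun`
        evaluation budget, and spends the rest polishing the annealing
        optimum with bounded L-BFGS-B (the objective is smooth away
        from the penalty region, where annealing alone converges
        slowly).  The scatter of the restart optima serves as the
        parameter-uncertainty envelope.  Deterministic per seed.
        """
        spec = self.spec
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(n_restarts)
        rows = []
        thetas = np.empty((n_restarts, spec.n_free))
        degenerate = spec.upper <= spec.lower
        lo = spec.lower
        hi = np.where(degenerate, spec.lower + 1e-12, spec.upper)
        span = hi - lo
        # optimize in bound-normalized coordinates: the free vector mixes
        # growth rates (~1/d) with carrying capacities (~1e8), which would
        # defeat the annealer's step sizes and the finite-difference polish
        unit_bounds = [(0.0, 1.0)] * spec.n_free
        anneal_budget = max(100, maxfun // 3)
        polish_budget = max(100, maxfun - anneal_budget)
        n_inter = spec.n_free - 4 * spec.n_species
        for r in range(n_restarts):
            rng = np.random.default_rng(children[r])
            if initial is not None and r == 0:
                z0 = (np.clip(np.asarray(initial, dtype=float), lo, hi) - lo) / span
            else:
                z0 = self._feasible_start(rng, n_inter)
            theta0 = lo + z0 * span
            tracker = {"z": z0.copy(), "f": np.inf}

            def fun(z, _tr=tracker, _theta0=theta0):
                zc = np.clip(z, 0.0, 1.0)
                f = self.penalized_objective(lo + zc * span, _theta0)
                if f < _tr["f"]:
                    _tr["f"] = f
                    _tr["z"] = zc.copy()
                return f

            anneal_seed = int(children[r].generate_state(1)[0] % (2**31 - 1))
            dual_annealing(
                fun, bounds=unit_bounds, x0=z0, seed=anneal_seed,
                maxfun=anneal_budget, no_local_search=True,
            )
            minimize(
                fun, tracker["z"], method="L-BFGS-B", bounds=unit_bounds,
                options={"maxfun": polish_budget},
            )
            thetas[r] = lo + tracker["z"] * span
            rows.append({"restart": r, "objective": float(tracker["f"])})
        table = pd.DataFrame(rows)
        best = int(table["objective"].idxmin())
        return GLVFitResults(
            model=self,
            scenario=spec.label,
            restart_table=table,
            restart_params=thetas,
            best_index=best,
        )


@dataclass
class GLVFitResults:
    """Results of :meth:`CommunityGLVModel.fit`.

    Carries all restart optima, the best-fit community parameters and
    the 2.5/97.5 percentile envelope of the restart estimates, from
    which Monte-Carlo evaluation samples parameter uncertainty.
    """

    model: CommunityGLVModel
    scenario: str
    restart_table: pd.DataFrame
    restart_params: np.ndarray
    best_index: int
    converged_factor: float = 1.5

    @property
    def best_objective(self) -> float:
        return float(self.restart_table["objective"].iloc[self.best_index])

    @property
    def best_theta(self) -> np.ndarray:
        return self.restart_params[self.best_index]

    @property
    def params(self) -> GLVParams:
        return self.model.spec.unpack(self.best_theta)

    @property
    def converged_mask(self) -> np.ndarray:
        """Restarts whose objective is within `converged_factor` of the best.

        With reduced annealing budgets a minority of restarts can stall
        far from the optimum; their scatter reflects optimizer failure,
        not parameter uncertainty, so the percentile envelope excludes
        them.
        """
        obj = self.restart_table["objective"].to_numpy()
        return obj <= self.converged_factor * self.best_objective + 1e-12

    def percentiles(self, lower: float = 2.5, upper: float = 97.5):
        """Per-free-parameter percentile envelope across converged restarts."""
        params = self.restart_params[self.converged_mask]
        lo = np.percentile(params, lower, axis=0)
        hi = np.percentile(params, upper, axis=0)
        return lo, hi

    def summary(self) -> str:
        lo, hi = self.percentiles()
        spec = self.model.spec
        n = spec.n_species
        names = []
        for what in ("mu", "K"):
            for c in FITTED_LEVELS:
                names += [f"{what}[{sp}]({c:g})" for sp in spec.species]
        names += [f"int[{k}]" for k in range(spec.n_free - 4 * n)]
        lines = [
            f"Community gLV fit — scenario {self.scenario}",
            f"communities: {len(self.model.communities)}   "
            f"free parameters: {spec.n_free}   restarts: {len(self.restart_table)}",
            f"best objective (weighted MAPE): {self.best_objective:.6g}",
            "",
            f"{'parameter':<24}{'best':>12}{'p2.5':>12}{'p97.5':>12}",
        ]
        for name, b, l, h in zip(names, self.best_theta, lo, hi):
            lines.append(f"{name:<24}{b:>12.4g}{l:>12.4g}{h:>12.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        lo, hi = self.percentiles()
        return {
            "scenario": self.scenario,
            "best_objective": self.best_objective,
            "best_theta": self.best_theta.tolist(),
            "percentile_2_5": lo.tolist(),
            "percentile_97_5": hi.tolist(),
            "restart_objectives": self.restart_table["objective"].tolist(),
            "params": self.params.to_dict(),
        }


def fit_scenario(
    data: pd.DataFrame,
    design: Design,
    scenario: str,
    monoculture_estimates: MonocultureEstimates | None = None,
    n_restarts: int = 100,
    maxfun: int = 20000,
    seed: int = 0,
    config: ObjectiveConfig | None = None,
    initial: np.ndarray | None = None,
) -> GLVFitResults:
    """Convenience wrapper: build the model and fit one scenario."""
    model = CommunityGLVModel(
        data, design, scenario=scenario, config=config,
        monoculture_estimates=monoculture_estimates,
    )
    return model.fit(n_restarts=n_restarts, maxfun=maxfun, seed=seed, initial=initial)
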