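"""End-to-end synthetic experiments: parameter recovery and scenario ordering.

These are the package's two headline self-checks, run on synthetic data
whose ground truth is known:

- `recovery_experiment`: generate scenario-4 data (stress-invariant
  per-capita interactions) for 8 species in 8 monocultures plus 10
  mixed 4-species communities with 5% observation noise, refit scenario
  4, and measure how well growth rates, carrying capacities and the
  interaction matrix are recovered.
- `ordering_experiment`: on the same kind of data, fit the
  no-interaction scenario S1 and the true scenario S4, propagate
  parameter uncertainty by paired Monte-Carlo runs, and measure how
  often S4 beats S1 on composition similarity; also verify that the
  unconstrained scenario S5, warm-started from S4's optimum, never
  fits worse (its feasible set contains S4's).

Problem sizes (10 mixed communities, reduced annealing budgets, 10
restarts) are scaled for a single-CPU desk run while keeping each
question answerable.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .estimation import CommunityGLVModel, fit_monocultures
from .evaluation import monte_carlo_evaluate
from .scenarios import make_scenario
from .synthetic import SyntheticConfig, gen_dataset, gen_ground_truth

# ten 4-species blocks (five parallel classes of a 1-factorization of the
# 8-species pool) covering all 28 unordered pairs, so every off-diagonal
# interaction coefficient co-occurs in at least one fitted mixture
COVERING_BLOCKS = (
    (0, 1, 2, 3), (4, 5, 6, 7),
    (0, 1, 4, 5), (2, 3, 6, 7),
    (0, 2, 4, 6), (1, 3, 5, 7),
    (0, 3, 4, 7), (1, 2, 5, 6),
    (0, 2, 5, 7), (1, 3, 4, 6),
)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def recovery_design(species_pool) -> "Design":
    """8 monocultures + 10 pair-covering 4-species mixtures."""
    from .design import Design

    assemblages = {f"R1_{i+1}": (sp,) for i, sp in enumerate(species_pool)}
    for b, block in enumerate(COVERING_BLOCKS, start=1):
        assemblages[f"R4_{b}"] = tuple(species_pool[i] for i in block)
    return Design(species_pool=list(species_pool), assemblages=assemblages)


def make_recovery_dataset(seed: int, noise_cv: float = 0.05,
                          scenario: str = "S4"):
    """Ground truth + noisy dataset for the recovery/ordering experiments."""
    s1, s2 = _seeds(seed, 2)
    cfg = SyntheticConfig(seed=s1, generating_scenario=scenario,
                          noise_cv=noise_cv)
    from .design import DEFAULT_SPECIES_POOL

    design = recovery_design(DEFAULT_SPECIES_POOL)
    truth, design = gen_ground_truth(cfg, design=design)
    data = gen_dataset(truth, design, noise_cv=noise_cv, seed=s2)
    return truth, design, data


def recovery_experiment(seed: int = 0, n_restarts: int = 10,
                        maxfun: int = 15000, noise_cv: float = 0.05) -> dict:
    """Refit scenario 4 to synthetic scenario-4 data and score recovery.

    Returns median relative error of mu and K (both stress levels
    pooled), the Spearman rank correlation between true and estimated
    off-diagonal interaction coefficients, the best objective and the
    objective of the truth itself.
    """
    truth, design, data = make_recovery_dataset(seed, noise_cv, "S4")
    model = CommunityGLVModel(data, design, scenario="S4")
    fit = model.fit(n_restarts=n_restarts, maxfun=maxfun, seed=_seeds(seed, 3)[2])
    est = fit.params
    errs = []
    for c in (0.0, 250.0):
        for attr in ("mu", "K"):
            t = getattr(truth.levels[c], attr)
            e = getattr(est.levels[c], attr)
            errs.extend(np.abs(e - t) / np.maximum(np.abs(t), 1e-12))
    off = ~np.eye(truth.n_species, dtype=bool)
    rho = spearmanr(truth.levels[0.0].A[off], est.levels[0.0].A[off]).statistic
    return {
        "median_mu_K_rel_error": float(np.median(errs)),
        "spearman_offdiag_A": float(rho),
        "best_objective": fit.best_objective,
        "objective_at_truth": model.objective(truth),
        "fit": fit,
        "truth": truth,
        "design": design,
        "data": data,
    }


def ordering_experiment(seed: int = 0, n_runs: int = 100,
                        n_restarts: int = 10, maxfun: int = 15000,
                        fit_s4=None, recovery: dict | None = None) -> dict:
    """Scenario ordering on synthetic scenario-4 truth.

    Fits S1 and S4 (reusing a supplied S4 fit when given), runs paired
    Monte-Carlo evaluations, and reports the fraction of runs in which
    S4's mean Bray-Curtis similarity is at least S1's, plus the S5
    warm-start check (optimal S5 objective <= optimal S4 objective).
    """
    if recovery is not None:
        truth, design, data = (recovery["truth"], recovery["design"],
                               recovery["data"])
        fit_s4 = recovery["fit"]
    else:
        truth, design, data = make_recovery_dataset(seed, scenario="S4")
    seeds = _seeds(seed, 6)
    mono = fit_monocultures(data, design)
    model1 = CommunityGLVModel(data, design, scenario="S1",
                               monoculture_estimates=mono)
    fit_s1 = model1.fit(n_restarts=max(3, n_restarts // 2),
                        maxfun=max(2000, maxfun // 3), seed=seeds[3])
    if fit_s4 is None:
        model4 = CommunityGLVModel(data, design, scenario="S4",
                                   monoculture_estimates=mono)
        fit_s4 = model4.fit(n_restarts=n_restarts, maxfun=maxfun, seed=seeds[2])

    # warm-start S5 from the S4 optimum: S4's feasible set lies inside S5's
    spec5 = make_scenario("S5", fit_s4.model.mono)
    theta5_init = spec5.pack(fit_s4.params)
    model5 = CommunityGLVModel(data, design, scenario="S5",
                               monoculture_estimates=fit_s4.model.mono)
    fit_s5 = model5.fit(n_restarts=2, maxfun=max(2000, maxfun // 3),
                        seed=seeds[4], initial=theta5_init)

    mc_seed = seeds[5]
    ev1 = monte_carlo_evaluate(fit_s1, data, design, n_runs=n_runs, seed=mc_seed)
    ev4 = monte_carlo_evaluate(fit_s4, data, design, n_runs=n_runs, seed=mc_seed)
    frac = float(np.mean(ev4.bray_curtis >= ev1.bray_curtis))
    return {
        "frac_s4_bc_ge_s1": frac,
        "s1_best_objective": fit_s1.best_objective,
        "s4_best_objective": fit_s4.best_objective,
        "s5_best_objective": fit_s5.best_objective,
        "s5_le_s4": fit_s5.best_objective <= fit_s4.best_objective + 1e-12,
        "mean_bc_s1": float(np.nanmean(ev1.bray_curtis)),
        "mean_bc_s4": float(np.nanmean(ev4.bray_curtis)),
        "eval_s1": ev1,
        "eval_s4": ev4,
    }
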