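"""Monte-Carlo propagation of parameter uncertainty and scenario comparison.

For each fitted scenario, parameter vectors are sampled uniformly from
the 2.5/97.5 percentile envelope of the restart estimates, the mixed
communities are re-simulated for 28 days from their inoculation
densities at both fitted stress levels, and two metrics are computed
per run:

- the negative Gaussian log-likelihood of the observed proportional
  function loss (control minus stressed total biovolume over control)
  given the predicted loss, with the per-community sigma estimated from
  replicate spread — how well the scenario predicts stress-induced
  change in ecosystem function;
- the mean Bray-Curtis similarity between observed and predicted
  relative community compositions over mixed communities and sampling
  days — how well it predicts composition.

Scenarios are compared pairwise on the paired per-run metrics by
Wilcoxon signed-rank tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, wilcoxon

from . import _kernels
from .design import Design
from .scenarios import FITTED_LEVELS

__all__ = [
    "function_loss",
    "bray_curtis_similarity",
    "EvalResult",
    "monte_carlo_evaluate",
    "compare_scenarios",
]


def function_loss(control_total: float, stressed_total: float) -> float:
    """Proportional loss of ecosystem function under stress.

    (control - stressed) / control; negative when function increases.
    """
    if control_total <= 0:
        raise ValueError("control function must be positive")
    return (control_total - stressed_total) / control_total


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y) between two compositions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("compositions must be non-negative")
    denom = float(x.sum() + y.sum())
    if denom == 0:
        raise ValueError("both compositions are zero")
    return 1.0 - float(np.abs(x - y).sum()) / denom


@dataclass
class EvalResult:
    """Per-run Monte-Carlo metrics for one fitted scenario."""

    scenario: str
    neg_log_lik: np.ndarray  # (n_runs,)
    bray_curtis: np.ndarray  # (n_runs,)
    n_communities: int
    n_comparisons: int  # communities x days entering the composition mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(len(self.neg_log_lik)),
                "scenario": self.scenario,
                "neg_log_lik": self.neg_log_lik,
                "bray_curtis": self.bray_curtis,
            }
        )


def _observed_losses(data: pd.DataFrame, design: Design, day: int,
                     sigma_floor: float = 0.01):
    """Observed day-`day` proportional function loss per mixed community.

    Returns (loss mean, loss sigma) per assemblage, with sigma from the
    replicate spread of the loss (replicates are unpaired across stress
    levels, so the spread is propagated from per-level replicate CVs).
    """
    sub = data[(data["day"] == day) & (data["stress"].isin(FITTED_LEVELS))]
    totals = (
        sub.groupby(["assemblage", "stress", "replicate"])["biovolume"]
        .sum()
        .reset_index()
    )
    out = {}
    for aid in design.mixed_assemblages():
        g = totals[totals["assemblage"] == aid]
        ctrl = g[g["stress"] == FITTED_LEVELS[0]]["biovolume"].to_numpy()
        strs = g[g["stress"] == FITTED_LEVELS[1]]["biovolume"].to_numpy()
        if ctrl.size == 0 or strs.size == 0:
            continue
        loss = function_loss(ctrl.mean(), strs.mean())
        # first-order propagation of replicate sems through the ratio
        ratio = strs.mean() / ctrl.mean()
        rel = 0.0
        if ctrl.size > 1:
            rel += (ctrl.std(ddof=1) / np.sqrt(ctrl.size) / ctrl.mean()) ** 2
        if strs.size > 1:
            rel += (strs.std(ddof=1) / np.sqrt(strs.size) / strs.mean()) ** 2
        sigma = max(abs(ratio) * np.sqrt(rel), sigma_floor)
        out[aid] = (loss, sigma)
    return out


def monte_carlo_evaluate(
    fit,
    data: pd.DataFrame,
    design: Design,
    n_runs: int = 1000,
    seed: int = 0,
    loss_day: int = 28,
    dt: float = 0.05,
) -> EvalResult:
    """Monte-Carlo evaluation of one fitted scenario against observations.

    Parameters are sampled uniformly within the fit's 2.5/97.5
    percentile box; each run simulates every mixed community at both
    fitted stress levels for the full experiment duration.  Runs are
    deterministic per seed, so evaluations of different scenarios under
    the same seed are paired run-by-run.
    """
    spec = fit.model.spec
    lo, hi = fit.percentiles()
    if np.any(hi < lo):
        raise ValueError("degenerate percentile box")
    rng = np.random.default_rng(seed)

    obs_losses = _observed_losses(data, design, loss_day)
    days = np.asarray(design.sampling_days, dtype=float)
    sp_index = {sp: i for i, sp in enumerate(design.species_pool)}
    means = (
        data[data["stress"].isin(FITTED_LEVELS)]
        .groupby(["assemblage", "stress", "day", "species"])["biovolume"]
        .mean()
        .reset_index()
    )
    comms = []
    for aid in design.mixed_assemblages():
        members = design.assemblages[aid]
        idx = np.array([sp_index[sp] for sp in members])
        n0 = np.array([design.initial_densities(aid)[sp] for sp in members])
        obs_comp = {}
        for c in FITTED_LEVELS:
            g = means[(means["assemblage"] == aid) & (means["stress"] == c)]
            piv = g.pivot_table(index="day", columns="species", values="biovolume")
            piv = piv.reindex(index=[int(d) for d in days], columns=list(members))
            obs_comp[c] = piv.to_numpy(dtype=float)
        comms.append((aid, idx, n0, obs_comp))

    blowup = 1e6 * float(data["biovolume"].max() + 1.0)
    floor = 1.0
    nll = np.zeros(n_runs)
    bc = np.zeros(n_runs)
    n_comp = 0
    day_pos = {int(d): k for k, d in enumerate(days)}
    loss_k = day_pos[loss_day]
    for run in range(n_runs):
        theta = rng.uniform(lo, np.maximum(hi, lo + 1e-15))
        params = spec.unpack(theta)
        run_nll = 0.0
        bc_vals = []
        for aid, idx, n0, obs_comp in comms:
            pred = {}
            for c in FITTED_LEVELS:
                lvl = params.levels[c]
                mu = np.ascontiguousarray(lvl.mu[idx])
                A = np.ascontiguousarray(lvl.A[np.ix_(idx, idx)])
                traj, status, _ = _kernels.glv_rk4(mu, A, n0, days, dt, floor, blowup)
                pred[c] = traj  # (n_days, n_members)
            if aid in obs_losses:
                obs_loss, sigma = obs_losses[aid]
                ctrl_tot = pred[FITTED_LEVELS[0]][loss_k].sum()
                strs_tot = pred[FITTED_LEVELS[1]][loss_k].sum()
                if ctrl_tot > 0:
                    pred_loss = function_loss(ctrl_tot, strs_tot)
                    run_nll -= norm.logpdf(obs_loss, loc=pred_loss, scale=sigma)
            for c in FITTED_LEVELS:
                for k in range(len(days)):
                    o = obs_comp[c][k]
                    p = pred[c][k]
                    if np.isnan(o).any():
                        continue
                    osum, psum = o.sum(), p.sum()
                    if osum <= 0 or psum <= 0:
                        continue
                    bc_vals.append(bray_curtis_similarity(o / osum, p / psum))
        nll[run] = run_nll
        bc[run] = float(np.mean(bc_vals)) if bc_vals else np.nan
        if run == 0:
            n_comp = len(bc_vals)
    return EvalResult(
        scenario=fit.scenario,
        neg_log_lik=nll,
        bray_curtis=bc,
        n_communities=len(comms),
        n_comparisons=n_comp,
    )


def compare_scenarios(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank comparisons with Bonferroni correction.

    `results` maps scenario labels to paired :class:`EvalResult`s (same
    run count, same seed stream).  Returns one row per (pair, metric)
    with the signed-rank statistic W and the Bonferroni-adjusted p.
    """
    labels = sorted(results)
    counts = {len(results[s].neg_log_lik) for s in labels}
    if len(counts) > 1:
        raise ValueError("unpaired inputs: run counts differ between scenarios")
    pairs = list(combinations(labels, 2))
    n_tests = len(pairs)
    rows = []
    for a, b in pairs:
        for metric in ("neg_log_lik", "bray_curtis"):
            x = getattr(results[a], metric)
            y = getattr(results[b], metric)
            diff = x - y
            if np.allclose(diff, 0.0):
                w, p = 0.0, 1.0
            else:
                w, p = wilcoxon(x, y)
            rows.append(
                {
                    "scenario_a": a,
                    "scenario_b": b,
                    "metric": metric,
                    "W": float(w),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, p * n_tests)),
                    "median_diff": float(np.median(diff)),
                }
            )
    return pd.DataFrame(rows)
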