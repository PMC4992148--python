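"""Mixed-effects regression stages of the analysis.

Three stages mirror the statistical analysis of the microcosm study:

1. the biodiversity-function relationship: log10 total biovolume
   modelled on log10 richness (LDiv), stress treatment (C: C0/LS/HS)
   and time (Day) with all interactions and a random intercept per
   assemblage;
2. diversity dependence of stress-induced changes in biodiversity
   effects: per component (dominance, trait-dependent, trait-independent
   complementarity), the change modelled on LDiv and Day;
3. the trait model: changes at day 21 and 28 modelled on the
   abundance-weighted stress tolerance Tol (monoculture yield ratio
   M250/M0) and the abundance-weighted per-capita interspecific
   interaction strength Inter (scenario-4 A0 estimates), plus their
   interaction; dInter (scenario-5 A250 - A0) can be added to test for
   stress effects on interactions.

Full models are reduced by hierarchical backward selection: the least
significant droppable interaction (likelihood-ratio test at alpha) is
removed first, and a main effect is never dropped while an interaction
containing it is retained.  Mixed models use statsmodels MixedLM
(random intercept per assemblage); residual normality is reported, not
enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import shapiro
from statsmodels.formula.api import mixedlm, ols
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "RegressionResult",
    "fit_biovolume_model",
    "fit_effect_change_models",
    "build_predictors",
    "fit_predictor_model",
]


@dataclass
class RegressionResult:
    """Coefficient table plus diagnostics for one fitted (mixed) model."""

    response: str
    formula: str
    table: pd.DataFrame  # Estimate, SE, t, p per fixed effect
    model_type: str  # "mixedlm" or "ols"
    normality_p: float
    group_var: float | None = None
    lr_vs_fixed: float | None = None  # loglik gain of the random intercept
    singular: bool = False
    dropped_terms: tuple = ()

    def summary(self) -> str:
        lines = [
            f"{self.model_type} fit: {self.formula}",
            f"residual normality (Shapiro p): {self.normality_p:.3g}"
            + ("   [singular]" if self.singular else ""),
        ]
        if self.group_var is not None:
            lines.append(f"random-intercept variance: {self.group_var:.4g}")
        if self.dropped_terms:
            lines.append(f"dropped by backward selection: {', '.join(self.dropped_terms)}")
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _contains(term_a: str, term_b: str) -> bool:
    """True if interaction `term_a` contains all factors of `term_b`."""
    return set(term_b.split(":")) <= set(term_a.split(":"))


def _fit_once(formula, data, groups, reml=False):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        if groups is not None:
            model = mixedlm(formula, data, groups=data[groups])
            try:
                res = model.fit(reml=reml)
                return res, "mixedlm"
            except (np.linalg.LinAlgError, ValueError):
                pass  # singular random-effect structure: fall back below
        res = ols(formula, data).fit()
        return res, "ols"


def _term_pvalue(res, model_type, term, formula, data, groups):
    """Likelihood-ratio p-value for dropping one term."""
    from scipy.stats import chi2

    reduced = _drop_term(formula, term)
    res_r, type_r = _fit_once(reduced, data, groups)
    try:
        ll_full = res.llf
        ll_red = res_r.llf
    except AttributeError:
        return 1.0
    df = max(1, int(res.params.size - res_r.params.size))
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    return float(chi2.sf(stat, df))


def _drop_term(formula, term):
    lhs, rhs = formula.split("~")
    terms = [t.strip() for t in rhs.split("+")]
    terms = [t for t in terms if t != term]
    return f"{lhs.strip()} ~ " + (" + ".join(terms) if terms else "1")


def _rhs_terms(formula):
    return [t.strip() for t in formula.split("~")[1].split("+") if t.strip() != "1"]


def backward_select(formula: str, data: pd.DataFrame, groups: str | None,
                    alpha: float = 0.05):
    """Hierarchical backward selection by likelihood-ratio tests.

    Repeatedly drops the least significant term (highest LRT p > alpha)
    among the droppable ones; a term is droppable only if no retained
    higher-order interaction contains it.  Returns the final fit, its
    type, the final formula and the dropped terms.
    """
    dropped = []
    while True:
        res, model_type = _fit_once(formula, data, groups)
        terms = _rhs_terms(formula)
        droppable = [
            t for t in terms
            if not any(u != t and _contains(u, t) for u in terms)
        ]
        if not droppable:
            break
        pvals = {
            t: _term_pvalue(res, model_type, t, formula, data, groups)
            for t in droppable
        }
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        formula = _drop_term(formula, worst)
        dropped.append(worst)
        if not _rhs_terms(formula):
            break
    res, model_type = _fit_once(formula, data, groups)
    return res, model_type, formula, tuple(dropped)


def _result_from_fit(res, model_type, formula, response, data, groups,
                     dropped=()) -> RegressionResult:
    if model_type == "mixedlm":
        fe = res.fe_params
        names = list(fe.index)
        table = pd.DataFrame(
            {
                "Estimate": fe.values,
                "SE": res.bse_fe.values,
                "t": res.tvalues[names].values,
                "p": res.pvalues[names].values,
            },
            index=names,
        )
        group_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        singular = group_var <= 1e-12
        resid = np.asarray(res.resid)
        ols_res = ols(formula, data).fit()
        lr = 2.0 * (res.llf - ols_res.llf)
    else:
        table = pd.DataFrame(
            {
                "Estimate": res.params.values,
                "SE": res.bse.values,
                "t": res.tvalues.values,
                "p": res.pvalues.values,
            },
            index=list(res.params.index),
        )
        group_var, lr = None, None
        singular = bool(np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1])
        resid = np.asarray(res.resid)
    if resid.size >= 3 and np.ptp(resid) > 0:
        norm_p = float(shapiro(resid).pvalue)
    else:
        norm_p = 1.0
    return RegressionResult(
        response=response,
        formula=formula,
        table=table,
        model_type=model_type,
        normality_p=norm_p,
        group_var=group_var,
        lr_vs_fixed=lr,
        singular=singular,
        dropped_terms=dropped,
    )


def _stress_factor(stress: pd.Series) -> pd.Series:
    levels = sorted(stress.unique())
    names = ["C0", "LS", "HS"][: len(levels)]
    mapping = dict(zip(levels, names))
    return pd.Categorical(stress.map(mapping), categories=names)


def fit_biovolume_model(data: pd.DataFrame, design=None,
                        select: bool = False) -> RegressionResult:
    """Biodiversity-function model: log10 biovolume ~ LDiv * C * Day.

    `data` is a canonical density table; the response is the log10 total
    biovolume per microcosm per day.  Richness comes from `design` when
    given, else from the number of species observed per assemblage.
    Random intercept per assemblage.
    """
    totals = (
        data.groupby(["assemblage", "replicate", "stress", "day"])["biovolume"]
        .sum()
        .reset_index()
    )
    if design is not None:
        richness = {a: design.richness(a) for a in design.assemblages}
    else:
        richness = data.groupby("assemblage")["species"].nunique().to_dict()
    totals["LDiv"] = np.log10([richness[a] for a in totals["assemblage"]])
    totals["C"] = _stress_factor(totals["stress"])
    totals["Day"] = totals["day"].astype(float)
    if (totals["biovolume"] <= 0).any():
        raise ValueError("biovolumes must be positive to log-transform")
    totals["logbio"] = np.log10(totals["biovolume"])

    n_levels = totals["C"].nunique()
    rhs = "LDiv * C * Day" if n_levels > 1 else "LDiv * Day"
    formula = f"logbio ~ {rhs}"
    if totals["logbio"].std() < 1e-12:
        # degenerate constant response: slopes are identically zero
        res, model_type = _fit_once(formula, totals, None)
        return _result_from_fit(res, model_type, formula, "logbio", totals, None)
    if select:
        res, model_type, formula, dropped = backward_select(
            _expand(formula), totals, "assemblage"
        )
        return _result_from_fit(res, model_type, formula, "logbio", totals,
                                "assemblage", dropped)
    res, model_type = _fit_once(formula, totals, "assemblage", reml=True)
    return _result_from_fit(res, model_type, formula, "logbio", totals, "assemblage")


def _expand(formula: str) -> str:
    """Expand '*' shorthands into explicit '+'-separated terms."""
    lhs, rhs = [s.strip() for s in formula.split("~")]
    out: list[str] = []
    for part in rhs.split("+"):
        part = part.strip()
        if "*" in part:
            factors = [f.strip() for f in part.split("*")]
            from itertools import combinations
            for k in range(1, len(factors) + 1):
                for combo in combinations(factors, k):
                    t = ":".join(combo)
                    if t not in out:
                        out.append(t)
        elif part and part not in out:
            out.append(part)
    return f"{lhs} ~ " + " + ".join(out)


EFFECT_COMPONENTS = (
    "delta_dominance",
    "delta_trait_dependent",
    "delta_trait_independent",
)


def fit_effect_change_models(changes: pd.DataFrame, alpha: float = 0.05,
                             ) -> dict[str, RegressionResult]:
    """Diversity dependence of effect changes: component ~ LDiv * Day.

    `changes` is a stress-change table (one row per mixed assemblage,
    day, stress level) with a `richness` column.  Single-day input
    excludes the Day terms.  Backward-selected per component; random
    intercept per assemblage.
    """
    df = changes.copy()
    df["LDiv"] = np.log10(df["richness"].astype(float))
    df["Day"] = df["day"].astype(float)
    multi_day = df["Day"].nunique() > 1
    out = {}
    for comp in EFFECT_COMPONENTS:
        if comp not in df.columns:
            continue
        rhs = "LDiv * Day" if multi_day else "LDiv"
        res, mt, formula, dropped = backward_select(
            _expand(f"{comp} ~ {rhs}"), df, "assemblage", alpha=alpha
        )
        out[comp] = _result_from_fit(res, mt, formula, comp, df, "assemblage", dropped)
    return out


def build_predictors(
    monoculture_yields: pd.DataFrame,
    fit_s4,
    fit_s5=None,
    data: pd.DataFrame | None = None,
    design=None,
) -> pd.DataFrame:
    """Per-assemblage weighted trait predictors Tol, Inter (and dInter).

    - Tol: abundance-weighted mean of the monoculture yield ratio
      M250/M0 over member species;
    - Inter: abundance-weighted mean per-capita interspecific
      interaction strength A0 acting on each member (scenario-4
      estimates);
    - dInter: same for A250 - A0 (scenario-5 estimates), when given.

    Weights are the species' mean relative biovolume in the control
    mixture.  `monoculture_yields` needs columns species, M0, M250.
    """
    from .scenarios import FITTED_LEVELS

    mono = monoculture_yields.set_index("species")
    params4 = fit_s4.params if hasattr(fit_s4, "params") else fit_s4
    params5 = None
    if fit_s5 is not None:
        params5 = fit_s5.params if hasattr(fit_s5, "params") else fit_s5
    sp_index = {sp: i for i, sp in enumerate(params4.species)}
    ctrl = data[data["stress"] == FITTED_LEVELS[0]]
    ctrl_mean = (
        ctrl.groupby(["assemblage", "species"])["biovolume"].mean().reset_index()
    )
    rows = []
    for aid in design.mixed_assemblages():
        members = list(design.assemblages[aid])
        missing = [sp for sp in members if sp not in mono.index]
        if missing:
            raise ValueError(f"missing monoculture yield for {missing} in {aid}")
        g = ctrl_mean[ctrl_mean["assemblage"] == aid].set_index("species")
        ab = np.array([float(g.loc[sp, "biovolume"]) if sp in g.index else 0.0
                       for sp in members])
        w = ab / ab.sum() if ab.sum() > 0 else np.full(len(members), 1 / len(members))
        ratios = np.array(
            [mono.loc[sp, "M250"] / mono.loc[sp, "M0"] for sp in members]
        )
        idx = np.array([sp_index[sp] for sp in members])
        A0 = params4.levels[FITTED_LEVELS[0]].A[np.ix_(idx, idx)]
        m = len(members)
        off = ~np.eye(m, dtype=bool)
        incoming0 = np.array([A0[i][off[i]].mean() for i in range(m)])
        row = {
            "assemblage": aid,
            "richness": m,
            "Tol": float(w @ ratios),
            "Inter": float(w @ incoming0),
        }
        if params5 is not None:
            dA = (
                params5.levels[FITTED_LEVELS[1]].A[np.ix_(idx, idx)]
                - params5.levels[FITTED_LEVELS[0]].A[np.ix_(idx, idx)]
            )
            d_in = np.array([dA[i][off[i]].mean() for i in range(m)])
            row["dInter"] = float(w @ d_in)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_predictor_model(
    changes: pd.DataFrame,
    predictors: pd.DataFrame,
    days=(21, 28),
    include_dinter: bool = False,
    alpha: float = 0.05,
) -> dict[str, RegressionResult]:
    """Trait model: effect changes at late days ~ Tol * Inter (+ dInter).

    Joins the stress-change table to the per-assemblage predictors,
    restricts to `days`, and backward-selects per component with a
    random intercept per assemblage.
    """
    df = changes[changes["day"].isin(days)].merge(
        predictors.drop(columns=["richness"], errors="ignore"), on="assemblage"
    )
    if df.empty:
        raise ValueError("no effect changes at the requested days")
    out = {}
    for comp in EFFECT_COMPONENTS:
        if comp not in df.columns:
            continue
        rhs = "Tol * Inter"
        if include_dinter and "dInter" in df.columns:
            rhs += " + dInter + Tol:dInter + Inter:dInter"
        if df[comp].std() < 1e-12:
            res, mt = _fit_once(f"{comp} ~ 1", df, None)
            out[comp] = _result_from_fit(res, mt, f"{comp} ~ 1", comp, df, None)
            continue
        res, mt, formula, dropped = backward_select(
            _expand(f"{comp} ~ {rhs}"), df, "assemblage", alpha=alpha
        )
        out[comp] = _result_from_fit(res, mt, formula, comp, df, "assemblage", dropped)
    return out
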