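import numpy as np
import pandas as pd
import pytest

from befstress.design import build_design
from befstress.glv import GLVParams, LevelParams, to_absolute
from befstress.regression import (
    backward_select,
    build_predictors,
    fit_biovolume_model,
    fit_effect_change_models,
    fit_predictor_model,
)


def synth_biovolume_table(rng, b_ldiv=0.5, b_day=0.02, sd_assemblage=0.05,
                          sd_noise=0.05, n_per_richness=4):
    """Density table with a known log10-biovolume structure (one stress level)."""
    rows = []
    aid = 0
    for richness in (1, 2, 4, 8):
        for _ in range(n_per_richness):
            aid += 1
            name = f"A{aid}"
            u = rng.normal(0, sd_assemblage)
            for rep in (1, 2, 3):
                for day in (7, 14, 21, 28):
                    logbio = (7.0 + b_ldiv * np.log10(richness) + b_day * day
                              + u + rng.normal(0, sd_noise))
                    total = 10**logbio
                    for s in range(richness):
                        rows.append({
                            "assemblage": name, "replicate": rep, "stress": 0.0,
                            "day": day, "species": f"sp{s+1}",
                            "biovolume": total / richness,
                        })
    return pd.DataFrame(rows)


class TestBiovolumeModel:
    def test_recovers_known_fixed_effects(self, rng):
        data = synth_biovolume_table(rng)
        res = fit_biovolume_model(data)
        t = res.table
        assert abs(t.loc["LDiv", "Estimate"] - 0.5) < 2 * t.loc["LDiv", "SE"]
        assert abs(t.loc["Day", "Estimate"] - 0.02) < 2 * t.loc["Day", "SE"]
        assert res.model_type == "mixedlm"

    def test_constant_biovolume_degenerates_to_intercept(self, rng):
        data = synth_biovolume_table(rng, b_ldiv=0, b_day=0, sd_assemblage=0,
                                     sd_noise=0)
        res = fit_biovolume_model(data)
        t = res.table
        assert t.loc["Intercept", "Estimate"] == pytest.approx(7.0, abs=1e-6)
        slopes = [i for i in t.index if i != "Intercept"]
        assert np.allclose(t.loc[slopes, "Estimate"], 0.0, atol=1e-6)

    def test_nonpositive_biovolume_rejected(self, rng):
        data = synth_biovolume_table(rng)
        data.loc[0, "biovolume"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_biovolume_model(data)


def synth_changes(rng, b_ldiv=0.0, b_tol=0.0, n_assemblages=24, sd=0.01):
    rows = []
    tol = {}
    for i in range(n_assemblages):
        name = f"A{i+1}"
        richness = int(rng.choice([2, 3, 4, 8]))
        tol[name] = rng.uniform(0.2, 1.0)
        for stress in (250.0,):
            for day in (7, 14, 21, 28):
                base = (b_ldiv * np.log10(richness) * day / 28
                        + b_tol * tol[name])
                rows.append({
                    "assemblage": name, "richness": richness, "stress": stress,
                    "day": day,
                    "delta_dominance": base + rng.normal(0, sd),
                    "delta_trait_dependent": rng.normal(0, sd),
                    "delta_trait_independent": rng.normal(0, sd),
                })
    changes = pd.DataFrame(rows)
    predictors = pd.DataFrame(
        {"assemblage": list(tol), "Tol": list(tol.values()),
         "Inter": rng.uniform(0, 2, n_assemblages)}
    )
    return changes, predictors


class TestEffectChangeModels:
    def test_diversity_dependence_detected_when_present(self, rng):
        changes, _ = synth_changes(rng, b_ldiv=0.5, sd=0.01)
        res = fit_effect_change_models(changes)["delta_dominance"]
        assert "LDiv" in res.formula

    def test_null_diversity_dependence_dropped(self, rng):
        changes, _ = synth_changes(rng, b_ldiv=0.0, sd=0.01)
        res = fit_effect_change_models(changes)["delta_trait_dependent"]
        assert "LDiv:Day" not in res.formula.replace(" ", "")

    def test_single_day_input_excludes_day_terms(self, rng):
        changes, _ = synth_changes(rng, b_ldiv=0.2)
        changes = changes[changes["day"] == 28]
        res = fit_effect_change_models(changes)["delta_dominance"]
        assert "Day" not in res.formula


class TestPredictors:
    def _setup(self):
        design = build_design(seed=0, pool_size=3,
                              assemblage_counts={1: 3, 3: 1},
                              species_pool=["a", "b", "c"])
        mono = pd.DataFrame({
            "species": ["a", "b", "c"],
            "M0": [100.0, 100.0, 100.0],
            "M250": [20.0, 60.0, 100.0],
        })
        alpha = np.full((3, 3), 2.0)
        np.fill_diagonal(alpha, 1.0)
        K = np.array([1e8, 1e8, 1e8])
        lvl = LevelParams(mu=np.ones(3) * 0.5, K=K, A=to_absolute(alpha, K))
        params = GLVParams(species=["a", "b", "c"],
                           levels={0.0: lvl, 250.0: lvl})
        mixed = design.mixed_assemblages()[0]
        rows = []
        for sp, bio in zip(["a", "b", "c"], [10.0, 30.0, 60.0]):
            rows.append({"assemblage": mixed, "replicate": 1, "stress": 0.0,
                         "day": 28, "species": sp, "biovolume": bio})
        data = pd.DataFrame(rows)
        return design, mono, params, data

    def test_tol_is_abundance_weighted_mean_of_yield_ratios(self):
        design, mono, params, data = self._setup()
        pred = build_predictors(mono, params, data=data, design=design)
        # weights (0.1, 0.3, 0.6) on ratios (0.2, 0.6, 1.0)
        assert pred["Tol"].iloc[0] == pytest.approx(0.1 * 0.2 + 0.3 * 0.6 + 0.6 * 1.0)

    def test_constant_interactions_give_constant_inter(self):
        design, mono, params, data = self._setup()
        pred = build_predictors(mono, params, data=data, design=design)
        assert pred["Inter"].iloc[0] == pytest.approx(2.0 / 1e8)

    def test_missing_monoculture_errors(self):
        design, mono, params, data = self._setup()
        with pytest.raises(ValueError, match="monoculture"):
            build_predictors(mono[mono["species"] != "a"], params,
                             data=data, design=design)


class TestPredictorModel:
    def test_recovers_tolerance_slope(self, rng):
        changes, predictors = synth_changes(rng, b_tol=0.5, sd=0.02)
        res = fit_predictor_model(changes, predictors)["delta_dominance"]
        t = res.table
        assert "Tol" in t.index
        assert abs(t.loc["Tol", "Estimate"] - 0.5) < 2 * t.loc["Tol", "SE"]

    def test_constant_response_reduces_to_intercept(self, rng):
        changes, predictors = synth_changes(rng, sd=0.0)
        changes["delta_trait_independent"] = 1.0
        res = fit_predictor_model(changes, predictors)["delta_trait_independent"]
        assert res.formula.endswith("~ 1")

    def test_no_changes_at_requested_days_rejected(self, rng):
        changes, predictors = synth_changes(rng)
        with pytest.raises(ValueError, match="requested days"):
            fit_predictor_model(changes[changes["day"] < 21], predictors)


class TestBackwardSelection:
    def test_never_drops_main_effect_under_retained_interaction(self, rng):
        n = 120
        x = rng.uniform(0, 1, n)
        z = rng.uniform(0, 1, n)
        y = 2.0 * x * z + rng.normal(0, 0.05, n)  # pure interaction signal
        df = pd.DataFrame({"y": y, "x": x, "z": z,
                           "g": rng.choice(["a", "b", "c"], n)})
        res, mt, formula, dropped = backward_select(
            "y ~ x + z + x:z", df, "g"
        )
        assert "x:z" in formula
        assert "x" in formula.split("~")[1]
        assert "z" in formula.split("~")[1]
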