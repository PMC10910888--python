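import numpy as np
import pandas as pd
import pytest

from conftest import drop_outcomes
from epitransport import DGMParams, NINFEA_MARGINS, simulate_population, true_target_ate
from epitransport.populations import stack_populations
from epitransport.simulate import sample_covariates, assign_exposure
from epitransport.tmle import (
    FormulaLogit,
    bound_probabilities,
    clever_covariates,
    eic_values,
    fit_nuisance_models,
    fluctuate,
    transport_tmle,
    transported_ate,
)


class TestCleverCovariates:
    @pytest.mark.parametrize(
        "a, expected",
        [(1.0, (0.0, 2.0)), (0.0, (2.0, 0.0))],
    )
    def test_direct_substitution(self, a, expected):
        h0, h1 = clever_covariates(np.array([a]), np.array([0.5]), np.array([0.5]))
        assert (h0[0], h1[0]) == pytest.approx(expected)

    def test_exactly_one_nonzero_per_row(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 50).astype(float)
        pS = rng.uniform(0.1, 0.9, 50)
        pA = rng.uniform(0.1, 0.9, 50)
        h0, h1 = clever_covariates(a, pS, pA)
        assert np.all(h0 >= 0) and np.all(h1 >= 0)
        assert np.all((h0 == 0) | (h1 == 0))
        assert np.all((h0 > 0) | (h1 > 0))

    def test_vanish_when_selection_certain(self):
        h0, h1 = clever_covariates(np.array([1.0, 0.0]), np.array([1 - 1e-9] * 2), np.array([0.5] * 2))
        assert h0 == pytest.approx([0.0, 0.0], abs=1e-8)
        assert h1 == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_unbounded_probabilities_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            clever_covariates(np.array([1.0]), np.array([1.0]), np.array([0.5]))


class TestBounding:
    def test_counts_truncations(self):
        p = np.array([0.0005, 0.5, 0.9999])
        bounded, n = bound_probabilities(p, (0.001, 0.999))
        assert n == 2
        assert bounded.min() == 0.001 and bounded.max() == 0.999

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            bound_probabilities(np.array([0.5]), (0.0, 1.0))


class TestFluctuation:
    @staticmethod
    def _study_pieces(study, formula="y ~ a + age + parity + education + a:education"):
        om = FormulaLogit(formula).fit(study)
        e0 = np.clip(om.predict_proba(study), 1e-9, 1 - 1e-9)
        rng = np.random.default_rng(3)
        pS = rng.uniform(0.1, 0.6, len(study))
        pA = rng.uniform(0.2, 0.8, len(study))
        h0, h1 = clever_covariates(study["a"].to_numpy(), pS, pA)
        return study["y"].to_numpy(), e0, h0, h1

    @pytest.mark.parametrize("scale", ["logit", "linear"])
    def test_score_equations_solved(self, study_small, scale):
        y, e0, h0, h1 = self._study_pieces(study_small)
        (eps0, eps1), update = fluctuate(y, e0, h0, h1, scale=scale)
        if scale == "logit":
            e_star = update(e0, h0, h1)
        else:
            # the linear normal equations hold for the raw additive update;
            # the update closure additionally truncates predictions to [0, 1]
            e_star = e0 + eps0 * h0 + eps1 * h1
        assert np.mean(h0 * (y - e_star)) == pytest.approx(0.0, abs=1e-6)
        assert np.mean(h1 * (y - e_star)) == pytest.approx(0.0, abs=1e-6)

    def test_epsilon_near_zero_for_maximum_likelihood_initial_fit(self, study_small):
        y, e0, h0, h1 = self._study_pieces(study_small)
        eps, _ = fluctuate(y, e0, h0, h1)
        assert abs(eps[0]) < 0.05 and abs(eps[1]) < 0.05

    def test_degenerate_outcome_pushes_predictions_to_one(self):
        n = 200
        y = np.ones(n)
        e0 = np.full(n, 0.8)
        a = np.tile([0.0, 1.0], n // 2)
        h0, h1 = clever_covariates(a, np.full(n, 0.4), np.full(n, 0.5))
        eps, update = fluctuate(y, e0, h0, h1)
        e_star = update(e0, h0, h1)
        assert np.all(e_star > 0.99)
        # counterfactual risks both approach 1, so the effect vanishes
        q1 = update(np.full(n, 0.8), np.zeros(n), h1 + h0)
        q0 = update(np.full(n, 0.8), h1 + h0, np.zeros(n))
        assert transported_ate(q1, q0) == pytest.approx(0.0, abs=0.02)

    def test_unknown_scale_rejected(self, study_small):
        y, e0, h0, h1 = self._study_pieces(study_small)
        with pytest.raises(ValueError):
            fluctuate(y, e0, h0, h1, scale="probit")


class TestTransportedATE:
    def test_predictor_independent_of_exposure_gives_zero(self):
        q = np.array([0.3, 0.7, 0.5])
        assert transported_ate(q, q) == 0.0

    def test_single_row_standardization(self):
        assert transported_ate(np.array([0.8]), np.array([0.3])) == pytest.approx(0.5)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            transported_ate(np.array([]), np.array([]))


class TestNuisanceModels:
    def test_identical_margins_make_selection_flat(self, dgm):
        study = simulate_population(NINFEA_MARGINS, 4000, seed=71, params=dgm)
        target = simulate_population(NINFEA_MARGINS, 8000, seed=72, params=dgm)
        stacked = stack_populations(study, drop_outcomes(target))
        _, _, smod = fit_nuisance_models(study, stacked)
        p = smod.predict_proba(stacked)
        assert np.mean(p) == pytest.approx(1 / 3, abs=0.01)
        assert np.std(p) < 0.03

    def test_treatment_model_recovers_generator_coefficients(self, study_large):
        _, tm, _ = fit_nuisance_models(
            study_large, stack_populations(study_large, drop_outcomes(study_large))
        )
        params = tm.params
        assert params["age"] == pytest.approx(0.1, abs=0.01)
        assert params["parity[T.1]"] == pytest.approx(-0.3, abs=0.05)
        assert params["parity[T.2]"] == pytest.approx(-0.5, abs=0.10)

    def test_outcome_prediction_is_logistic_in_fitted_predictor(self, study_small):
        om, _, _ = fit_nuisance_models(
            study_small, stack_populations(study_small, drop_outcomes(study_small))
        )
        from scipy.special import expit

        design = om.result_.model.exog
        lp = design @ om.params.to_numpy()
        assert om.predict_proba(study_small) == pytest.approx(expit(lp), abs=1e-10)


class TestTransportTMLEPipeline:
    def test_eic_mean_and_scores_vanish_at_solution(self, study_small, target_small):
        res = transport_tmle(study_small, drop_outcomes(target_small))
        assert np.mean(res.eic) == pytest.approx(0.0, abs=1e-6)
        y = study_small["y"].to_numpy()
        e_star_resid = res.eic[: res.n_study] * (res.n_target / (res.n_study + res.n_target))
        # study-side EIC values are (H1-H0)(Y-E*)/p0; their mean is the score difference
        assert np.mean(e_star_resid) == pytest.approx(0.0, abs=1e-6)

    def test_result_invariants(self, study_small, target_small):
        res = transport_tmle(study_small, drop_outcomes(target_small))
        lo, hi = res.ci95
        assert lo <= res.psi <= hi
        assert -1 <= res.psi <= 1
        assert np.all(res.clever_h0 >= 0) and np.all(res.clever_h1 >= 0)
        assert res.n_study == len(study_small)
        assert res.n_target == len(target_small)

    def test_row_order_permutation_invariance(self, study_small, target_small):
        rng = np.random.default_rng(5)
        res = transport_tmle(study_small, drop_outcomes(target_small))
        shuffled = transport_tmle(
            study_small.sample(frac=1, random_state=rng).reset_index(drop=True),
            drop_outcomes(target_small).sample(frac=1, random_state=rng).reset_index(drop=True),
        )
        assert shuffled.psi == pytest.approx(res.psi, abs=1e-10)

    def test_education_relabeling_invariance(self, study_small, target_small):
        # the outcome model is saturated in education, so renaming levels
        # (consistently in both populations) cannot move the estimate
        relabel = {"high": "low", "low": "high", "medium": "medium"}

        def rename(df):
            out = df.copy()
            out["education"] = pd.Categorical(
                [relabel[e] for e in df["education"]], categories=["high", "medium", "low"]
            )
            return out

        res = transport_tmle(study_small, drop_outcomes(target_small))
        res2 = transport_tmle(rename(study_small), rename(drop_outcomes(target_small)))
        assert res2.psi == pytest.approx(res.psi, abs=1e-8)

    def test_non_binding_bounds_leave_estimate_unchanged(self, study_small, target_small):
        res = transport_tmle(study_small, drop_outcomes(target_small), bounds=(0.001, 0.999))
        res2 = transport_tmle(study_small, drop_outcomes(target_small), bounds=(1e-7, 1 - 1e-7))
        if sum(res.truncation_counts.values()) == 0:
            assert res2.psi == pytest.approx(res.psi, abs=1e-12)
        else:  # pragma: no cover - depends on fixture draw
            pytest.skip("bounds bind on this draw")

    def test_linear_and_logit_fluctuations_agree_closely(self, study_small, target_small):
        logit_res = transport_tmle(study_small, drop_outcomes(target_small), fluctuation="logit")
        linear_res = transport_tmle(study_small, drop_outcomes(target_small), fluctuation="linear")
        assert linear_res.psi == pytest.approx(logit_res.psi, abs=0.01)

    def test_residual_variance_smaller_than_plugin_here(self, study_small, target_small):
        plugin = transport_tmle(study_small, drop_outcomes(target_small), variance="plugin")
        residual = transport_tmle(study_small, drop_outcomes(target_small), variance="residual")
        assert plugin.psi == residual.psi
        assert plugin.se > 0 and residual.se > 0

    def test_missing_rows_are_dropped_with_count(self, study_small, target_small):
        study = study_small.copy()
        study.loc[study.index[:7], "y"] = np.nan
        res = transport_tmle(study, drop_outcomes(target_small))
        assert res.n_dropped_study == 7
        assert res.n_study == len(study_small) - 7

    def test_empty_target_rejected(self, study_small, target_small):
        with pytest.raises(ValueError):
            transport_tmle(study_small, drop_outcomes(target_small).iloc[:0])

    def test_split_population_matches_internal_standardization(self, dgm):
        # a population split at random transports to itself: the transported
        # effect and the within-study g-computation estimate the same thing
        pop = simulate_population(NINFEA_MARGINS, 20_000, seed=81, params=dgm)
        rng = np.random.default_rng(82)
        mask = rng.random(len(pop)) < 0.5
        study, target = pop[mask].reset_index(drop=True), pop[~mask].reset_index(drop=True)
        res = transport_tmle(study, drop_outcomes(target))
        from epitransport import adjusted_rd_gcomp

        gc = adjusted_rd_gcomp(study, n_boot=0)
        assert res.psi == pytest.approx(gc.estimate, abs=2 * res.se)

    def test_double_robustness_against_oracle(self, dgm):
        # misspecify one side at a time; both remain consistent for the oracle
        study = simulate_population(NINFEA_MARGINS, 30_000, seed=91, params=dgm, s=1)
        from epitransport import PBR_2019_MARGINS

        target_full = simulate_population(PBR_2019_MARGINS, 30_000, seed=92, params=dgm, s=0)
        target = drop_outcomes(target_full)
        oracle = true_target_ate(dgm, target)
        no_interactions = transport_tmle(
            study, target, outcome_formula="y ~ a + age + parity + education"
        )
        flat_weights = transport_tmle(
            study, target, treatment_formula="a ~ 1", selection_formula="s ~ 1"
        )
        assert no_interactions.psi == pytest.approx(oracle, abs=0.03)
        assert flat_weights.psi == pytest.approx(oracle, abs=0.03)
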