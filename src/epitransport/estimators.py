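"""Risk-difference estimators with a scikit-learn-style interface.

Three estimators cover the usual comparison when an effect is moved between
populations: the crude contrast of outcome means, the within-population
covariate-adjusted contrast by g-computation (standardization), and the
transported contrast by targeted maximum likelihood.  Each is a
:class:`sklearn.base.BaseEstimator`: configure in ``__init__``, call ``fit``,
read trailing-underscore attributes.  Module-level functions
(:func:`crude_rd`, :func:`adjusted_rd_gcomp`, :func:`transport_tmle`) are thin
wrappers for one-shot use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import tmle as _tmle
from .populations import complete_cases, validate_population
from .tmle import (
    DEFAULT_BOUNDS,
    DEFAULT_OUTCOME_FORMULA,
    DEFAULT_SELECTION_FORMULA,
    DEFAULT_TREATMENT_FORMULA,
    EstimateResult,
    FormulaLogit,
    TMLEResult,
)


def _require_exposure_outcome_columns(pop: pd.DataFrame) -> None:
    for col in ("a", "y"):
        if col not in pop.columns:
            raise ValueError(f"population is missing required column {col!r}")


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


class CrudeRiskDifference(BaseEstimator):
    """Unadjusted risk difference mean(Y|A=1) - mean(Y|A=0).

    Parameters
    ----------
    n_boot : int
        Number of percentile-bootstrap resamples for the 95% CI; 0 skips the
        bootstrap (``ci95_`` is then None).
    seed : int or None
        Seed for the bootstrap resampling.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, population: pd.DataFrame):
        pop = validate_population(population)
        _require_exposure_outcome_columns(pop)
        pop, self.n_dropped_ = complete_cases(pop, require_exposure_outcome=True)
        a = pop["a"].to_numpy(dtype=float)
        y = pop["y"].to_numpy(dtype=float)
        if not (np.any(a == 1) and np.any(a == 0)):
            raise ValueError("both exposure arms must be non-empty")
        self.estimate_ = float(y[a == 1].mean() - y[a == 0].mean())
        self.ci95_ = None
        if self.n_boot > 0:
            rng = np.random.default_rng(self.seed)
            n = len(pop)
            reps = np.empty(self.n_boot)
            for b in range(self.n_boot):
                idx = rng.integers(0, n, n)
                ab, yb = a[idx], y[idx]
                if not (np.any(ab == 1) and np.any(ab == 0)):
                    reps[b] = np.nan
                    continue
                reps[b] = yb[ab == 1].mean() - yb[ab == 0].mean()
            reps = reps[~np.isnan(reps)]
            self.boot_estimates_ = reps
            self.ci95_ = _percentile_ci(reps)
        self.result_ = EstimateResult(
            estimate=self.estimate_, ci95=self.ci95_, method="crude", n_boot=self.n_boot
        )
        return self


class GComputationRD(BaseEstimator):
    """Covariate-adjusted marginal risk difference by g-computation.

    Fits a logistic outcome regression (by default including the
    exposure-by-education effect-modification terms) on ``population`` and
    standardizes the predicted counterfactual risks over
    ``standardization_population`` (the population itself when omitted).
    """

    def __init__(
        self,
        outcome_formula: str = DEFAULT_OUTCOME_FORMULA,
        n_boot: int = 1000,
        seed: int | None = None,
    ):
        self.outcome_formula = outcome_formula
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _point(pop, std_pop, formula) -> float:
        model = FormulaLogit(formula, name="outcome model").fit(pop)
        q1 = model.predict_proba(std_pop.assign(a=1.0))
        q0 = model.predict_proba(std_pop.assign(a=0.0))
        return float(np.mean(q1 - q0))

    def fit(self, population: pd.DataFrame, standardization_population: pd.DataFrame | None = None):
        pop = validate_population(population)
        _require_exposure_outcome_columns(pop)
        pop, self.n_dropped_ = complete_cases(pop, require_exposure_outcome=True)
        same = standardization_population is None
        if same:
            std = pop
        else:
            std = validate_population(standardization_population, name="standardization population")
            std, _ = complete_cases(std, require_exposure_outcome=False)
        self.estimate_ = self._point(pop, std, self.outcome_formula)
        self.ci95_ = None
        if self.n_boot > 0:
            rng = np.random.default_rng(self.seed)
            reps = np.empty(self.n_boot)
            for b in range(self.n_boot):
                pop_b = pop.sample(len(pop), replace=True, random_state=rng)
                std_b = pop_b if same else std.sample(len(std), replace=True, random_state=rng)
                reps[b] = self._point(pop_b, std_b, self.outcome_formula)
            self.boot_estimates_ = reps
            self.ci95_ = _percentile_ci(reps)
        self.result_ = EstimateResult(
            estimate=self.estimate_, ci95=self.ci95_, method="gcomp", n_boot=self.n_boot
        )
        return self


class TransportTMLE(BaseEstimator):
    """Transported risk difference E(Y^1 - Y^0 | S=0) by targeted maximum likelihood.

    Parameters
    ----------
    outcome_formula, treatment_formula, selection_formula : str
        Logistic-regression formulas for the three nuisance fits.  The outcome
        and treatment models are fit on the study rows, the selection model on
        the stacked study+target sample.
    bounds : (float, float)
        Truncation bounds applied to the selection and treatment probabilities
        before the clever covariates are formed.
    fluctuation : {"logit", "linear"}
        Scale of the targeting update; the logit scale keeps updated
        predictions in (0, 1), the linear scale is the plain additive update.
    variance : {"plugin", "residual"}
        EIC variance estimate; the plug-in form (model-based conditional
        second moment averaged over the stacked sample) is the default, the
        residual form is the classical sample variance of the EIC.

    Attributes (after ``fit(study, target)``)
    -----------------------------------------
    psi_ : float            transported risk difference
    se_ : float             EIC-based standard error
    ci95_ : (float, float)  Wald 95% confidence interval
    epsilon_ : (float, float) fluctuation parameters
    result_ : TMLEResult    full internals (clever covariates, EIC, models)
    """

    def __init__(
        self,
        outcome_formula: str = DEFAULT_OUTCOME_FORMULA,
        treatment_formula: str = DEFAULT_TREATMENT_FORMULA,
        selection_formula: str = DEFAULT_SELECTION_FORMULA,
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
        fluctuation: str = "logit",
        variance: str = "plugin",
    ):
        self.outcome_formula = outcome_formula
        self.treatment_formula = treatment_formula
        self.selection_formula = selection_formula
        self.bounds = bounds
        self.fluctuation = fluctuation
        self.variance = variance

    def fit(self, study: pd.DataFrame, target: pd.DataFrame):
        result = _tmle.transport_tmle(
            study,
            target,
            outcome_formula=self.outcome_formula,
            treatment_formula=self.treatment_formula,
            selection_formula=self.selection_formula,
            bounds=self.bounds,
            fluctuation=self.fluctuation,
            variance=self.variance,
        )
        self.result_ = result
        self.psi_ = result.psi
        self.se_ = result.se
        self.ci95_ = result.ci95
        self.epsilon_ = result.epsilon
        self.n_dropped_ = result.n_dropped_study + result.n_dropped_target
        return self

    def predict_counterfactual(self, target_like: pd.DataFrame) -> pd.DataFrame:
        """Updated counterfactual risks E*(a=1,z), E*(a=0,z) for new covariate rows."""
        if not hasattr(self, "result_"):
            raise RuntimeError("TransportTMLE is not fitted")
        res = self.result_
        om = res.models["outcome"]
        tm = res.models["treatment"]
        smod = res.models["selection"]
        pS, _ = _tmle.bound_probabilities(smod.predict_proba(target_like), self.bounds)
        pA, _ = _tmle.bound_probabilities(tm.predict_proba(target_like), self.bounds)
        h1 = (1 - pS) / (pS * pA)
        h0 = (1 - pS) / (pS * (1 - pA))
        from scipy.special import expit, logit

        e1 = np.clip(om.predict_proba(target_like.assign(a=1.0)), 1e-9, 1 - 1e-9)
        e0 = np.clip(om.predict_proba(target_like.assign(a=0.0)), 1e-9, 1 - 1e-9)
        eps0, eps1 = res.epsilon
        if self.fluctuation == "logit":
            q1 = expit(logit(e1) + eps1 * h1)
            q0 = expit(logit(e0) + eps0 * h0)
        else:
            q1 = np.clip(e1 + eps1 * h1, 0, 1)
            q0 = np.clip(e0 + eps0 * h0, 0, 1)
        return pd.DataFrame({"q1": q1, "q0": q0})


def crude_rd(population: pd.DataFrame, n_boot: int = 1000, seed: int | None = None) -> EstimateResult:
    """Crude risk difference with a percentile-bootstrap 95% CI."""
    return CrudeRiskDifference(n_boot=n_boot, seed=seed).fit(population).result_


def adjusted_rd_gcomp(
    population: pd.DataFrame,
    standardization_population: pd.DataFrame | None = None,
    outcome_formula: str = DEFAULT_OUTCOME_FORMULA,
    n_boot: int = 1000,
    seed: int | None = None,
) -> EstimateResult:
    """Adjusted marginal risk difference by g-computation."""
    est = GComputationRD(outcome_formula=outcome_formula, n_boot=n_boot, seed=seed)
    return est.fit(population, standardization_population).result_


def transport_tmle(study: pd.DataFrame, target: pd.DataFrame, **kwargs) -> TMLEResult:
    """One-shot transported risk difference; see :class:`TransportTMLE`."""
    return TransportTMLE(**kwargs).fit(study, target).result_
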