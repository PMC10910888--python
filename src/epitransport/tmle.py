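"""Targeted maximum likelihood estimation of a transported risk difference.

The estimand is the average treatment effect in the target population,

    psi = E(Y^1 - Y^0 | S=0)
        = sum_z [E(Y|S=1,A=1,Z=z) - E(Y|S=1,A=0,Z=z)] P(Z=z|S=0),

identified from study outcomes/exposures plus target covariates alone under
conditional exchangeability (of treatment and of selection) and positivity.

The TMLE proceeds in one targeting step:

1. fit an initial outcome regression E0(Y|S=1,Z,A) on the study rows;
2. fit the treatment propensity P(A=1|S=1,Z) on the study rows and the
   selection propensity P(S=1|Z) on the stacked study+target sample;
3. form the two clever covariates on study rows,

       H0 = (1-A) (1-pS) / [pS (1-pA)],    H1 = A (1-pS) / (pS pA),

   and fluctuate the initial fit by regressing Y on (H0, H1) with the logit of
   E0 as offset and no intercept (logit scale, the default) or by the additive
   update E* = E0 + eps0 H0 + eps1 H1 (linear scale);
4. standardize the updated counterfactual predictions E*(a=1,z) - E*(a=0,z)
   over the empirical target covariate distribution;
5. estimate the standard error from the efficient influence curve (EIC).

The fluctuation solves the weighted score equations sum H_a (Y - E*) = 0, which
makes the sample mean of the EIC vanish at the solution and yields the usual
double robustness: psi is consistent if either the outcome model, or both the
treatment and selection models, are correctly specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import expit, logit

from .populations import complete_cases, stack_populations, validate_population

DEFAULT_OUTCOME_FORMULA = "y ~ a + age + parity + education + a:education"
DEFAULT_TREATMENT_FORMULA = "a ~ age + parity"
# the two populations' age laws differ in dispersion, not just location, so the
# selection log-odds are curved in age; a quadratic term covers normal
# location-scale differences exactly
DEFAULT_SELECTION_FORMULA = "s ~ age + I(age**2) + parity + education"

DEFAULT_BOUNDS = (0.001, 0.999)
_PRED_EPS = 1e-9


class BinaryModelContract(Protocol):
    """Anything that fits a binary response and predicts event probabilities."""

    def fit(self, data: pd.DataFrame) -> "BinaryModelContract": ...

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray: ...


class FormulaLogit:
    """Logistic regression behind a formula, the default nuisance learner.

    Thin wrapper over a statsmodels binomial GLM keeping the contract small:
    ``fit(df)`` then ``predict_proba(df)`` returning event probabilities.
    """

    def __init__(self, formula: str, name: str = "model"):
        self.formula = formula
        self.name = name
        self.result_ = None

    def fit(self, data: pd.DataFrame) -> "FormulaLogit":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.result_ = smf.glm(
                    self.formula, data=data, family=sm.families.Binomial()
                ).fit()
        except Exception as exc:  # pragma: no cover - depends on data pathology
            raise RuntimeError(f"{self.name} ({self.formula!r}) failed to fit: {exc}") from exc
        if not np.all(np.isfinite(self.result_.params)):
            raise RuntimeError(
                f"{self.name} ({self.formula!r}) did not converge to finite coefficients "
                "(possible separation)"
            )
        return self

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        if self.result_ is None:
            raise RuntimeError(f"{self.name} is not fitted")
        return np.asarray(self.result_.predict(data), dtype=float)

    @property
    def params(self) -> pd.Series:
        return self.result_.params


@dataclass
class TMLEResult:
    """Transported risk difference with targeting and inference internals."""

    psi: float
    se: float
    ci95: tuple[float, float]
    epsilon: tuple[float, float]
    clever_h0: np.ndarray
    clever_h1: np.ndarray
    initial_predictions: np.ndarray
    updated_q1_target: np.ndarray
    updated_q0_target: np.ndarray
    eic: np.ndarray
    n_study: int
    n_target: int
    n_dropped_study: int = 0
    n_dropped_target: int = 0
    truncation_counts: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.psi <= hi):
            raise ValueError("ci95 must contain psi")


@dataclass
class EstimateResult:
    """A risk difference with a bootstrap percentile confidence interval."""

    estimate: float
    ci95: tuple[float, float] | None
    method: str
    n_boot: int = 0
    se: float | None = None

    def __post_init__(self):
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo <= self.estimate <= hi):
                raise ValueError("ci95 must contain the estimate")


def fit_nuisance_models(
    study: pd.DataFrame,
    stacked: pd.DataFrame,
    outcome_formula: str = DEFAULT_OUTCOME_FORMULA,
    treatment_formula: str = DEFAULT_TREATMENT_FORMULA,
    selection_formula: str = DEFAULT_SELECTION_FORMULA,
    outcome_model: BinaryModelContract | None = None,
    treatment_model: BinaryModelContract | None = None,
    selection_model: BinaryModelContract | None = None,
):
    """Fit the three nuisance regressions.

    Outcome E(Y|S=1,Z,A) and treatment P(A=1|S=1,Z) are fit on the study rows;
    selection P(S=1|Z) on the stacked study+target sample.  Custom learners
    satisfying :class:`BinaryModelContract` may replace any of the defaults.
    """
    om = outcome_model or FormulaLogit(outcome_formula, name="outcome model")
    tm = treatment_model or FormulaLogit(treatment_formula, name="treatment model")
    smod = selection_model or FormulaLogit(selection_formula, name="selection model")
    om.fit(study)
    tm.fit(study)
    smod.fit(stacked)
    return om, tm, smod


def clever_covariates(a: np.ndarray, p_selection: np.ndarray, p_treatment: np.ndarray, bounds=DEFAULT_BOUNDS):
    """The two transport clever covariates for study rows.

    H0 targets the untreated mean, H1 the treated mean; exactly one is nonzero
    per row.  ``p_selection`` and ``p_treatment`` must already be bounded away
    from 0 and 1 (see :func:`bound_probabilities`).
    """
    a = np.asarray(a, dtype=float)
    pS = np.asarray(p_selection, dtype=float)
    pA = np.asarray(p_treatment, dtype=float)
    lo, hi = bounds
    for name, p in (("p_selection", pS), ("p_treatment", pA)):
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError(
                f"{name} contains probabilities at 0 or 1; apply bound_probabilities "
                f"with bounds such as {DEFAULT_BOUNDS} first"
            )
    h0 = (1.0 - a) * (1.0 - pS) / (pS * (1.0 - pA))
    h1 = a * (1.0 - pS) / (pS * pA)
    return h0, h1


def bound_probabilities(p: np.ndarray, bounds=DEFAULT_BOUNDS) -> tuple[np.ndarray, int]:
    """Truncate probabilities into [lo, hi]; returns (bounded, n_truncated)."""
    lo, hi = bounds
    if not (0 < lo < hi < 1):
        raise ValueError(f"bounds must satisfy 0 < lo < hi < 1, got {bounds}")
    p = np.asarray(p, dtype=float)
    n_trunc = int(np.sum((p < lo) | (p > hi)))
    return np.clip(p, lo, hi), n_trunc


def fluctuate(
    y: np.ndarray,
    e0_pred: np.ndarray,
    h0: np.ndarray,
    h1: np.ndarray,
    scale: str = "logit",
):
    """Estimate the fluctuation parameters eps = (eps0, eps1).

    ``scale="logit"`` fits a no-intercept logistic regression of Y on (H0, H1)
    with offset logit(E0), so E* = plogis(logit(E0) + eps0 H0 + eps1 H1) stays
    in (0, 1).  ``scale="linear"`` solves the additive update
    E* = E0 + eps0 H0 + eps1 H1 by least squares (whose normal equations are
    exactly the score equations sum H_a (Y - E*) = 0), with downstream
    predictions truncated to [0, 1].  Returns ``(epsilon, update)`` where
    ``update(e0, h0, h1)`` applies the fitted fluctuation to new rows (e.g.
    counterfactual target rows with the corresponding clever covariate).
    """
    y = np.asarray(y, dtype=float)
    e0 = np.clip(np.asarray(e0_pred, dtype=float), _PRED_EPS, 1 - _PRED_EPS)
    H = np.column_stack([h0, h1])
    if scale == "logit":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, H, family=sm.families.Binomial(), offset=logit(e0)).fit()
        except Exception as exc:
            raise RuntimeError(f"fluctuation fit failed to converge: {exc}") from exc
        eps = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(eps)):
            raise RuntimeError("fluctuation fit returned non-finite epsilon")

        def update(e0_new, h0_new, h1_new):
            e0_new = np.clip(np.asarray(e0_new, dtype=float), _PRED_EPS, 1 - _PRED_EPS)
            return expit(logit(e0_new) + eps[0] * np.asarray(h0_new) + eps[1] * np.asarray(h1_new))

    elif scale == "linear":
        resid = y - e0
        gram = H.T @ H
        if np.linalg.matrix_rank(gram) < 2:
            # a degenerate arm (all treated or all untreated) leaves one clever
            # covariate identically zero; solve the surviving component only
            eps = np.zeros(2)
            for j in range(2):
                denom = float(H[:, j] @ H[:, j])
                if denom > 0:
                    eps[j] = float(H[:, j] @ resid) / denom
        else:
            eps = np.linalg.solve(gram, H.T @ resid)

        def update(e0_new, h0_new, h1_new):
            raw = (
                np.asarray(e0_new, dtype=float)
                + eps[0] * np.asarray(h0_new)
                + eps[1] * np.asarray(h1_new)
            )
            return np.clip(raw, 0.0, 1.0)

    else:
        raise ValueError(f"scale must be 'logit' or 'linear', got {scale!r}")
    return (float(eps[0]), float(eps[1])), update


def transported_ate(q1_target: np.ndarray, q0_target: np.ndarray) -> float:
    """Standardize updated counterfactual predictions over the target rows."""
    q1 = np.asarray(q1_target, dtype=float)
    q0 = np.asarray(q0_target, dtype=float)
    if q1.size == 0:
        raise ValueError("target is empty")
    return float(np.mean(q1 - q0))


def eic_values(
    psi: float,
    y: np.ndarray,
    h0: np.ndarray,
    h1: np.ndarray,
    e_star: np.ndarray,
    q1_target: np.ndarray,
    q0_target: np.ndarray,
) -> np.ndarray:
    """Per-unit efficient influence curve, study rows first then target rows.

    D_i = S_i (H1_i - H0_i)(Y_i - E*_i)/P(S=0)
        + (1 - S_i) [E*(1,Z_i) - E*(0,Z_i) - psi]/P(S=0),

    with P(S=0) the empirical target fraction of the stacked sample.
    """
    n_study, n_target = len(y), len(q1_target)
    p0 = n_target / (n_study + n_target)
    d_study = (np.asarray(h1) - np.asarray(h0)) * (np.asarray(y, dtype=float) - np.asarray(e_star)) / p0
    d_target = (np.asarray(q1_target) - np.asarray(q0_target) - psi) / p0
    return np.concatenate([d_study, d_target])


def eic_inference(
    psi: float,
    eic: np.ndarray,
    *,
    variance_terms: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """Standard error and Wald 95% CI from the efficient influence curve.

    With ``variance_terms=None`` the variance is the sample variance of the
    per-unit EIC values.  That residual form is anti-conservative in small
    samples, for two reasons: the fluctuation shrinks the realized residuals
    exactly at high-weight points, and the sample mean of the heavy-tailed
    squared clever covariates is itself noisy.  When per-unit model-based
    conditional second moments E(D^2 | Z) are supplied (the package default,
    see :class:`TransportTMLE`), their mean replaces the sample variance —
    the expected-information analogue of the observed-information form.
    """
    eic = np.asarray(eic, dtype=float)
    n = eic.size
    if variance_terms is None:
        var_d = float(np.var(eic))
    else:
        var_d = float(np.mean(variance_terms))
    if var_d == 0 and n > 1:
        warnings.warn("EIC variance is exactly zero; inference is degenerate")
    se = float(np.sqrt(var_d / n))
    return se, (psi - 1.96 * se, psi + 1.96 * se)


def transport_tmle(
    study: pd.DataFrame,
    target: pd.DataFrame,
    outcome_formula: str = DEFAULT_OUTCOME_FORMULA,
    treatment_formula: str = DEFAULT_TREATMENT_FORMULA,
    selection_formula: str = DEFAULT_SELECTION_FORMULA,
    bounds=DEFAULT_BOUNDS,
    fluctuation: str = "logit",
    variance: str = "plugin",
    outcome_model: BinaryModelContract | None = None,
    treatment_model: BinaryModelContract | None = None,
    selection_model: BinaryModelContract | None = None,
) -> TMLEResult:
    """Run the full transport-TMLE pipeline and return a :class:`TMLEResult`.

    ``variance`` selects the EIC variance estimate: ``"plugin"`` (default)
    averages the model-based conditional second moment E(D^2 | Z) over the
    stacked sample, ``"residual"`` uses the classical sample variance of the
    realized EIC values.
    """
    if variance not in ("plugin", "residual"):
        raise ValueError(f"variance must be 'plugin' or 'residual', got {variance!r}")
    study = validate_population(study, name="study")
    target = validate_population(target, name="target")
    study, n_drop_s = complete_cases(study, require_exposure_outcome=True)
    target, n_drop_t = complete_cases(target, require_exposure_outcome=False)
    if len(study) == 0:
        raise ValueError("study has no complete-case rows with exposure and outcome")
    if len(target) == 0:
        raise ValueError("target has no complete-case rows")

    stacked = stack_populations(study, target)
    om, tm, smod = fit_nuisance_models(
        study,
        stacked,
        outcome_formula=outcome_formula,
        treatment_formula=treatment_formula,
        selection_formula=selection_formula,
        outcome_model=outcome_model,
        treatment_model=treatment_model,
        selection_model=selection_model,
    )

    a = study["a"].to_numpy(dtype=float)
    y = study["y"].to_numpy(dtype=float)
    p_sel_study, trunc_sel_s = bound_probabilities(smod.predict_proba(study), bounds)
    p_trt_study, trunc_trt_s = bound_probabilities(tm.predict_proba(study), bounds)
    h0, h1 = clever_covariates(a, p_sel_study, p_trt_study, bounds)
    e0 = np.clip(om.predict_proba(study), _PRED_EPS, 1 - _PRED_EPS)
    epsilon, update = fluctuate(y, e0, h0, h1, scale=fluctuation)
    e_star = update(e0, h0, h1)

    p_sel_target, trunc_sel_t = bound_probabilities(smod.predict_proba(target), bounds)
    p_trt_target, trunc_trt_t = bound_probabilities(tm.predict_proba(target), bounds)
    h0_target = (1.0 - p_sel_target) / (p_sel_target * (1.0 - p_trt_target))
    h1_target = (1.0 - p_sel_target) / (p_sel_target * p_trt_target)
    e0_target_1 = np.clip(om.predict_proba(target.assign(a=1.0)), _PRED_EPS, 1 - _PRED_EPS)
    e0_target_0 = np.clip(om.predict_proba(target.assign(a=0.0)), _PRED_EPS, 1 - _PRED_EPS)
    q1 = update(e0_target_1, np.zeros_like(h1_target), h1_target)
    q0 = update(e0_target_0, h0_target, np.zeros_like(h0_target))

    psi = transported_ate(q1, q0)
    eic = eic_values(psi, y, h0, h1, e_star, q1, q0)
    n_total = len(study) + len(target)
    p0 = len(target) / n_total
    if variance == "plugin":
        # model-smoothed Var(D) = mean over the stacked sample of E(D^2 | Z),
        # with the population-membership, exposure and outcome draws integrated
        # out analytically under the fitted Bernoulli models; this removes the
        # Monte-Carlo noise of the realized heavy-tailed clever covariates from
        # the variance estimate
        p_sel_all = np.concatenate([p_sel_study, p_sel_target])
        p_trt_all = np.concatenate([p_trt_study, p_trt_target])
        h1_all = (1.0 - p_sel_all) / (p_sel_all * p_trt_all)
        h0_all = (1.0 - p_sel_all) / (p_sel_all * (1.0 - p_trt_all))
        e1_study = np.clip(om.predict_proba(study.assign(a=1.0)), _PRED_EPS, 1 - _PRED_EPS)
        e0_study = np.clip(om.predict_proba(study.assign(a=0.0)), _PRED_EPS, 1 - _PRED_EPS)
        e1_all = np.concatenate([e1_study, e0_target_1])
        e0_all = np.concatenate([e0_study, e0_target_0])
        q1_all = update(e1_all, np.zeros_like(h1_all), h1_all)
        q0_all = update(e0_all, h0_all, np.zeros_like(h0_all))
        study_part = (
            p_sel_all
            * (
                p_trt_all * h1_all**2 * e1_all * (1.0 - e1_all)
                + (1.0 - p_trt_all) * h0_all**2 * e0_all * (1.0 - e0_all)
            )
            / p0**2
        )
        target_part = (1.0 - p_sel_all) * (q1_all - q0_all - psi) ** 2 / p0**2
        se, ci = eic_inference(psi, eic, variance_terms=study_part + target_part)
    else:
        se, ci = eic_inference(psi, eic)

    return TMLEResult(
        psi=psi,
        se=se,
        ci95=ci,
        epsilon=epsilon,
        clever_h0=h0,
        clever_h1=h1,
        initial_predictions=e0,
        updated_q1_target=q1,
        updated_q0_target=q0,
        eic=eic,
        n_study=len(study),
        n_target=len(target),
        n_dropped_study=n_drop_s,
        n_dropped_target=n_drop_t,
        truncation_counts={
            "selection_study": trunc_sel_s,
            "treatment_study": trunc_trt_s,
            "selection_target": trunc_sel_t,
            "treatment_target": trunc_trt_t,
        },
        models={"outcome": om, "treatment": tm, "selection": smod},
    )
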