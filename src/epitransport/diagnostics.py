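"""Verifiable-assumption diagnostics: positivity and covariate overlap.

Two of the assumptions behind transporting an effect are checkable from data:
positivity of treatment assignment (every covariate pattern in the study has a
non-degenerate probability of each exposure level) and positivity of selection
(every covariate pattern present in the target has positive probability of
appearing in the study).  The remaining assumptions — exchangeability,
consistency, no interference — are untestable and are surfaced here only as a
documentation checklist, never as pass/fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .populations import EDUCATION_LEVELS, PARITY_LEVELS, validate_population

UNTESTABLE_ASSUMPTIONS = (
    "conditional treatment exchangeability (no unmeasured confounding in the study)",
    "conditional exchangeability for study selection (outcome mechanism shared across populations)",
    "no interference between subjects, within or across populations",
    "treatment definition and version consistency across populations",
)

_QUANTILES = (0.0, 0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99, 1.0)


@dataclass
class PositivityReport:
    """Summaries and flags for the two positivity assumptions."""

    selection_quantiles: dict
    treatment_quantiles: dict
    n_selection_below: int
    n_treatment_outside: int
    stratum_table: pd.DataFrame
    flags: list = field(default_factory=list)
    threshold: float = 0.01
    untestable_assumptions: tuple = UNTESTABLE_ASSUMPTIONS

    def to_dict(self) -> dict:
        return {
            "selection_quantiles": self.selection_quantiles,
            "treatment_quantiles": self.treatment_quantiles,
            "n_selection_below": self.n_selection_below,
            "n_treatment_outside": self.n_treatment_outside,
            "flags": list(self.flags),
            "threshold": self.threshold,
            "stratum_table": self.stratum_table.to_dict(orient="records"),
            "untestable_assumptions": list(self.untestable_assumptions),
        }


@dataclass
class BalanceTable:
    """Study-vs-target covariate summaries with standardized differences."""

    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {"rows": self.table.to_dict(orient="records")}


def _quantile_dict(p: np.ndarray) -> dict:
    qs = np.quantile(p, _QUANTILES)
    return {f"q{int(q * 100):02d}": float(v) for q, v in zip(_QUANTILES, qs)}


def positivity_report(
    study: pd.DataFrame,
    target: pd.DataFrame,
    selection_model,
    treatment_model,
    threshold: float = 0.01,
) -> PositivityReport:
    """Positivity diagnostics from fitted selection and treatment models.

    Flags a selection-positivity problem when a categorical stratum present in
    the target is absent from the study, or when estimated P(S=1|Z) for target
    rows falls below ``threshold``; flags a treatment-positivity problem when
    estimated P(A=1|S=1,Z) on study rows leaves (threshold, 1-threshold).
    The flag threshold is descriptive and distinct from the estimation
    truncation bounds.
    """
    study = validate_population(study, name="study")
    target = validate_population(target, name="target")
    flags: list[str] = []

    p_sel_target = np.asarray(selection_model.predict_proba(target), dtype=float)
    p_trt_study = np.asarray(treatment_model.predict_proba(study), dtype=float)

    n_sel_below = int(np.sum(p_sel_target < threshold))
    n_trt_outside = int(np.sum((p_trt_study < threshold) | (p_trt_study > 1 - threshold)))

    rows = []
    for par in PARITY_LEVELS:
        for edu in EDUCATION_LEVELS:
            in_study = ((study["parity"] == par) & (study["education"] == edu)).sum()
            in_target = ((target["parity"] == par) & (target["education"] == edu)).sum()
            mask = (study["parity"] == par) & (study["education"] == edu)
            exp_prev = float(study.loc[mask, "a"].mean()) if ("a" in study and in_study) else np.nan
            rows.append(
                {
                    "parity": par,
                    "education": edu,
                    "n_study": int(in_study),
                    "n_target": int(in_target),
                    "study_exposure_prevalence": exp_prev,
                }
            )
            if in_target > 0 and in_study == 0:
                flags.append(
                    f"structural selection-positivity violation: stratum parity={par}, "
                    f"education={edu} present in target ({int(in_target)} rows) but absent from study"
                )
    if n_sel_below > 0:
        flags.append(
            f"{n_sel_below} target rows with estimated P(S=1|Z) below {threshold}"
        )
    if n_trt_outside > 0:
        flags.append(
            f"{n_trt_outside} study rows with estimated treatment probability outside "
            f"({threshold}, {1 - threshold})"
        )

    return PositivityReport(
        selection_quantiles=_quantile_dict(p_sel_target),
        treatment_quantiles=_quantile_dict(p_trt_study),
        n_selection_below=n_sel_below,
        n_treatment_outside=n_trt_outside,
        stratum_table=pd.DataFrame(rows),
        flags=flags,
        threshold=threshold,
    )


def _std_diff_continuous(x_s: np.ndarray, x_t: np.ndarray) -> float:
    pooled = np.sqrt((np.var(x_s, ddof=1) + np.var(x_t, ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float((np.mean(x_s) - np.mean(x_t)) / pooled)


def _std_diff_proportion(p_s: float, p_t: float) -> float:
    pooled = np.sqrt((p_s * (1 - p_s) + p_t * (1 - p_t)) / 2)
    if pooled == 0:
        return 0.0
    return float((p_s - p_t) / pooled)


def covariate_balance(study: pd.DataFrame, target: pd.DataFrame) -> BalanceTable:
    """Covariate-distribution table (median/IQR, counts/percentages) with
    standardized differences between study and target."""
    study = validate_population(study, name="study")
    target = validate_population(target, name="target")
    rows = []

    age_s = study["age"].dropna().to_numpy()
    age_t = target["age"].dropna().to_numpy()
    rows.append(
        {
            "covariate": "age",
            "level": "median (IQR)",
            "study": f"{np.median(age_s):.1f} ({np.quantile(age_s, 0.25):.1f}, {np.quantile(age_s, 0.75):.1f})",
            "target": f"{np.median(age_t):.1f} ({np.quantile(age_t, 0.25):.1f}, {np.quantile(age_t, 0.75):.1f})",
            "study_value": float(np.median(age_s)),
            "target_value": float(np.median(age_t)),
            "std_diff": _std_diff_continuous(age_s, age_t),
        }
    )
    for cov, levels in (("parity", PARITY_LEVELS), ("education", EDUCATION_LEVELS)):
        for level in levels:
            n_s = int((study[cov] == level).sum())
            n_t = int((target[cov] == level).sum())
            p_s = n_s / len(study)
            p_t = n_t / len(target)
            rows.append(
                {
                    "covariate": cov,
                    "level": str(level),
                    "study": f"{n_s} ({100 * p_s:.1f})",
                    "target": f"{n_t} ({100 * p_t:.1f})",
                    "study_value": 100 * p_s,
                    "target_value": 100 * p_t,
                    "std_diff": _std_diff_proportion(p_s, p_t),
                }
            )
    return BalanceTable(table=pd.DataFrame(rows))
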