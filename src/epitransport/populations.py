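"""Population tables: the tabular unit all estimation operates on.

A population table is a :class:`pandas.DataFrame` with one row per subject and
columns

``s``
    binary population indicator (1 = study, 0 = target); optional until two
    populations are stacked.
``age``
    maternal age in years, a positive real within the configured support.
``parity``
    categorical number of previous births, coded ``0``, ``1``, ``2`` where
    ``2`` stands for "2 or more".
``education``
    categorical maternal educational level: ``high``, ``medium``, ``low``.
``a``
    binary exposure; required for study rows entering estimation, may be
    missing for target rows.
``y``
    binary outcome; same requirement pattern as ``a``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PARITY_LEVELS = (0, 1, 2)
EDUCATION_LEVELS = ("high", "medium", "low")
AGE_SUPPORT = (15.0, 50.0)

COLUMNS = ("s", "age", "parity", "education", "a", "y")


def as_parity(values) -> pd.Categorical:
    """Coerce a parity vector to the three-level categorical (2 = "2+")."""
    return pd.Categorical(values, categories=list(PARITY_LEVELS))


def as_education(values) -> pd.Categorical:
    """Coerce an education vector to the ordered high/medium/low categorical."""
    return pd.Categorical(values, categories=list(EDUCATION_LEVELS))


def validate_population(
    df: pd.DataFrame,
    *,
    require_exposure: bool = False,
    require_outcome: bool = False,
    age_support: tuple[float, float] = AGE_SUPPORT,
    name: str = "population",
) -> pd.DataFrame:
    """Validate and normalize a population table.

    Returns a copy with canonical dtypes. Raises ``ValueError`` on schema
    violations (unknown category codes, ages outside the support, non-binary
    a/y, or missing required columns).
    """
    if not isinstance(df, pd.DataFrame):
        raise TypeError(f"{name} must be a pandas DataFrame, got {type(df)!r}")
    missing = {"age", "parity", "education"} - set(df.columns)
    if missing:
        raise ValueError(f"{name} is missing required columns: {sorted(missing)}")
    out = df.copy()

    age = pd.to_numeric(out["age"], errors="coerce")
    finite = age.notna()
    lo, hi = age_support
    bad = finite & ((age < lo) | (age > hi))
    if bad.any():
        rows = list(out.index[bad][:5])
        raise ValueError(
            f"{name}: {int(bad.sum())} ages outside support [{lo}, {hi}] (rows {rows})"
        )
    out["age"] = age.astype(float)

    parity = as_parity(out["parity"])
    if parity.isna().sum() > pd.isna(out["parity"]).sum():
        bad_vals = sorted(set(out["parity"].dropna()) - set(PARITY_LEVELS))
        raise ValueError(f"{name}: parity values outside {PARITY_LEVELS}: {bad_vals}")
    out["parity"] = parity

    education = as_education(out["education"])
    if education.isna().sum() > pd.isna(out["education"]).sum():
        bad_vals = sorted(set(out["education"].dropna()) - set(EDUCATION_LEVELS))
        raise ValueError(f"{name}: education values outside {EDUCATION_LEVELS}: {bad_vals}")
    out["education"] = education

    for col, required in (("a", require_exposure), ("y", require_outcome), ("s", False)):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            present = vals.notna()
            if not vals[present].isin([0, 1]).all():
                raise ValueError(f"{name}: column {col!r} must be binary 0/1 where present")
            out[col] = vals.astype(float)
        elif required:
            raise ValueError(f"{name}: required column {col!r} is absent")
        if required and out[col].isna().any():
            raise ValueError(
                f"{name}: column {col!r} has {int(out[col].isna().sum())} missing values "
                "but is required on every row"
            )
    return out


def complete_cases(
    df: pd.DataFrame, *, require_exposure_outcome: bool
) -> tuple[pd.DataFrame, int]:
    """Drop rows with missing covariates (and a/y when required).

    Returns the filtered table and the number of rows dropped; mirrors a
    complete-case analysis.
    """
    keep = df["age"].notna() & df["parity"].notna() & df["education"].notna()
    if require_exposure_outcome:
        for col in ("a", "y"):
            keep &= df[col].notna() if col in df.columns else False
    n_dropped = int((~keep).sum())
    return df.loc[keep].reset_index(drop=True), n_dropped


def stack_populations(study: pd.DataFrame, target: pd.DataFrame) -> pd.DataFrame:
    """Stack study (s=1) on target (s=0) for selection-model fitting."""
    s = study.assign(s=1.0)
    t = target.assign(s=0.0)
    cols = ["s", "age", "parity", "education"]
    stacked = pd.concat([s[cols], t[cols]], ignore_index=True)
    stacked["parity"] = as_parity(stacked["parity"])
    stacked["education"] = as_education(stacked["education"])
    return stacked


def empirical_exposure_design(df: pd.DataFrame) -> pd.DataFrame:
    """Indicator expansion used by closed-form probability evaluation."""
    return pd.DataFrame(
        {
            "age": df["age"].to_numpy(dtype=float),
            "par1": (df["parity"] == 1).to_numpy(dtype=float),
            "par2": (df["parity"] == 2).to_numpy(dtype=float),
            "eduM": (df["education"] == "medium").to_numpy(dtype=float),
            "eduL": (df["education"] == "low").to_numpy(dtype=float),
        }
    )
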