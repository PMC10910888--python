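"""Population-table CSV I/O and run configuration.

The on-disk format is a comma-separated UTF-8 file with header
``s,age,parity,education,a,y``; parity coded 0/1/2 (2 meaning "2+"),
education coded high/medium/low, and missing a/y left as empty fields.
Configuration files may be JSON or YAML with the same structure as
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .populations import COLUMNS, validate_population
from .simulate import DGMParams, NINFEA_MARGINS, PBR_2019_MARGINS, N_NINFEA, N_PBR_2019, PopulationMargins
from .tmle import (
    DEFAULT_BOUNDS,
    DEFAULT_OUTCOME_FORMULA,
    DEFAULT_SELECTION_FORMULA,
    DEFAULT_TREATMENT_FORMULA,
)

_SCHEMA_VERSION = 1


def read_population_csv(path) -> pd.DataFrame:
    """Read and validate a population CSV.

    Unparseable fields raise ``ValueError`` naming the offending line (1-based,
    counting the header as line 1) and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"age", "parity", "education"} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    out = pd.DataFrame(index=raw.index)
    def parse(col, converter, allowed=None, required=True):
        if col not in raw.columns:
            return None
        values = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                if required:
                    raise ValueError(f"{path}: line {i + 2}, column {col!r}: empty value")
                values.append(np.nan)
                continue
            try:
                v = converter(cell)
            except ValueError:
                raise ValueError(f"{path}: line {i + 2}, column {col!r}: cannot parse {cell!r}") from None
            if allowed is not None and v not in allowed:
                raise ValueError(
                    f"{path}: line {i + 2}, column {col!r}: value {cell!r} not in {sorted(allowed)}"
                )
            values.append(v)
        return values

    out["age"] = parse("age", float)
    out["parity"] = parse("parity", int, allowed={0, 1, 2})
    out["education"] = parse("education", str, allowed={"high", "medium", "low"})
    for col in ("s", "a", "y"):
        parsed = parse(col, int, allowed={0, 1}, required=False)
        if parsed is not None:
            out[col] = parsed
    return validate_population(out, name=str(path))


def write_population_csv(pop: pd.DataFrame, path) -> None:
    """Write a population table using the canonical column order and coding."""
    path = Path(path)
    out = pd.DataFrame()
    for col in COLUMNS:
        if col in pop.columns:
            out[col] = pop[col]
    for col in ("s", "a", "y"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to replay a full run.

    Exactly one of ``{study_csv, study_margins}`` and one of
    ``{target_csv, target_margins}`` must be supplied.
    """

    study_csv: str | None = None
    target_csv: str | None = None
    study_margins: PopulationMargins | None = None
    target_margins: PopulationMargins | None = None
    n_study: int = N_NINFEA
    n_target: int = N_PBR_2019
    dgm: DGMParams = field(default_factory=DGMParams)
    outcome_formula: str = DEFAULT_OUTCOME_FORMULA
    treatment_formula: str = DEFAULT_TREATMENT_FORMULA
    selection_formula: str = DEFAULT_SELECTION_FORMULA
    estimator: str = "tmle"
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    fluctuation: str = "logit"
    variance: str = "plugin"
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for side in ("study", "target"):
            has_csv = getattr(self, f"{side}_csv") is not None
            has_margins = getattr(self, f"{side}_margins") is not None
            if has_csv == has_margins:
                raise ValueError(
                    f"exactly one of {side}_csv / {side}_margins must be supplied"
                )
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def default_example(cls, seed: int = 0, **overrides) -> "RunConfig":
        """The built-in worked example: NINFEA-margin study, PBR-margin target."""
        kwargs = dict(
            study_margins=NINFEA_MARGINS,
            target_margins=PBR_2019_MARGINS,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _margins_from_dict(d: dict) -> PopulationMargins:
    return PopulationMargins(
        age_median=d["age_median"],
        age_q1=d["age_q1"],
        age_q3=d["age_q3"],
        parity_probs=tuple(d["parity_probs"]),
        education_probs=tuple(d["education_probs"]),
        label=d.get("label", ""),
        age_support=tuple(d.get("age_support", (15.0, 50.0))),
        age_model=d.get("age_model", "truncnorm"),
    )


_NAMED_MARGINS = {"ninfea": NINFEA_MARGINS, "pbr2019": PBR_2019_MARGINS}


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or YAML file.

    Margins may be given inline as a mapping or by the names ``ninfea`` /
    ``pbr2019``; DGM coefficients as a mapping under ``dgm``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs = dict(data)
    for side in ("study_margins", "target_margins"):
        if side in kwargs and kwargs[side] is not None:
            m = kwargs[side]
            if isinstance(m, str):
                kwargs[side] = _NAMED_MARGINS[m.lower()]
            else:
                kwargs[side] = _margins_from_dict(m)
    if "dgm" in kwargs and isinstance(kwargs["dgm"], dict):
        kwargs["dgm"] = DGMParams(**kwargs["dgm"])
    if "bounds" in kwargs:
        kwargs["bounds"] = tuple(kwargs["bounds"])
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**kwargs)


def config_to_jsonable(cfg: RunConfig) -> dict:
    """Serializable view of a config, recorded in every run report."""
    d = dataclasses.asdict(cfg)
    d["schema_version"] = _SCHEMA_VERSION
    return d
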