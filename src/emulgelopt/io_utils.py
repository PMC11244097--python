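"""CSV readers/writers and run configuration.

Dialect: comma-separated UTF-8 with a mandatory header row and "."
decimals; percentages are stored as numbers on the 0–100 scale as
printed, never as fractions.

Schemas
-------
design:    run_id, oil_pct, polysorbate_pct, coded_A, coded_B,
           poloxamer_pct, water_pct, cpo_pct
responses: run_id, replicate_id, response_name, value
release:   run_id, time_h, concentration_mg_per_ml
rheology:  run_id, temperature_C, g_prime_Pa
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .design import (
    EMULGEL_FACTOR_SPACE,
    DesignRun,
    DesignTable,
    FactorSpace,
    FormulationRule,
    complete_formulation,
)

__all__ = [
    "RunConfig",
    "write_design_csv",
    "read_design_csv",
    "write_responses_csv",
    "read_responses_csv",
    "read_release_csv",
    "write_release_csv",
    "read_rheology_csv",
    "write_rheology_csv",
]

DESIGN_COLUMNS = [
    "run_id", "oil_pct", "polysorbate_pct", "coded_A", "coded_B",
    "poloxamer_pct", "water_pct", "cpo_pct",
]
RESPONSE_COLUMNS = ["run_id", "replicate_id", "response_name", "value"]
RELEASE_COLUMNS = ["run_id", "time_h", "concentration_mg_per_ml"]
RHEOLOGY_COLUMNS = ["run_id", "temperature_C", "g_prime_Pa"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def write_design_csv(design: DesignTable, path) -> None:
    frame = design.to_frame()
    for col in DESIGN_COLUMNS:
        if col not in frame.columns:
            frame[col] = float("nan")
    frame[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design_csv(path, factor_space: FactorSpace | None = None) -> DesignTable:
    df = pd.read_csv(path)
    _require_columns(df, DESIGN_COLUMNS[:5], path)
    if factor_space is None:
        factor_space = EMULGEL_FACTOR_SPACE
    runs = []
    for i, row in df.iterrows():
        actual = (float(row["oil_pct"]), float(row["polysorbate_pct"]))
        coded = (float(row["coded_A"]), float(row["coded_B"]))
        if "poloxamer_pct" in df.columns and pd.notna(row.get("poloxamer_pct")):
            formulation = {
                "mineral_oil": actual[0],
                "polysorbate_80": actual[1],
                "poloxamer_407": float(row["poloxamer_pct"]),
                "purified_water": float(row["water_pct"]),
                "ciclopirox_olamine": float(row["cpo_pct"]),
            }
        else:
            formulation = None
        runs.append(DesignRun(run_id=str(row["run_id"]), coded=coded, actual=actual,
                              formulation=formulation))
    return DesignTable(factor_space=factor_space, runs=tuple(runs))


def write_responses_csv(responses: pd.DataFrame, path) -> None:
    _require_columns(responses, RESPONSE_COLUMNS, path)
    responses[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESPONSE_COLUMNS, path)
    return df


def response_series(responses: pd.DataFrame, response_name: str) -> pd.DataFrame:
    """Rows of one response as a (run_id, value) frame suitable for fitting."""
    sub = responses[responses["response_name"] == response_name]
    if sub.empty:
        raise ValueError(f"no rows for response {response_name!r}")
    return sub[["run_id", "value"]].copy()


def write_release_csv(profiles: pd.DataFrame, path) -> None:
    _require_columns(profiles, RELEASE_COLUMNS, path)
    profiles[RELEASE_COLUMNS].to_csv(path, index=False)


def read_release_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RELEASE_COLUMNS, path)
    return df


def write_rheology_csv(sweeps: pd.DataFrame, path) -> None:
    _require_columns(sweeps, RHEOLOGY_COLUMNS, path)
    sweeps[RHEOLOGY_COLUMNS].to_csv(path, index=False)


def read_rheology_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RHEOLOGY_COLUMNS, path)
    return df


@dataclass
class RunConfig:
    """Whole-pipeline configuration with the study's validation thresholds."""

    oil_min: float = 10.0
    oil_max: float = 50.0
    polysorbate_min: float = 0.0
    polysorbate_max: float = 10.0
    responses: tuple[str, ...] = ("ph", "d50", "t_sol_gel", "flux", "firmness", "work_of_shear")
    candidate_families: tuple[str, ...] = ("linear", "2FI", "quadratic")
    prune_threshold: float = 0.10
    model_p_threshold: float = 0.05
    r2_gap_threshold: float = 0.2
    adeq_precision_min: float = 4.0
    criteria: tuple[dict, ...] = (
        {"response": "flux", "goal": "maximize"},
        {"response": "t_sol_gel", "goal": "minimize"},
        {"response": "d50", "goal": "minimize"},
    )
    seed: int = 0
    output_dir: str = "emulgelopt-out"

    def __post_init__(self) -> None:
        for name, v in (("prune_threshold", self.prune_threshold),
                        ("model_p_threshold", self.model_p_threshold),
                        ("r2_gap_threshold", self.r2_gap_threshold),
                        ("adeq_precision_min", self.adeq_precision_min)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for c in self.criteria:
            if c["response"] not in self.responses:
                raise ValueError(
                    f"criterion references undeclared response {c['response']!r}"
                )

    @property
    def factor_space(self) -> FactorSpace:
        return FactorSpace(
            names=("mineral_oil", "polysorbate_80"),
            low=(self.oil_min, self.polysorbate_min),
            high=(self.oil_max, self.polysorbate_max),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("responses", "candidate_families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "criteria" in raw:
            raw["criteria"] = tuple(raw["criteria"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["responses"] = list(data["responses"])
        data["candidate_families"] = list(data["candidate_families"])
        data["criteria"] = [dict(c) for c in data["criteria"]]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
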