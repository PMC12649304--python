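"""CSV/JSON/YAML readers and writers plus pipeline configuration.

All tabular interchange is comma-separated UTF-8 with a required header
and "." decimals.  Readers validate every row and report all offending
rows (with line numbers) in a single :class:`SchemaError`; numeric fields
round-trip losslessly to 12 significant digits.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from cocpd.ddi import BMI_GROUPS, INDUCERS, ExposureRecord, Scenario
from cocpd.model import DEFAULT_DRUGS, DrugSpec, Endpoint, TrialArm

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "load_config",
    "default_drug_registry",
    "default_exposure_table",
    "default_scenarios",
    "read_arms",
    "write_arms",
    "read_exposure",
    "read_scenarios",
    "write_table",
]

log = logging.getLogger("cocpd")

FLOAT_FMT = "%.12g"

ARM_COLUMNS = ["study_id", "arm_id", "drug_id", "dose_ug", "ee_dose_ug",
               "endpoint", "observed", "n_subjects", "cavg_ng_ml"]
EXPOSURE_COLUMNS = ["drug_id", "dose_ug", "ee_dose_ug", "bmi_group", "inducer",
                    "cavg_ng_ml", "gcv_percent"]
SCENARIO_COLUMNS = ["drug_id", "dose_ug", "ee_dose_ug", "bmi_group", "inducer",
                    "n_virtual", "seed", "is_reference"]


class SchemaError(ValueError):
    """Raised when a file fails validation; message lists offending rows."""


# ---------------------------------------------------------------------------
# configuration


class EndpointFixed(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline: float
    imax: float = 1.0


class DrugEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    molecular_weight: float = Field(gt=0)
    log10_kd: float


class EstimationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grad_tol: float = 1e-8
    tau_starts: list[float] = [0.3, 1.5, 5.0]
    hill_starts: list[float] = [1.0, 5.0, 20.0]


class TauSimOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 500
    seed: int = 20210501
    se_inflation: bool = True


class ScenarioDefaults(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_virtual: int = 100
    gcv_percent: float = 30.0


class PipelineConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    drugs: dict[str, DrugEntry] = {
        "LNG": DrugEntry(molecular_weight=312.45, log10_kd=3.556),
        "DRSP": DrugEntry(molecular_weight=366.49, log10_kd=2.949),
    }
    concentration_scale: str = "log10"
    fixed: dict[str, EndpointFixed] = {
        "PI": EndpointFixed(baseline=85.0, imax=1.0),
        "OR": EndpointFixed(baseline=100.0, imax=1.0),
    }
    estimation: EstimationOptions = EstimationOptions()
    tau_sim: TauSimOptions = TauSimOptions()
    scenario: ScenarioDefaults = ScenarioDefaults()

    def drug_specs(self) -> dict[str, DrugSpec]:
        return {
            d: DrugSpec(d, e.molecular_weight, e.log10_kd)
            for d, e in self.drugs.items()
        }


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load (or default) the pipeline configuration and log the result."""
    if path is None:
        cfg = PipelineConfig()
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig.model_validate(raw)
    log.info("resolved config: %s", cfg.model_dump())
    return cfg


def default_drug_registry() -> dict[str, DrugSpec]:
    return dict(DEFAULT_DRUGS)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("cocpd").joinpath("data", name))


def default_exposure_table() -> list[ExposureRecord]:
    """Packaged dose->Cavg fixture emulating external PBPK model output."""
    return read_exposure(_data_path("exposure_default.csv"))


def default_scenarios() -> list[tuple[Scenario, bool]]:
    """Packaged DDI x BMI scenario grid (LNG 100/150, DRSP 3000; CBZ/RIF)."""
    return read_scenarios(_data_path("scenarios_default.csv"))


# ---------------------------------------------------------------------------
# tabular readers / writers


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        log.warning("%s: no data rows", path)
    return df


def _collect(errors: list[str], path) -> None:
    if errors:
        raise SchemaError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )


def read_arms(path: str | Path) -> list[TrialArm]:
    """Read trial arms; n_subjects must be >= 1.

    A negative ``observed`` is legal (synthetic arms carry untruncated
    additive noise) but is logged, since real endpoint data cannot be
    negative.  The ``cavg_ng_ml`` field may be empty (unresolved
    exposure).
    """
    df = _read_table(path, ARM_COLUMNS)
    arms: list[TrialArm] = []
    errors: list[str] = []
    n_negative = 0
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            endpoint = Endpoint(row["endpoint"])
            observed = float(row["observed"])
            n_negative += observed < 0
            n_subjects = int(row["n_subjects"])
            cavg = float(row["cavg_ng_ml"]) if row["cavg_ng_ml"] != "" else None
            arms.append(TrialArm(
                study_id=row["study_id"],
                arm_id=row["arm_id"],
                drug_id=row["drug_id"],
                dose_ug=float(row["dose_ug"]),
                ee_dose_ug=float(row["ee_dose_ug"]),
                endpoint=endpoint,
                observed=observed,
                n_subjects=n_subjects,
                cavg=cavg,
            ))
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    _collect(errors, path)
    if n_negative:
        log.warning("%s: %d arm(s) with negative observed values", path, n_negative)
    return arms


def write_arms(arms: Sequence[TrialArm], path: str | Path) -> None:
    rows = [{
        "study_id": a.study_id,
        "arm_id": a.arm_id,
        "drug_id": a.drug_id,
        "dose_ug": a.dose_ug,
        "ee_dose_ug": a.ee_dose_ug,
        "endpoint": a.endpoint.value,
        "observed": a.observed,
        "n_subjects": a.n_subjects,
        "cavg_ng_ml": "" if a.cavg is None else a.cavg,
    } for a in arms]
    pd.DataFrame(rows, columns=ARM_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_exposure(path: str | Path) -> list[ExposureRecord]:
    df = _read_table(path, EXPOSURE_COLUMNS)
    records: list[ExposureRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            if row["bmi_group"] not in BMI_GROUPS:
                raise ValueError(f"unknown bmi_group {row['bmi_group']!r}")
            if row["inducer"] not in INDUCERS:
                raise ValueError(f"unknown inducer {row['inducer']!r}")
            records.append(ExposureRecord(
                drug_id=row["drug_id"],
                dose_ug=float(row["dose_ug"]),
                ee_dose_ug=float(row["ee_dose_ug"]),
                bmi_group=row["bmi_group"],
                inducer=row["inducer"],
                cavg_ng_ml=float(row["cavg_ng_ml"]),
                gcv_percent=float(row["gcv_percent"]),
            ))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    _collect(errors, path)
    return records


def read_scenarios(path: str | Path) -> list[tuple[Scenario, bool]]:
    df = _read_table(path, SCENARIO_COLUMNS)
    out: list[tuple[Scenario, bool]] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            is_ref = row["is_reference"].strip().lower()
            if is_ref not in ("true", "false", "0", "1"):
                raise ValueError(f"is_reference must be boolean, got {row['is_reference']!r}")
            out.append((Scenario(
                drug_id=row["drug_id"],
                dose_ug=float(row["dose_ug"]),
                ee_dose_ug=float(row["ee_dose_ug"]),
                bmi_group=row["bmi_group"],
                inducer=row["inducer"],
                n_virtual=int(row["n_virtual"]),
                seed=int(row["seed"]),
            ), is_ref in ("true", "1")))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    _collect(errors, path)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output (stable column order, 12-sig-digit floats)."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def log_stage(stage: str, seeds: dict | None = None, **params) -> None:
    """One structured log line per pipeline stage."""
    log.info("stage=%s seeds=%s params=%s", stage, seeds or {}, params)
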