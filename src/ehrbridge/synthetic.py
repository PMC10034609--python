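"""Deterministic synthetic hospital source dataset.

Emulates a cohort of emergency-room and hospitalized patients over a fixed
inclusion window (2020-02-17 to 2022-02-15 by default) as one CSV per
source entity — patients, episodes, diagnoses, prescriptions, drug
administrations, cumulative doses, unit movements, clinical observations,
laboratory observations, procedures and limitation-of-life-sustaining-
treatment records — with referentially consistent keys and local codes
drawn from the packaged toy terminology. Event counts are Poisson per
episode and event times uniform within the episode span: distributional
realism is irrelevant to the transformation contract being tested.

The first patient's first episode always carries one diagnosis with the
local glaucoma code (DX011 → ICD-10-CM H40.9), so the worked example is
reproducible on every generated dataset. Same seed → byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

SOURCE_NAME = "HIS-SYNTH"

_DX_CODES = [f"DX{i:03d}" for i in range(1, 51)] + ["DX900", "DX901"]  # 2 unmapped legacy
_DRUG_CODES = [f"DRUG{i:02d}" for i in range(1, 13)]
_LAB_CODES = [f"LAB{i:02d}" for i in range(1, 21)]
_OBS_CODES = [f"OBS{i:02d}" for i in range(1, 11)]
_PROC_CODES = [f"PROC{i:02d}" for i in range(1, 6)]
_LLST_CODES = [f"LLST{i:02d}" for i in range(1, 4)]
_UNIT_CODES = [f"UNIT{i:02d}" for i in range(1, 9)]

GLAUCOMA_LOCAL_CODE = "DX011"


class GeneratorConfig(BaseModel):
    """Cohort size, per-episode event rates and the inclusion window."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int = 0
    n_patients: int = Field(default=40, ge=1)
    episodes_per_patient: float = Field(default=1.8, ge=0)
    diagnoses_per_episode: float = Field(default=2.5, ge=0)
    prescriptions_per_episode: float = Field(default=3.0, ge=0)
    administrations_per_episode: float = Field(default=5.0, ge=0)
    movements_per_episode: float = Field(default=1.5, ge=0)
    clinical_obs_per_episode: float = Field(default=6.0, ge=0)
    lab_obs_per_episode: float = Field(default=8.0, ge=0)
    procedures_per_episode: float = Field(default=0.8, ge=0)
    llst_probability: float = Field(default=0.08, ge=0, le=1)
    death_probability: float = Field(default=0.08, ge=0, le=1)
    device_procedure_probability: float = Field(default=0.25, ge=0, le=1)
    window_start: str = "2020-02-17"
    window_end: str = "2022-02-15"

    @model_validator(mode="after")
    def _window(self) -> "GeneratorConfig":
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        return self


@dataclass
class SourceDataset:
    tables: Dict[str, pd.DataFrame]
    manifest: Dict

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tables

    def keys(self):
        return self.tables.keys()


def _fmt(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%d %H:%M:%S")


def _uniform_dt(rng: np.random.Generator, start: datetime, end: datetime) -> datetime:
    span = max((end - start).total_seconds(), 1.0)
    return start + timedelta(seconds=float(rng.uniform(0, span)))


def generate(
    config: Optional[GeneratorConfig] = None, out_dir: Optional[Path | str] = None
) -> SourceDataset:
    """Generate the source dataset; optionally write CSVs + manifest JSON."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    window_start = datetime.fromisoformat(config.window_start)
    window_end = datetime.fromisoformat(config.window_end)

    patients: List[Dict] = []
    episodes: List[Dict] = []
    diagnoses: List[Dict] = []
    prescriptions: List[Dict] = []
    administrations: List[Dict] = []
    cumulative: List[Dict] = []
    movements: List[Dict] = []
    clinical_obs: List[Dict] = []
    lab_obs: List[Dict] = []
    procedures: List[Dict] = []
    llst_rows: List[Dict] = []

    counters = {k: 0 for k in ["ep", "dx", "rx", "adm", "cum", "mov", "obs", "lab", "proc", "llst"]}

    def next_id(kind: str, prefix: str, width: int = 6) -> str:
        counters[kind] += 1
        return f"{prefix}{counters[kind]:0{width}d}"

    for i in range(config.n_patients):
        patient_id = f"PAT{i + 1:05d}"
        birth = _uniform_dt(
            rng, datetime(1930, 1, 1), datetime(2004, 12, 31)
        ).replace(hour=0, minute=0, second=0)
        sex = "M" if rng.random() < 0.5 else "F"
        patients.append(
            {
                "patient_id": patient_id,
                "birth_date": birth.strftime("%Y-%m-%d"),
                "sex": sex,
                "source": SOURCE_NAME,
            }
        )
        n_episodes = max(1, int(rng.poisson(config.episodes_per_patient)))
        admissions = sorted(
            _uniform_dt(rng, window_start, window_end - timedelta(days=30))
            for _ in range(n_episodes)
        )
        dies = rng.random() < config.death_probability
        for j, admission in enumerate(admissions):
            episode_id = next_id("ep", "EP")
            stay_days = float(rng.exponential(5.0)) + 0.25
            discharge = admission + timedelta(days=stay_days)
            is_last = j == n_episodes - 1
            discharge_type = "DEATH" if (dies and is_last) else (
                "TRANSFER" if rng.random() < 0.1 else "HOME"
            )
            episodes.append(
                {
                    "episode_id": episode_id,
                    "patient_id": patient_id,
                    "episode_type": "ER" if rng.random() < 0.4 else "HOSP",
                    "admission_datetime": _fmt(admission),
                    "discharge_datetime": _fmt(discharge),
                    "discharge_type": discharge_type,
                    "source": SOURCE_NAME,
                }
            )

            def event_time() -> str:
                return _fmt(_uniform_dt(rng, admission, discharge))

            n_dx = int(rng.poisson(config.diagnoses_per_episode))
            forced_glaucoma = i == 0 and j == 0
            for k in range(n_dx + (1 if forced_glaucoma else 0)):
                code = (
                    GLAUCOMA_LOCAL_CODE
                    if forced_glaucoma and k == 0
                    else _DX_CODES[int(rng.integers(len(_DX_CODES)))]
                )
                diagnoses.append(
                    {
                        "diagnosis_id": next_id("dx", "DXREC"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_dx_code": code,
                        "recorded_datetime": event_time(),
                        "source": SOURCE_NAME,
                    }
                )
            for _ in range(int(rng.poisson(config.prescriptions_per_episode))):
                prescriptions.append(
                    {
                        "prescription_id": next_id("rx", "RX"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_drug_code": _DRUG_CODES[int(rng.integers(len(_DRUG_CODES)))],
                        "prescribed_datetime": event_time(),
                        "dose_value": str(round(float(rng.uniform(1, 500)), 1)),
                        "dose_unit": "mg",
                        "frequency": ["q4h", "q8h", "q12h", "q24h"][int(rng.integers(4))],
                        "source": SOURCE_NAME,
                    }
                )
            episode_drugs: Dict[str, float] = {}
            for _ in range(int(rng.poisson(config.administrations_per_episode))):
                drug = _DRUG_CODES[int(rng.integers(len(_DRUG_CODES)))]
                dose = round(float(rng.uniform(1, 250)), 1)
                episode_drugs[drug] = episode_drugs.get(drug, 0.0) + dose
                administrations.append(
                    {
                        "administration_id": next_id("adm", "ADM"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_drug_code": drug,
                        "administered_datetime": event_time(),
                        "dose_value": str(dose),
                        "dose_unit": "mg",
                        "route": ["oral", "iv", "subcutaneous"][int(rng.integers(3))],
                        "source": SOURCE_NAME,
                    }
                )
            for drug, total in sorted(episode_drugs.items()):
                cumulative.append(
                    {
                        "cumulative_dose_id": next_id("cum", "CUM"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_drug_code": drug,
                        "period_start": _fmt(admission),
                        "period_end": _fmt(discharge),
                        "total_dose_value": str(round(total, 1)),
                        "dose_unit": "mg",
                        "source": SOURCE_NAME,
                    }
                )
            for _ in range(max(1, int(rng.poisson(config.movements_per_episode)))):
                start = _uniform_dt(rng, admission, discharge)
                movements.append(
                    {
                        "movement_id": next_id("mov", "MOV"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "unit_code": _UNIT_CODES[int(rng.integers(len(_UNIT_CODES)))],
                        "start_datetime": _fmt(start),
                        "end_datetime": _fmt(_uniform_dt(rng, start, discharge)),
                        "source": SOURCE_NAME,
                    }
                )
            for _ in range(int(rng.poisson(config.clinical_obs_per_episode))):
                clinical_obs.append(
                    {
                        "observation_id": next_id("obs", "OBSREC"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_obs_code": _OBS_CODES[int(rng.integers(len(_OBS_CODES)))],
                        "observed_datetime": event_time(),
                        "value": str(round(float(rng.uniform(30, 200)), 1)),
                        "unit": "1",
                        "source": SOURCE_NAME,
                    }
                )
            for _ in range(int(rng.poisson(config.lab_obs_per_episode))):
                lab_obs.append(
                    {
                        "lab_observation_id": next_id("lab", "LABREC"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_test_code": _LAB_CODES[int(rng.integers(len(_LAB_CODES)))],
                        "observed_datetime": event_time(),
                        "value": str(round(float(rng.uniform(0.1, 400)), 2)),
                        "unit": "mg/dL",
                        "source": SOURCE_NAME,
                    }
                )
            for _ in range(int(rng.poisson(config.procedures_per_episode))):
                procedures.append(
                    {
                        "procedure_id": next_id("proc", "PROCREC"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_procedure_code": _PROC_CODES[int(rng.integers(len(_PROC_CODES)))],
                        "procedure_datetime": event_time(),
                        "device_flag": "1"
                        if rng.random() < config.device_procedure_probability
                        else "0",
                        "source": SOURCE_NAME,
                    }
                )
            if rng.random() < config.llst_probability:
                llst_rows.append(
                    {
                        "llst_id": next_id("llst", "LLSTREC"),
                        "episode_id": episode_id,
                        "patient_id": patient_id,
                        "local_llst_code": _LLST_CODES[int(rng.integers(len(_LLST_CODES)))],
                        "recorded_datetime": event_time(),
                        "source": SOURCE_NAME,
                    }
                )

    tables = {
        "patients": pd.DataFrame(patients),
        "episodes": pd.DataFrame(episodes),
        "diagnoses": pd.DataFrame(diagnoses),
        "prescriptions": pd.DataFrame(prescriptions),
        "administrations": pd.DataFrame(administrations),
        "cumulative_doses": pd.DataFrame(cumulative),
        "movements": pd.DataFrame(movements),
        "clinical_observations": pd.DataFrame(clinical_obs),
        "lab_observations": pd.DataFrame(lab_obs),
        "procedures": pd.DataFrame(procedures),
        "llst": pd.DataFrame(llst_rows),
    }
    _COLUMNS = {
        "diagnoses": ["diagnosis_id", "episode_id", "patient_id", "local_dx_code", "recorded_datetime", "source"],
        "prescriptions": ["prescription_id", "episode_id", "patient_id", "local_drug_code", "prescribed_datetime", "dose_value", "dose_unit", "frequency", "source"],
        "administrations": ["administration_id", "episode_id", "patient_id", "local_drug_code", "administered_datetime", "dose_value", "dose_unit", "route", "source"],
        "cumulative_doses": ["cumulative_dose_id", "episode_id", "patient_id", "local_drug_code", "period_start", "period_end", "total_dose_value", "dose_unit", "source"],
        "movements": ["movement_id", "episode_id", "patient_id", "unit_code", "start_datetime", "end_datetime", "source"],
        "clinical_observations": ["observation_id", "episode_id", "patient_id", "local_obs_code", "observed_datetime", "value", "unit", "source"],
        "lab_observations": ["lab_observation_id", "episode_id", "patient_id", "local_test_code", "observed_datetime", "value", "unit", "source"],
        "llst": ["llst_id", "episode_id", "patient_id", "local_llst_code", "recorded_datetime", "source"],
        "procedures": ["procedure_id", "episode_id", "patient_id", "local_procedure_code", "procedure_datetime", "device_flag", "source"],
    }
    for name, cols in _COLUMNS.items():
        if tables[name].empty:
            tables[name] = pd.DataFrame(columns=cols)

    manifest = {
        "seed": config.seed,
        "counts": {name: int(len(df)) for name, df in tables.items()},
        "window": [config.window_start, config.window_end],
    }
    dataset = SourceDataset(tables=tables, manifest=manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return dataset


def load_source(directory: Path | str) -> SourceDataset:
    """Read a generated source dataset back from CSV files."""
    directory = Path(directory)
    tables = {
        p.stem: pd.read_csv(p, dtype=str, keep_default_na=False)
        for p in sorted(directory.glob("*.csv"))
    }
    manifest_path = directory / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text(encoding="utf-8"))
        if manifest_path.exists()
        else {}
    )
    return SourceDataset(tables=tables, manifest=manifest)
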