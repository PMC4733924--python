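"""Plain-text persistence: cohorts as CSV, cohort specs as YAML/JSON.

Claims are stored long-format (one row per claim event), patients and
outcomes one row each; a cohort directory holds ``patients.csv``,
``claims.csv`` and ``outcomes.csv``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .synthetic_claims import CohortSpec
from .types import (
    Category,
    ClaimEvent,
    PatientRecord,
    ReferenceOutcome,
    Sex,
    Site,
    Stage,
    TumorType,
)


def claims_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "date": e.date,
            "domain": e.domain.value,
            "category": e.category.value,
            "site": e.site.value,
            "agent_id": e.agent_id or "",
        }
        for p in patients
        for e in p.events
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "domain", "category", "site", "agent_id"]
    )


def patients_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "tumor_type": p.tumor_type.value,
                "age_at_index": p.age_at_index,
                "sex": p.sex.value,
                "stage_at_dx": p.stage_at_dx.value,
                "index_date": p.index_date,
                "enrollment_start": p.enrollment_start,
                "enrollment_end": p.enrollment_end,
            }
            for p in patients
        ]
    )


def outcomes_frame(outcomes: Sequence[ReferenceOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "progressed": int(o.progressed),
                "progression_date": "" if o.progression_date is None else o.progression_date,
            }
            for o in outcomes
        ]
    )


def write_cohort(
    out_dir: str | Path,
    patients: Sequence[PatientRecord],
    outcomes: Sequence[ReferenceOutcome],
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients_frame(patients).to_csv(out / "patients.csv", index=False)
    claims_frame(patients).to_csv(out / "claims.csv", index=False)
    outcomes_frame(outcomes).to_csv(out / "outcomes.csv", index=False)
    return out


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[PatientRecord], list[ReferenceOutcome]]:
    src = Path(in_dir)
    pf = pd.read_csv(src / "patients.csv")
    cf = pd.read_csv(src / "claims.csv", keep_default_na=False)
    of = pd.read_csv(src / "outcomes.csv", keep_default_na=False)

    events_by_pid: dict[str, list[ClaimEvent]] = {}
    for row in cf.itertuples(index=False):
        events_by_pid.setdefault(str(row.patient_id), []).append(
            ClaimEvent(
                patient_id=str(row.patient_id),
                date=int(row.date),
                category=Category(row.category),
                site=Site(row.site),
                agent_id=str(row.agent_id) or None,
            )
        )
    patients = [
        PatientRecord(
            patient_id=str(row.patient_id),
            tumor_type=TumorType(row.tumor_type),
            age_at_index=float(row.age_at_index),
            sex=Sex(row.sex),
            stage_at_dx=Stage(row.stage_at_dx),
            index_date=int(row.index_date),
            enrollment_start=int(row.enrollment_start),
            enrollment_end=int(row.enrollment_end),
            events=events_by_pid.get(str(row.patient_id), []),
        )
        for row in pf.itertuples(index=False)
    ]
    outcomes = [
        ReferenceOutcome(
            patient_id=str(row.patient_id),
            progressed=bool(int(row.progressed)),
            progression_date=None if row.progression_date == "" else int(row.progression_date),
        )
        for row in of.itertuples(index=False)
    ]
    return patients, outcomes


def save_spec(spec: CohortSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_spec(path: str | Path) -> CohortSpec:
    return CohortSpec.from_dict(yaml.safe_load(Path(path).read_text()))
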