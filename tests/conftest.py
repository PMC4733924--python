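from __future__ import annotations

import numpy as np
import pytest

from metaclaims.types import (
    Category,
    ClaimEvent,
    PatientRecord,
    ReferenceOutcome,
    Sex,
    Site,
    Stage,
    TumorType,
)


def make_patient(
    events=(),
    patient_id="p0",
    tumor_type=TumorType.BREAST,
    index_date=400,
    enrollment_start=100,
    enrollment_end=2000,
    age=60.0,
    sex=None,
    stage=Stage.II,
):
    """Hand-built patient with sensible defaults for window tests."""
    if sex is None:
        sex = Sex.F if tumor_type is TumorType.BREAST else Sex.M
    return PatientRecord(
        patient_id=patient_id,
        tumor_type=tumor_type,
        age_at_index=age,
        sex=sex,
        stage_at_dx=stage,
        index_date=index_date,
        enrollment_start=enrollment_start,
        enrollment_end=enrollment_end,
        events=list(events),
    )


def ev(pid, day, category, site=Site.NA, agent=None):
    return ClaimEvent(pid, day, category, site=site, agent_id=agent)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_event_stream(rng, pid, index_date, enrollment_end, n_events):
    """Random small claim stream covering all categories/sites."""
    from metaclaims.types import SITED_CATEGORIES

    cats = list(Category)
    events = []
    for _ in range(n_events):
        cat = cats[int(rng.integers(0, len(cats)))]
        day = int(rng.integers(index_date - 100, enrollment_end + 1))
        site = Site.NA
        if cat in SITED_CATEGORIES:
            site = Site.PRIMARY_SITE if rng.random() < 0.5 else Site.OTHER_SITE
        agent = f"ag{int(rng.integers(0, 3))}" if cat is Category.CHEMO_AGENT else None
        events.append(ClaimEvent(pid, day, cat, site=site, agent_id=agent))
    return events


def simple_outcome(pid, progressed=False, progression_date=None):
    return ReferenceOutcome(pid, progressed, progression_date)
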