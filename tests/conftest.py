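import numpy as np
import pytest

from wardtriage.context import AlarmCandidate, ClinicalPriority, NurseState, ResidentProfile
from wardtriage.motion import CalibrationSpec, KeypointFrame, Role
from wardtriage.simulate import ScenarioConfig, generate_scenario


@pytest.fixture
def calib():
    return CalibrationSpec(frame_rate=30.0, scale=0.01)


def make_frame(
    keypoints,
    frame_index=0,
    timestamp=0.0,
    person_id="p1",
    role=Role.RESIDENT,
    visibility=None,
    bbox=None,
):
    kpts = np.asarray(keypoints, dtype=float)
    if bbox is None:
        bbox = (
            float(kpts[:, 0].min()),
            float(kpts[:, 1].min()),
            float(kpts[:, 0].max()),
            float(kpts[:, 1].max()),
        )
    return KeypointFrame(
        frame_index=frame_index,
        timestamp=timestamp,
        person_id=person_id,
        role=role,
        keypoints=kpts,
        visibility=visibility,
        bbox=bbox,
    )


def profile_for(clinical: ClinicalPriority, resident_id="R01") -> ResidentProfile:
    """A resident profile that maps to the requested priority class."""
    if clinical is ClinicalPriority.LOW:
        return ResidentProfile(resident_id, care_level=5, assistance=(5, 5, 5, 5, 5))
    if clinical is ClinicalPriority.MID:
        return ResidentProfile(resident_id, care_level=1, assistance=(1, 1, 1, 1, 1))
    return ResidentProfile(resident_id, care_level=3, assistance=(3, 3, 4, 3, 3))


def make_alarm(
    urgency=0.5,
    clinical=ClinicalPriority.HIGH,
    workload=0.5,
    distances=None,
    timestamp=0.0,
    alarm_id="A0",
):
    return AlarmCandidate(
        timestamp=timestamp,
        nurse_speed=1.2,
        distances=dict(distances or {"N1": 1.0}),
        urgency=urgency,
        clinical=clinical,
        workload=workload,
        profile=profile_for(ClinicalPriority(clinical)),
        alarm_id=alarm_id,
    )


def make_roster(n=2, busy=()):
    return [
        NurseState(nurse_id=f"N{i + 1}", position=(100.0 * i, 0.0), busy=(f"N{i + 1}" in busy))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_session():
    """A short, fully deterministic ward session shared by structural tests."""
    cfg = ScenarioConfig.noiseless(
        seed=7,
        session_minutes=6.0,
        tier_counts={"high": 2, "medium": 2, "low": 4},
        n_rooms=2,
        n_nurses=3,
        n_stationed=1,
        event_rate={"high": 10.0, "medium": 20.0, "low": 30.0},
    )
    return generate_scenario(cfg)
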