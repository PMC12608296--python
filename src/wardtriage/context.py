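"""Five-part alarm context: temporal, spatial, urgency, clinical, resource.

Every detected anomaly becomes an :class:`AlarmCandidate` tuple
``(t, x, u, c, r)``:

* ``t`` — event timestamp plus the nominal nurse walking speed that
  governs reachability,
* ``x`` — per-nurse centroid distances in metres,
* ``u`` — urgency in [0, 1], a convex combination of squashed velocity,
  squashed acceleration, a risky-activity indicator and a squashed count
  of recent abnormal-behaviour flags (weights gamma, summing to 1;
  defaults 0.2 / 0.2 / 0.25 / 0.35 — recurrence weighs most),
* ``c`` — clinical priority (high / mid / low) from the resident's care
  level CL (1–5) and per-activity assistance levels AL (1–5 over meals,
  bath, excretion, movement, dress-up),
* ``r`` — ward workload: the busy fraction of the on-duty roster.

The clinical mapping is deliberately non-monotone: fully dependent
residents (CL 4–5, AL 5) map to *low* alert priority because a stationed
attendant is already beside them, fully independent residents (CL 1,
AL 1) to *mid*, and the mobile-but-impaired band in between — the real
fall-risk population — to *high*.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .anomaly import ActivityLabel, AnomalyEvent
from .motion import CalibrationSpec, bbox_centroid

__all__ = [
    "ACTIVITIES",
    "ClinicalPriority",
    "ResidentProfile",
    "NurseState",
    "UrgencyWeights",
    "SaturatingNormalizer",
    "AlarmCandidate",
    "DEFAULT_RISKY_ACTIVITIES",
    "urgency_score",
    "clinical_priority",
    "nurse_workload",
    "assemble_alarm",
]

ACTIVITIES = ("meals", "bath", "excretion", "movement", "dressup")

DEFAULT_RISKY_ACTIVITIES = frozenset(
    {ActivityLabel.STAND_UP_ATTEMPT, ActivityLabel.UNSTABLE_POSTURE}
)


class ClinicalPriority(str, Enum):
    HIGH = "high"
    MID = "mid"
    LOW = "low"


@dataclass
class ResidentProfile:
    """Care record for one resident.

    ``assistance`` holds the five AL scores in :data:`ACTIVITIES` order
    (1 = independent … 5 = full assistance). ``recent_flags`` counts
    recent abnormal-behaviour detections; ``baseline_speed`` (m/s) scales
    the urgency squashing for this resident.
    """

    resident_id: str
    care_level: int
    assistance: tuple[int, int, int, int, int]
    recent_flags: int = 0
    baseline_speed: float = 0.05
    room: str | None = None

    def __post_init__(self) -> None:
        if self.care_level not in range(1, 6):
            raise ValueError(f"care_level must be in 1..5, got {self.care_level}")
        self.assistance = tuple(int(a) for a in self.assistance)  # type: ignore[assignment]
        if len(self.assistance) != 5 or any(a not in range(1, 6) for a in self.assistance):
            raise ValueError(f"assistance must be five integers in 1..5, got {self.assistance}")
        if self.recent_flags < 0:
            raise ValueError("recent_flags must be >= 0")


@dataclass
class NurseState:
    """Live state of one on-duty nurse (position in pixels)."""

    nurse_id: str
    position: tuple[float, float] = (0.0, 0.0)
    speed: float = 0.0
    busy: bool = False
    workload_index: int = 0
    available: bool = True
    room: str | None = None
    busy_until: float = -np.inf  # transient engine lock, not persisted

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.workload_index < 0:
            raise ValueError("workload_index must be >= 0")


@dataclass(frozen=True)
class UrgencyWeights:
    """Simplex weights (gamma) of the four urgency terms."""

    velocity: float = 0.2
    acceleration: float = 0.2
    activity: float = 0.25
    flags: float = 0.35

    def __post_init__(self) -> None:
        vals = (self.velocity, self.acceleration, self.activity, self.flags)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError(f"urgency weights must each lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"urgency weights must sum to 1, got {sum(vals)}")


@dataclass(frozen=True)
class SaturatingNormalizer:
    """Parameter-free squashing of urgency inputs onto [0, 1].

    Velocity and acceleration use the bounded ratio ``v / (v + v0)``
    against a per-resident baseline (0.5 exactly at baseline, saturating
    towards 1); flag counts saturate linearly at ``flag_cap``.
    """

    velocity_baseline: float = 0.05  # m/s
    acceleration_baseline: float = 0.05  # m/s^2
    flag_cap: int = 3

    def velocity(self, v: float) -> float:
        v = max(0.0, v)
        return v / (v + self.velocity_baseline) if v > 0 else 0.0

    def acceleration(self, a: float) -> float:
        a = abs(a)
        return a / (a + self.acceleration_baseline) if a > 0 else 0.0

    def flags(self, count: int) -> float:
        return min(count, self.flag_cap) / self.flag_cap


@dataclass
class AlarmCandidate:
    """The alarm tuple (t, x, u, c, r) plus provenance.

    ``distances`` is the per-nurse map in metres. ``feature_vector``
    concatenates the five contexts into a flat array for downstream
    decisions (distances in sorted nurse-id order, clinical priority
    encoded high=2 / mid=1 / low=0).
    """

    timestamp: float
    nurse_speed: float
    distances: dict[str, float]
    urgency: float
    clinical: ClinicalPriority
    workload: float
    profile: ResidentProfile
    source_event: AnomalyEvent | None = None
    alarm_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.urgency <= 1.0:
            raise ValueError(f"urgency must lie in [0, 1], got {self.urgency}")
        if not 0.0 <= self.workload <= 1.0:
            raise ValueError(f"workload must lie in [0, 1], got {self.workload}")
        if any(d < 0 for d in self.distances.values()):
            raise ValueError("distances must be >= 0")
        self.clinical = ClinicalPriority(self.clinical)

    @property
    def min_distance(self) -> float:
        """Nearest-nurse distance in metres (inf on an empty map)."""
        return min(self.distances.values(), default=float("inf"))

    @property
    def feature_vector(self) -> np.ndarray:
        enc = {ClinicalPriority.HIGH: 2.0, ClinicalPriority.MID: 1.0, ClinicalPriority.LOW: 0.0}
        dists = [self.distances[k] for k in sorted(self.distances)]
        return np.array(
            [self.timestamp, self.nurse_speed, *dists, self.urgency, enc[self.clinical], self.workload]
        )


def urgency_score(
    velocity: float,
    acceleration: float,
    activity: ActivityLabel | str,
    flag_count: int,
    weights: UrgencyWeights | None = None,
    normalizer: SaturatingNormalizer | None = None,
    risky: frozenset = DEFAULT_RISKY_ACTIVITIES,
) -> float:
    """Urgency u in [0, 1]: how quickly the event needs a nurse.

    ``g1*sig(v) + g2*sig(a) + g3*[activity risky] + g4*sig_f(flags)``,
    clamped to [0, 1]. Monotone non-decreasing in each input.
    """
    if flag_count < 0:
        raise ValueError(f"flag_count must be >= 0, got {flag_count}")
    w = weights or UrgencyWeights()
    nz = normalizer or SaturatingNormalizer()
    act = ActivityLabel(activity)
    u = (
        w.velocity * nz.velocity(velocity)
        + w.acceleration * nz.acceleration(acceleration)
        + w.activity * (1.0 if act in risky else 0.0)
        + w.flags * nz.flags(flag_count)
    )
    return float(min(1.0, max(0.0, u)))


def clinical_priority(profile: ResidentProfile, aggregation: str = "max") -> ClinicalPriority:
    """Map a resident's CL and aggregated AL to an alert priority class.

    * low  — fully dependent: CL in {4, 5} and aggregated AL = 5 (a
      stationed attendant is already present);
    * mid  — fully independent: CL = 1 and aggregated AL = 1;
    * high — everything in between (mobile but impaired).

    The five per-activity AL scores collapse to a scalar by worst-case
    ``max`` (default) or ``mean``. Total on the whole CL x AL grid.
    """
    if aggregation == "max":
        al = max(profile.assistance)
    elif aggregation == "mean":
        al = float(np.mean(profile.assistance))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if profile.care_level in (4, 5) and al == 5:
        return ClinicalPriority.LOW
    if profile.care_level == 1 and al == 1:
        return ClinicalPriority.MID
    return ClinicalPriority.HIGH


def nurse_workload(roster: Sequence[NurseState]) -> float:
    """Busy fraction of the on-duty roster: (sum of busy flags) / |roster|."""
    if not roster:
        raise ValueError("nurse_workload needs a non-empty on-duty roster")
    return float(np.mean([1.0 if n.busy else 0.0 for n in roster]))


def assemble_alarm(
    event: AnomalyEvent,
    profiles: Mapping[str, ResidentProfile],
    roster: Sequence[NurseState],
    calib: CalibrationSpec,
    resident_bbox: Sequence[float],
    velocity: float = 0.0,
    acceleration: float = 0.0,
    nurse_speed: float = 1.2,
    weights: UrgencyWeights | None = None,
    normalizer: SaturatingNormalizer | None = None,
    alarm_id: str = "",
) -> AlarmCandidate:
    """Fill all five contexts of the alarm tuple for one detected event.

    Distances use nurse positions against the resident's bounding-box
    centroid (pixels x scale -> metres). ``velocity`` / ``acceleration``
    are the resident's body speed and its first difference around the
    event. Raises on an unknown resident or empty roster.
    """
    if event.person_id not in profiles:
        raise KeyError(f"no profile for resident {event.person_id!r}")
    if not roster:
        raise ValueError("assemble_alarm needs a non-empty roster")
    profile = profiles[event.person_id]
    nz = normalizer or SaturatingNormalizer(velocity_baseline=max(profile.baseline_speed, 1e-6))
    cx, cy = bbox_centroid(resident_bbox)
    distances = {
        n.nurse_id: float(np.hypot(n.position[0] - cx, n.position[1] - cy)) * calib.scale
        for n in roster
    }
    u = urgency_score(
        velocity, acceleration, event.activity_label, profile.recent_flags, weights, nz
    )
    return AlarmCandidate(
        timestamp=event.timestamp,
        nurse_speed=nurse_speed,
        distances=distances,
        urgency=u,
        clinical=clinical_priority(profile),
        workload=nurse_workload(roster),
        profile=profile,
        source_event=event,
        alarm_id=alarm_id or f"{event.person_id}@{event.timestamp:.3f}",
    )
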