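"""Seeded synthetic ward sessions with ground-truth labels.

Emulates a long-term-care lunchtime setting: 28 residents in three care
tiers (6 high / 8 medium / 14 low) seated across 3 dining rooms, 4
nurses, sessions of 30-60 minutes. Residents are stick-figure skeletons
(17 keypoints, COCO layout) seated at fixed places; stand-up attempts
are injected as scripted vertical keypoint excursions (cosine-eased
rise, hold, sit back down) at tier-dependent Poisson rates. Stationed
nurses sit beside the fully dependent residents and are permanently
busy attending them; the remaining nurses roam the rooms on piecewise
constant-velocity waypoint tracks. Keypoint jitter and Bernoulli
acknowledgment failures are the two noise sources; a scenario with both
off is the package's "noiseless" condition.

Everything is reproducible: one integer seed fixes the session length,
seats, event times, trajectories, jitter and acknowledgment behaviour.
No attempt is made at photorealism — the streams exist to exercise the
detection and triage logic, not to look like video.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
import numpy as np

from .context import ACTIVITIES, ClinicalPriority, NurseState, ResidentProfile, clinical_priority
from .motion import CalibrationSpec, PersonTrack, Role
from .triage import TriageParams

__all__ = [
    "ScenarioConfig",
    "TruthEvent",
    "SimulatedSession",
    "SeededAckModel",
    "generate_scenario",
    "ground_truth_labels",
]

TIERS = ("high", "medium", "low")

# Stick-model offsets from the hip centre, metres, image-y down.
# COCO-17: nose, eyes, ears, shoulders, elbows, wrists, hips, knees, ankles.
_SEATED_OFFSETS = np.array(
    [
        (0.00, -0.70),
        (-0.03, -0.72), (0.03, -0.72),
        (-0.07, -0.70), (0.07, -0.70),
        (-0.18, -0.50), (0.18, -0.50),
        (-0.25, -0.30), (0.25, -0.30),
        (-0.28, -0.10), (0.28, -0.10),
        (-0.10, 0.00), (0.10, 0.00),
        (-0.12, 0.25), (0.12, 0.25),
        (-0.13, 0.45), (0.13, 0.45),
    ]
)
# Per-keypoint vertical shift (metres, negative = up) at full standing.
_STAND_DELTA = np.zeros_like(_SEATED_OFFSETS)
_STAND_DELTA[:13, 1] = -1.0  # upper body rises by the full rise
_STAND_DELTA[13:15, 1] = -0.25 / 0.45  # knees straighten
# ankles stay planted


@dataclass
class ScenarioConfig:
    """Study conditions of one simulated session."""

    n_rooms: int = 3
    tier_counts: dict[str, int] = field(
        default_factory=lambda: {"high": 6, "medium": 8, "low": 14}
    )
    n_nurses: int = 4
    n_stationed: int = 2
    session_minutes: float | None = None  # None: drawn uniformly from 30-60
    frame_rate: float = 5.0
    scale: float = 0.01  # metres per pixel
    room_px: tuple[int, int] = (640, 480)
    event_rate: dict[str, float] = field(
        default_factory=lambda: {"high": 4.0, "medium": 8.0, "low": 12.0}
    )  # stand-up attempts per resident-hour
    event_duration_s: float = 3.0
    event_hold_s: float = 2.0
    rise_m: float = 0.45  # hip rise of a full stand-up
    min_event_gap_s: float = 30.0
    noise_sigma: float = 1.0  # keypoint jitter, pixels
    p_ack: float = 0.9
    ack_latency_mean_s: float = 5.0
    nurse_speed: float = 1.2  # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stationed > self.n_nurses:
            raise ValueError(
                f"cannot station {self.n_stationed} nurses with a roster of {self.n_nurses}"
            )
        for name, v in (("n_rooms", self.n_rooms), ("n_nurses", self.n_nurses)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if any(c < 0 for c in self.tier_counts.values()):
            raise ValueError("tier counts must be >= 0")
        if not 0.0 <= self.p_ack <= 1.0:
            raise ValueError("p_ack must lie in [0, 1]")

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Clean condition: no keypoint jitter, no acknowledgment failures."""
        kw = dict(noise_sigma=0.0, p_ack=1.0, ack_latency_mean_s=0.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @property
    def calibration(self) -> CalibrationSpec:
        return CalibrationSpec(frame_rate=self.frame_rate, scale=self.scale)


@dataclass
class TruthEvent:
    timestamp: float
    resident_id: str
    kind: str = "stand_up_attempt"
    duration_s: float = 8.0  # rise + hold + sit back


@dataclass
class SimulatedSession:
    config: ScenarioConfig
    tracks: list[PersonTrack]
    truth_events: list[TruthEvent]
    profiles: dict[str, ResidentProfile]
    roster: list[NurseState]
    stationed_ids: tuple[str, ...]
    rooms: dict[str, str]  # person_id -> room name
    session_seconds: float
    metadata: dict

    @property
    def calibration(self) -> CalibrationSpec:
        return self.config.calibration

    def track(self, person_id: str) -> PersonTrack:
        for t in self.tracks:
            if t.person_id == person_id:
                return t
        raise KeyError(person_id)

    def frame_at(self, ts: float) -> int:
        n = len(self.tracks[0])
        return min(n - 1, max(0, int(round(ts * self.config.frame_rate))))


class SeededAckModel:
    """Bernoulli acknowledgment with exponential latency, fully seeded.

    The outcome for a (nurse, alarm) pair is a pure function of the
    session seed and the pair's identifiers, so replays and different
    strategies see identical acknowledgment behaviour.
    """

    def __init__(self, p_ack: float, latency_mean_s: float, seed: int):
        self.p_ack = p_ack
        self.latency_mean_s = latency_mean_s
        self.seed = seed

    def acknowledges(self, nurse_id: str, alarm) -> tuple[bool, float]:
        key = zlib.crc32(f"{nurse_id}|{alarm.alarm_id}".encode())
        rng = np.random.default_rng([self.seed % (2**31), key])
        acked = bool(rng.random() < self.p_ack)
        latency = float(rng.exponential(self.latency_mean_s)) if self.latency_mean_s > 0 else 0.0
        return acked, latency


def _make_profiles(config: ScenarioConfig, rng: np.random.Generator) -> dict[str, ResidentProfile]:
    """Tier-typical care records.

    High tier: fully dependent (CL 4-5, all AL 5). Medium: CL 3, partial
    assistance. Low: CL 1-2 with at least one "check"-level activity —
    care-certified residents are never literally fully independent, so
    the fully-independent (mid-priority) class does not arise in the
    default ward.
    """
    profiles: dict[str, ResidentProfile] = {}
    baseline = {"high": 0.01, "medium": 0.03, "low": 0.05}
    idx = 0
    for tier in TIERS:
        for k in range(config.tier_counts.get(tier, 0)):
            rid = f"R{idx + 1:02d}"
            if tier == "high":
                cl, al = 4 + (k % 2), (5, 5, 5, 5, 5)
            elif tier == "medium":
                cl = 3
                al = tuple(int(rng.integers(3, 5)) for _ in ACTIVITIES)
            else:
                cl = 1 + (k % 2)
                al = [int(rng.integers(1, 3)) for _ in ACTIVITIES]
                if max(al) < 2:
                    al[int(rng.integers(0, 5))] = 2
                al = tuple(al)
            profiles[rid] = ResidentProfile(
                resident_id=rid,
                care_level=cl,
                assistance=al,  # type: ignore[arg-type]
                baseline_speed=baseline[tier],
            )
            idx += 1
    return profiles


def _draw_event_times(
    rng: np.random.Generator, n: int, t0: float, t1: float, gap: float
) -> np.ndarray:
    """Up to ``n`` event onsets in [t0, t1] separated by >= gap."""
    for _ in range(200):
        times = np.sort(rng.uniform(t0, t1, size=n))
        if n < 2 or np.all(np.diff(times) >= gap):
            return times
    # extremely dense draw: keep a maximal gap-respecting subset
    times = np.sort(rng.uniform(t0, t1, size=n))
    kept = [times[0]] if n else []
    for t in times[1:]:
        if t - kept[-1] >= gap:
            kept.append(t)
    return np.array(kept)


def _event_phase(
    n_frames: int, frame_rate: float, events: np.ndarray, dur: float, hold: float
) -> np.ndarray:
    """Per-frame standing fraction in [0, 1] for a scripted excursion."""
    t = np.arange(n_frames) / frame_rate
    phase = np.zeros(n_frames)
    for ts in events:
        rise = (t >= ts) & (t < ts + dur)
        phase[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - ts) / dur))
        held = (t >= ts + dur) & (t < ts + dur + hold)
        phase[held] = 1.0
        fall = (t >= ts + dur + hold) & (t < ts + 2 * dur + hold)
        phase[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - ts - dur - hold) / dur))
    return phase


def _skeleton_track(
    person_id: str,
    role: Role,
    centers: np.ndarray,  # (n, 2) hip-centre positions, pixels
    phase: np.ndarray,  # (n,) standing fraction
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> PersonTrack:
    n = len(centers)
    s = config.scale
    base = _SEATED_OFFSETS / s  # px
    delta = _STAND_DELTA * config.rise_m / s  # px at full standing
    kpts = centers[:, None, :] + base[None, :, :] + phase[:, None, None] * delta[None, :, :]
    if config.noise_sigma > 0:
        kpts = kpts + rng.normal(0.0, config.noise_sigma, size=kpts.shape)
    pad = 5.0
    bbox = np.column_stack(
        [
            kpts[..., 0].min(axis=1) - pad,
            kpts[..., 1].min(axis=1) - pad,
            kpts[..., 0].max(axis=1) + pad,
            kpts[..., 1].max(axis=1) + pad,
        ]
    )
    return PersonTrack(
        person_id=person_id,
        role=role,
        frame_indices=np.arange(n),
        timestamps=np.arange(n) / config.frame_rate,
        keypoints=kpts,
        visibility=np.ones((n, len(base)), dtype=bool),
        bbox=bbox,
    )


def _roaming_path(
    n_frames: int, config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Waypoint walk at nominal nurse speed with pauses, across all rooms."""
    w, h = config.room_px
    speed_px = config.nurse_speed / config.scale / config.frame_rate  # px per frame
    margin = 60.0
    pos = np.array(
        [rng.uniform(margin, config.n_rooms * w - margin), rng.uniform(margin, h - margin)]
    )
    out = np.empty((n_frames, 2))
    i = 0
    while i < n_frames:
        target = np.array(
            [rng.uniform(margin, config.n_rooms * w - margin), rng.uniform(margin, h - margin)]
        )
        seg = target - pos
        dist = float(np.hypot(*seg))
        steps = max(1, int(np.ceil(dist / speed_px)))
        for k in range(1, steps + 1):
            if i >= n_frames:
                break
            out[i] = pos + seg * (k / steps)
            i += 1
        pos = target
        for _ in range(int(rng.uniform(2, 10) * config.frame_rate)):
            if i >= n_frames:
                break
            out[i] = pos
            i += 1
    return out


def generate_scenario(config: ScenarioConfig | None = None) -> SimulatedSession:
    """Build one fully reproducible session from the scenario seed."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    w, h = config.room_px

    minutes = (
        config.session_minutes
        if config.session_minutes is not None
        else float(rng.uniform(30.0, 60.0))
    )
    session_s = minutes * 60.0
    n_frames = int(round(session_s * config.frame_rate))

    profiles = _make_profiles(config, rng)
    tiers = {
        rid: ("high" if p.care_level >= 4 else "medium" if p.care_level == 3 else "low")
        for rid, p in profiles.items()
    }

    # seats: per-room grids, residents dealt round-robin per tier
    rooms: dict[str, str] = {}
    seats: dict[str, np.ndarray] = {}
    per_room_count = {r: 0 for r in range(config.n_rooms)}
    for j, rid in enumerate(profiles):
        room = j % config.n_rooms
        rooms[rid] = f"room{room + 1}"
        k = per_room_count[room]
        per_room_count[room] += 1
        col, row = k % 4, k // 4
        seats[rid] = np.array(
            [
                room * w + 120 + col * 130 + rng.uniform(-15, 15),
                120 + row * 110 + rng.uniform(-15, 15),
            ]
        )

    # truth events
    truth: list[TruthEvent] = []
    draws: dict[str, int] = {}
    hours = session_s / 3600.0
    dur_total = 2 * config.event_duration_s + config.event_hold_s
    for rid in profiles:
        rate = config.event_rate.get(tiers[rid], 0.0)
        n = int(rng.poisson(rate * hours))
        times = _draw_event_times(
            rng, n, 30.0, max(31.0, session_s - dur_total - 10.0), config.min_event_gap_s
        )
        draws[rid] = len(times)
        truth.extend(
            TruthEvent(timestamp=float(t), resident_id=rid, duration_s=dur_total) for t in times
        )
    truth.sort(key=lambda e: (e.timestamp, e.resident_id))

    # resident tracks
    tracks: list[PersonTrack] = []
    for rid in profiles:
        ev = np.array([e.timestamp for e in truth if e.resident_id == rid])
        phase = _event_phase(
            n_frames, config.frame_rate, ev, config.event_duration_s, config.event_hold_s
        )
        centers = np.broadcast_to(seats[rid], (n_frames, 2)).copy()
        tracks.append(_skeleton_track(rid, Role.RESIDENT, centers, phase, config, rng))

    # nurses: station beside fully dependent residents, rest roam
    high_ids = [rid for rid, t in tiers.items() if t == "high"]
    roster: list[NurseState] = []
    stationed: list[str] = []
    for j in range(config.n_nurses):
        nid = f"N{j + 1}"
        if j < config.n_stationed and high_ids:
            anchor = high_ids[j % len(high_ids)]
            pos = seats[anchor] + np.array([40.0, 0.0])
            centers = np.broadcast_to(pos, (n_frames, 2)).copy()
            roster.append(
                NurseState(
                    nurse_id=nid,
                    position=(float(pos[0]), float(pos[1])),
                    speed=0.0,
                    busy=True,
                    available=True,
                    room=rooms[anchor],
                )
            )
            stationed.append(nid)
        else:
            centers = _roaming_path(n_frames, config, rng)
            roster.append(
                NurseState(
                    nurse_id=nid,
                    position=(float(centers[0, 0]), float(centers[0, 1])),
                    speed=config.nurse_speed,
                    busy=False,
                    available=True,
                )
            )
        tracks.append(
            _skeleton_track(nid, Role.NURSE, centers, np.ones(n_frames), config, rng)
        )

    metadata = {
        "seed": config.seed,
        "session_minutes": minutes,
        "poisson_draws": draws,
        "n_events": len(truth),
        "config": {k: v for k, v in asdict(config).items()},
    }
    return SimulatedSession(
        config=config,
        tracks=tracks,
        truth_events=truth,
        profiles=profiles,
        roster=roster,
        stationed_ids=tuple(stationed),
        rooms=rooms,
        session_seconds=session_s,
        metadata=metadata,
    )


def ground_truth_labels(
    session: SimulatedSession, params: TriageParams | None = None
) -> list[str | None]:
    """Programmatic annotation: the nurse who *should* answer each event.

    None (the no-alert class) when the resident is fully dependent with a
    stationed attendant in the room, or when no free nurse can reach the
    resident within the acceptable reaching time; otherwise the nearest
    free nurse whose reach distance is within theta_x. A declared proxy
    for human annotation of staff interventions, not a claim of
    equivalence.
    """
    params = params or TriageParams(nurse_speed=session.config.nurse_speed)
    theta_x = params.theta_x
    labels: list[str | None] = []
    nurse_tracks = {t.person_id: t for t in session.tracks if t.role is Role.NURSE}
    res_tracks = {t.person_id: t for t in session.tracks if t.role is Role.RESIDENT}
    free_nurses = [n for n in session.roster if not n.busy]
    for ev in session.truth_events:
        profile = session.profiles[ev.resident_id]
        room = session.rooms[ev.resident_id]
        stationed_here = any(
            n.room == room for n in session.roster if n.nurse_id in session.stationed_ids
        )
        if clinical_priority(profile) is ClinicalPriority.LOW and stationed_here:
            labels.append(None)
            continue
        i = session.frame_at(ev.timestamp)
        cx, cy = res_tracks[ev.resident_id].centroid(i)
        best: tuple[float, str] | None = None
        for n in free_nurses:
            tr = nurse_tracks[n.nurse_id]
            nx, ny = tr.centroid(i)
            d = float(np.hypot(nx - cx, ny - cy)) * session.config.scale
            if d <= theta_x and (best is None or d < best[0]):
                best = (d, n.nurse_id)
        labels.append(best[1] if best else None)
    return labels
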