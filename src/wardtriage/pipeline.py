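"""End-to-end replay: detection -> context assembly -> triage.

Detection runs once per session (it is strategy-independent); the four
strategies then replay the identical alarm stream. Detected per-frame
flags are coalesced into episodes (one per excursion), matched to
ground-truth events by resident and time overlap, and each episode is
assembled into an alarm candidate using the nurse positions at its
onset frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .anomaly import AnomalyEvent, DetectionConfig, coalesce_events, detect_events
from .context import AlarmCandidate, NurseState, ResidentProfile, assemble_alarm
from .motion import CalibrationSpec, PersonTrack, Role, bbox_centroid
from .simulate import SeededAckModel, SimulatedSession
from .triage import AckProvider, PriorityBackend, Strategy, TriageParams, TriageResult, run_triage

__all__ = [
    "PipelineRun",
    "detect_session",
    "match_episodes",
    "alarms_from_tracks",
    "build_alarms",
    "run_session",
]

FLAG_LOOKBACK_S = 600.0  # window for the "recent abnormal flags" count
MATCH_SLACK_S = 2.0


@dataclass
class PipelineRun:
    """One strategy's replay over one session."""

    strategy: Strategy
    session: SimulatedSession
    episodes: list[AnomalyEvent]
    alarms: list[AlarmCandidate]
    result: TriageResult
    matches: list[int | None]  # per truth event: episode index or None
    spurious: list[int]  # episode indices with no truth event


def detect_session(
    session: SimulatedSession, config: DetectionConfig | None = None
) -> list[AnomalyEvent]:
    """Episode-level anomaly events for every resident in the session."""
    cfg = config or DetectionConfig()
    residents = [t for t in session.tracks if t.role is Role.RESIDENT]
    flags = detect_events(residents, cfg, frame_rate=session.config.frame_rate)
    return coalesce_events(flags, gap_s=cfg.episode_gap_s)


def match_episodes(
    session: SimulatedSession, episodes: Sequence[AnomalyEvent]
) -> tuple[list[int | None], list[int]]:
    """Greedy one-to-one matching of truth events to detected episodes.

    An episode matches a truth event of the same resident when its onset
    falls within the event span plus a small slack either side.
    """
    used: set[int] = set()
    matches: list[int | None] = []
    for ev in session.truth_events:
        hit = None
        for j, ep in enumerate(episodes):
            if j in used or ep.person_id != ev.resident_id:
                continue
            if ev.timestamp - MATCH_SLACK_S <= ep.timestamp <= ev.timestamp + ev.duration_s + MATCH_SLACK_S:
                hit = j
                break
        if hit is not None:
            used.add(hit)
        matches.append(hit)
    spurious = [j for j in range(len(episodes)) if j not in used]
    return matches, spurious


def _body_speed_series(track: PersonTrack, scale: float, frame_rate: float) -> np.ndarray:
    d = np.linalg.norm(np.diff(track.keypoints, axis=0), axis=2)  # (n-1, N)
    speed = np.concatenate([[0.0], d.mean(axis=1)]) * scale * frame_rate
    return speed


def alarms_from_tracks(
    tracks: Sequence[PersonTrack],
    profiles: dict[str, ResidentProfile],
    roster: Sequence[NurseState],
    calib: CalibrationSpec,
    episodes: Sequence[AnomalyEvent],
    params: TriageParams | None = None,
) -> list[AlarmCandidate]:
    """Assemble the (t, x, u, c, r) tuple for every detected episode.

    Nurse distances come from nurse bounding-box centroids at the
    episode's onset frame; the resident's velocity is the peak body
    speed within one second of onset and the acceleration its first
    difference; the recent-flag count tallies the resident's earlier
    episodes within the lookback window.
    """
    params = params or TriageParams()
    f = calib.frame_rate
    h = max(1, round(f))  # one second of frames
    nurse_tracks = {t.person_id: t for t in tracks if t.role is Role.NURSE}
    res_tracks = {t.person_id: t for t in tracks if t.role is Role.RESIDENT}
    speed_cache: dict[str, np.ndarray] = {}
    episode_times: dict[str, list[float]] = {}
    alarms: list[AlarmCandidate] = []
    for k, ep in enumerate(sorted(episodes, key=lambda e: (e.timestamp, e.person_id))):
        track = res_tracks[ep.person_id]
        if ep.person_id not in speed_cache:
            speed_cache[ep.person_id] = _body_speed_series(track, calib.scale, f)
        speed = speed_cache[ep.person_id]
        i = int(np.clip(np.searchsorted(track.timestamps, ep.timestamp), 0, len(track) - 1))
        j0, j1 = max(0, i - h), min(len(speed), i + h + 1)
        velocity = float(speed[j0:j1].max(initial=0.0))
        accel = (speed[i] - speed[j0]) / ((i - j0) / f) if i > j0 else 0.0
        prior = episode_times.setdefault(ep.person_id, [])
        flags = sum(1 for t in prior if ep.timestamp - t <= FLAG_LOOKBACK_S)
        prior.append(ep.timestamp)
        profile = replace(profiles[ep.person_id], recent_flags=flags)
        snapshot = [
            replace(
                n,
                position=bbox_centroid(nurse_tracks[n.nurse_id].bbox[min(i, len(nurse_tracks[n.nurse_id]) - 1)])
                if n.nurse_id in nurse_tracks
                else n.position,
                busy_until=-np.inf,
            )
            for n in roster
        ]
        alarms.append(
            assemble_alarm(
                ep,
                {profile.resident_id: profile},
                snapshot,
                calib,
                resident_bbox=track.bbox[i],
                velocity=velocity,
                acceleration=float(accel),
                nurse_speed=params.nurse_speed,
                alarm_id=f"E{k:04d}",
            )
        )
    return alarms


def build_alarms(
    session: SimulatedSession,
    episodes: Sequence[AnomalyEvent],
    params: TriageParams | None = None,
) -> list[AlarmCandidate]:
    """Session-level convenience wrapper around :func:`alarms_from_tracks`."""
    params = params or TriageParams(nurse_speed=session.config.nurse_speed)
    return alarms_from_tracks(
        session.tracks, session.profiles, session.roster, session.calibration, episodes, params
    )


def run_session(
    session: SimulatedSession,
    strategy: Strategy | str,
    params: TriageParams | None = None,
    detection: DetectionConfig | None = None,
    episodes: Sequence[AnomalyEvent] | None = None,
    alarms: Sequence[AlarmCandidate] | None = None,
    backend: PriorityBackend | None = None,
    ack: AckProvider | None = None,
) -> PipelineRun:
    """Replay one session under one strategy.

    Precomputed ``episodes`` / ``alarms`` can be passed so that a
    strategy comparison shares a single detection pass.
    """
    params = params or TriageParams(nurse_speed=session.config.nurse_speed)
    eps = list(episodes) if episodes is not None else detect_session(session, detection)
    alms = list(alarms) if alarms is not None else build_alarms(session, eps, params)
    if ack is None:
        cfg = session.config
        ack = SeededAckModel(cfg.p_ack, cfg.ack_latency_mean_s, cfg.seed)
    result = run_triage(alms, session.roster, params, strategy, backend=backend, ack=ack)
    matches, spurious = match_episodes(session, eps)
    return PipelineRun(
        strategy=Strategy(strategy),
        session=session,
        episodes=eps,
        alarms=alms,
        result=result,
        matches=matches,
        spurious=spurious,
    )
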