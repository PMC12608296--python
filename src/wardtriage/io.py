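"""File formats: JSON-lines streams and logs, CSV rosters.

Streams and decision logs are JSON-lines (append-friendly, one schema-
checked record per line); rosters are CSV (hand-editable). All writers
are deterministic — sorted keys, plain ``repr`` floats — so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .context import ACTIVITIES, NurseState, ResidentProfile
from .motion import KeypointFrame, PersonTrack, Role
from .simulate import SimulatedSession, TruthEvent
from .triage import TriageResult

__all__ = [
    "write_stream_jsonl",
    "read_stream_jsonl",
    "write_residents_csv",
    "read_residents_csv",
    "write_nurses_csv",
    "read_nurses_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_decisions_jsonl",
    "read_decisions_jsonl",
    "write_shadow_jsonl",
    "write_events_jsonl",
]


def _dump(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_stream_jsonl(tracks: Sequence[PersonTrack], path: str | Path) -> None:
    """One record per (frame, person): frame, ts, person_id, role, bbox, kpts."""
    path = Path(path)
    with path.open("w") as fh:
        order = np.argsort([(t.person_id) for t in tracks], kind="stable")
        n_frames = max(len(t) for t in tracks)
        for i in range(n_frames):
            for k in order:
                t = tracks[k]
                if i >= len(t):
                    continue
                kpts = [
                    [float(x), float(y), int(v)]
                    for (x, y), v in zip(t.keypoints[i], t.visibility[i])
                ]
                fh.write(
                    _dump(
                        {
                            "frame": int(t.frame_indices[i]),
                            "ts": float(t.timestamps[i]),
                            "person_id": t.person_id,
                            "role": t.role.value,
                            "bbox": [float(v) for v in t.bbox[i]],
                            "kpts": kpts,
                        }
                    )
                    + "\n"
                )


def read_stream_jsonl(path: str | Path) -> list[PersonTrack]:
    frames: dict[str, list[KeypointFrame]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            kpts = np.array([[p[0], p[1]] for p in rec["kpts"]], dtype=float)
            vis = np.array([bool(p[2]) for p in rec["kpts"]])
            frames.setdefault(rec["person_id"], []).append(
                KeypointFrame(
                    frame_index=int(rec["frame"]),
                    timestamp=float(rec["ts"]),
                    person_id=rec["person_id"],
                    role=Role(rec["role"]),
                    keypoints=kpts,
                    visibility=vis,
                    bbox=tuple(rec["bbox"]),
                )
            )
    return [
        PersonTrack.from_frames(sorted(fs, key=lambda f: f.timestamp))
        for _, fs in sorted(frames.items())
    ]


def write_residents_csv(profiles: Iterable[ResidentProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"resident_id": p.resident_id, "care_level": p.care_level}
        row.update({f"al_{a}": al for a, al in zip(ACTIVITIES, p.assistance)})
        row["baseline_speed"] = p.baseline_speed
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_residents_csv(path: str | Path) -> dict[str, ResidentProfile]:
    df = pd.read_csv(path)
    out: dict[str, ResidentProfile] = {}
    for _, r in df.iterrows():
        out[str(r.resident_id)] = ResidentProfile(
            resident_id=str(r.resident_id),
            care_level=int(r.care_level),
            assistance=tuple(int(r[f"al_{a}"]) for a in ACTIVITIES),  # type: ignore[arg-type]
            baseline_speed=float(r.get("baseline_speed", 0.05)),
        )
    return out


def write_nurses_csv(roster: Iterable[NurseState], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "nurse_id": n.nurse_id,
                "room": n.room or "",
                "busy": int(n.busy),
                "x": n.position[0],
                "y": n.position[1],
            }
            for n in roster
        ]
    ).to_csv(path, index=False)


def read_nurses_csv(path: str | Path) -> list[NurseState]:
    df = pd.read_csv(path)
    return [
        NurseState(
            nurse_id=str(r.nurse_id),
            room=str(r.room) if not pd.isna(r.room) and str(r.room) else None,
            busy=bool(int(r.busy)),
            position=(float(r.get("x", 0.0)), float(r.get("y", 0.0))),
        )
        for _, r in df.iterrows()
    ]


def write_truth_csv(session: SimulatedSession, path: str | Path, labels=None) -> None:
    rows = []
    for i, ev in enumerate(session.truth_events):
        row = {
            "ts": ev.timestamp,
            "resident_id": ev.resident_id,
            "kind": ev.kind,
            "duration_s": ev.duration_s,
        }
        if labels is not None:
            row["label"] = labels[i] if labels[i] is not None else "NaN"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> tuple[list[TruthEvent], list[str | None]]:
    df = pd.read_csv(path)
    events, labels = [], []
    for _, r in df.iterrows():
        events.append(
            TruthEvent(
                timestamp=float(r.ts),
                resident_id=str(r.resident_id),
                kind=str(r.get("kind", "stand_up_attempt")),
                duration_s=float(r.get("duration_s", 8.0)),
            )
        )
        lab = r.get("label", "NaN")
        labels.append(None if pd.isna(lab) or str(lab) == "NaN" else str(lab))
    return events, labels


def _decision_record(d, strategy: str) -> dict:
    return {
        "alarm_id": d.alarm.alarm_id,
        "ts": d.alarm.timestamp,
        "resident": d.alarm.profile.resident_id,
        "disposition": d.disposition.value,
        "reason": d.suppression_reason.value,
        "delay": d.delay,
        "delay_s": d.delay_s,
        "priority": d.priority,
        "tau": d.tau,
        "nurse": d.assigned_nurse,
        "notified": list(d.notified),
        "strategy": strategy,
    }


def write_decisions_jsonl(result: TriageResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in result.decisions:
            fh.write(_dump(_decision_record(d, result.strategy.value)) + "\n")


def read_decisions_jsonl(path: str | Path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_shadow_jsonl(result: TriageResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in result.shadow_log:
            fh.write(
                _dump(
                    {
                        "alarm_id": e.alarm_id,
                        "ts": e.timestamp,
                        "reason": e.reason,
                        "urgency": e.urgency,
                        "clinical": e.clinical.value,
                        "min_distance": e.min_distance,
                        "workload": e.workload,
                        "strategy": result.strategy.value,
                    }
                )
                + "\n"
            )


def write_events_jsonl(events, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in events:
            fh.write(
                _dump(
                    {
                        "ts": e.timestamp,
                        "end_ts": e.end_timestamp,
                        "person_id": e.person_id,
                        "score": e.score,
                        "tau_A": e.tau,
                        "label": e.activity_label.value,
                        "flagged": e.flagged,
                    }
                )
                + "\n"
            )
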