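"""Scoring triage decisions against ground truth.

Events are scored as a multi-class assignment problem over the nurse
ids plus the ``NaN`` class, which means "no alert sent" — either the
correct outcome (fully dependent resident with a stationed attendant,
or nobody reachable in time) or a miss. The notify-all baseline
contributes one (truth, notified nurse) pair per notification, so with
four nurses each event yields four rows and the baseline's per-class
recall is diluted accordingly; single-assignment strategies contribute
one row per event. Escalated alarms are credited to the nurse who
finally acknowledged.

Metrics: per-class precision / recall / F1 (0 and flagged when
undefined), accuracy, unweighted macro F1, and one-vs-rest
macro-averaged false-positive and false-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anomaly import DetectionConfig
from .pipeline import PipelineRun, build_alarms, detect_session, run_session
from .simulate import SimulatedSession, ground_truth_labels
from .triage import Disposition, Strategy, TriageParams, TriageResult

__all__ = [
    "NAN_CLASS",
    "ConfusionMatrix",
    "MetricsReport",
    "label_pairs",
    "confusion",
    "metrics",
    "alarm_load",
    "compare_strategies",
    "CompareReport",
]

NAN_CLASS = "NaN"


@dataclass
class ConfusionMatrix:
    """Square truth x predicted tally over nurse classes plus NaN."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # precision / recall / f1 / support, one row per class
    accuracy: float
    macro_f1: float
    fpr: float
    fnr: float
    undefined_classes: tuple[str, ...] = ()

    def __repr__(self) -> str:  # compact, table-first
        head = (
            f"accuracy={self.accuracy:.4f} macro_f1={self.macro_f1:.4f} "
            f"fpr={self.fpr:.4f} fnr={self.fnr:.4f}"
        )
        return head + "\n" + self.per_class.to_string()


def confusion(
    truth: Sequence[str | None],
    predicted: Sequence[str | None],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally truth vs predicted labels; None means the NaN (no-alert) class."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth and predictions must cover the same events: {len(truth)} vs {len(predicted)}"
        )
    t = [NAN_CLASS if x is None else str(x) for x in truth]
    p = [NAN_CLASS if x is None else str(x) for x in predicted]
    if classes is None:
        nurse_classes = sorted(set(t) | set(p) - {NAN_CLASS})
        classes = [c for c in nurse_classes if c != NAN_CLASS] + [NAN_CLASS]
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(t) | set(p)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(t, p):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def metrics(matrix: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F1 plus macro F1, accuracy, FPR, FNR.

    A class with neither truth nor predicted instances has undefined
    precision/recall; it is reported as 0 and flagged so macro averages
    stay conservative. FPR/FNR are computed one-vs-rest per class and
    macro-averaged.
    """
    if matrix.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    c = matrix.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = matrix.total - tp - fp - fn
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
        fpr = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
        fnr = np.where(tp + fn > 0, fn / (tp + fn), 0.0)
    undefined = tuple(
        cls
        for cls, t_, p_ in zip(matrix.classes, c.sum(axis=1), c.sum(axis=0))
        if t_ == 0 and p_ == 0
    )
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": c.sum(axis=1).astype(int),
        },
        index=list(matrix.classes),
    )
    return MetricsReport(
        per_class=per_class,
        accuracy=float(tp.sum() / matrix.total),
        macro_f1=float(f1.mean()),
        fpr=float(fpr.mean()),
        fnr=float(fnr.mean()),
        undefined_classes=undefined,
    )


def label_pairs(
    run: PipelineRun, truth_labels: Sequence[str | None]
) -> list[tuple[str | None, str | None, str]]:
    """(truth, predicted, room) rows for one strategy's replay.

    Truth events without a matched detection predict NaN; spurious
    detections enter with truth NaN. The baseline expands into one row
    per notified nurse.
    """
    session = run.session
    if len(truth_labels) != len(session.truth_events):
        raise ValueError("truth labels must align with the session's truth events")
    dmap = {d.alarm.alarm_id: d for d in run.result.decisions}
    baseline = run.strategy is Strategy.BASELINE
    rows: list[tuple[str | None, str | None, str]] = []

    def decision_pred(j: int) -> str | None:
        d = dmap.get(f"E{j:04d}")
        if d is None:
            return None
        if d.disposition in (Disposition.DISPATCHED, Disposition.ESCALATED):
            return d.assigned_nurse
        return None

    for i, ev in enumerate(session.truth_events):
        room = session.rooms[ev.resident_id]
        j = run.matches[i]
        if j is None:
            rows.append((truth_labels[i], None, room))
            continue
        if baseline:
            d = dmap.get(f"E{j:04d}")
            for nid in d.notified if d else ():
                rows.append((truth_labels[i], nid, room))
        else:
            rows.append((truth_labels[i], decision_pred(j), room))
    for j in run.spurious:
        room = session.rooms[run.episodes[j].person_id]
        if baseline:
            d = dmap.get(f"E{j:04d}")
            for nid in d.notified if d else ():
                rows.append((None, nid, room))
        else:
            rows.append((None, decision_pred(j), room))
    return rows


def alarm_load(
    results: Mapping[str, TriageResult], baseline_key: str = "baseline"
) -> pd.DataFrame:
    """Per-nurse notification load relative to the notify-all baseline.

    load = notifications / baseline notifications; reduction = 1 - load.
    A nurse with zero baseline notifications has undefined load (NaN).
    """
    if baseline_key not in results:
        raise ValueError(f"baseline run {baseline_key!r} missing from results")
    base = results[baseline_key].notifications
    rows = []
    for strat, res in results.items():
        for nurse, n in sorted(res.notifications.items()):
            b = base.get(nurse, 0)
            load = n / b if b > 0 else np.nan
            rows.append(
                {
                    "strategy": strat,
                    "nurse": nurse,
                    "notifications": n,
                    "baseline_notifications": b,
                    "load_pct": 100.0 * load if b > 0 else np.nan,
                    "reduction_pct": 100.0 * (1.0 - load) if b > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CompareReport:
    """Four-strategy ablation over one or more sessions ("days")."""

    per_slice: pd.DataFrame  # strategy x (day | room) metric rows
    overall: pd.DataFrame  # one row per strategy, pooled over everything
    summary: pd.DataFrame  # mean +/- SD of macro F1 / accuracy across slices
    loads: pd.DataFrame  # per-nurse alarm load vs baseline, pooled
    runs: dict = field(default_factory=dict, repr=False)

    def __repr__(self) -> str:
        return (
            "Overall (pooled):\n" + self.overall.to_string()
            + "\n\nAcross slices (mean +/- SD):\n" + self.summary.to_string()
        )


def compare_strategies(
    sessions: SimulatedSession | Sequence[SimulatedSession],
    params: TriageParams | None = None,
    detection: DetectionConfig | None = None,
) -> CompareReport:
    """Run all four strategies on the identical detected stream of each
    session and score them overall, per room, and per day (session).

    Detection runs once per session and is shared, so strategies differ
    only in triage behaviour. Deterministic: rerunning with the same
    sessions and parameters reproduces the report exactly.
    """
    if isinstance(sessions, SimulatedSession):
        sessions = [sessions]
    if not sessions:
        raise ValueError("compare_strategies needs at least one session")
    params = params or TriageParams(nurse_speed=sessions[0].config.nurse_speed)
    classes = tuple(sorted(n.nurse_id for n in sessions[0].roster)) + (NAN_CLASS,)

    all_pairs: dict[str, list[tuple[str | None, str | None, str, str]]] = {
        s.value: [] for s in Strategy
    }
    notifications: dict[str, dict[str, int]] = {s.value: {} for s in Strategy}
    runs: dict[tuple[str, int], PipelineRun] = {}
    for day, session in enumerate(sessions, start=1):
        episodes = detect_session(session, detection)
        alarms = build_alarms(session, episodes, params)
        truth = ground_truth_labels(session, params)
        for strat in Strategy:
            run = run_session(
                session, strat, params, episodes=episodes, alarms=alarms
            )
            runs[(strat.value, day)] = run
            for t, p, room in label_pairs(run, truth):
                all_pairs[strat.value].append((t, p, room, f"day{day}"))
            for nurse, n in run.result.notifications.items():
                notifications[strat.value][nurse] = (
                    notifications[strat.value].get(nurse, 0) + n
                )

    def score(pairs: list) -> dict:
        if not pairs:
            return {"n": 0, "accuracy": np.nan, "macro_f1": np.nan, "fpr": np.nan, "fnr": np.nan}
        m = metrics(confusion([r[0] for r in pairs], [r[1] for r in pairs], classes))
        return {
            "n": len(pairs),
            "accuracy": m.accuracy,
            "macro_f1": m.macro_f1,
            "fpr": m.fpr,
            "fnr": m.fnr,
        }

    slice_rows = []
    overall_rows = []
    for strat in Strategy:
        pairs = all_pairs[strat.value]
        overall_rows.append({"strategy": strat.value, **score(pairs)})
        for kind, key in (("room", 2), ("day", 3)):
            for name in sorted({r[key] for r in pairs}):
                sub = [r for r in pairs if r[key] == name]
                slice_rows.append(
                    {"strategy": strat.value, "slice_type": kind, "slice": name, **score(sub)}
                )
    per_slice = pd.DataFrame(slice_rows)
    overall = pd.DataFrame(overall_rows).set_index("strategy")

    summary_rows = []
    for strat in Strategy:
        for kind in ("room", "day"):
            sub = per_slice[(per_slice.strategy == strat.value) & (per_slice.slice_type == kind)]
            summary_rows.append(
                {
                    "strategy": strat.value,
                    "slice_type": kind,
                    "macro_f1_mean": sub.macro_f1.mean(),
                    "macro_f1_sd": sub.macro_f1.std(ddof=1) if len(sub) > 1 else 0.0,
                    "accuracy_mean": sub.accuracy.mean(),
                    "accuracy_sd": sub.accuracy.std(ddof=1) if len(sub) > 1 else 0.0,
                }
            )
    summary = pd.DataFrame(summary_rows)

    fake_results = {
        s.value: TriageResult(
            strategy=Strategy(s), decisions=[], shadow_log=[], notifications=notifications[s.value]
        )
        for s in Strategy
    }
    loads = alarm_load(fake_results, baseline_key=Strategy.BASELINE.value)
    return CompareReport(
        per_slice=per_slice, overall=overall, summary=summary, loads=loads, runs=runs
    )
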