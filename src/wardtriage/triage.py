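"""The alert triage engine: suppression, delay, validation, dispatch.

Each alarm candidate passes three sequential gates and, if it survives,
is dispatched to a ranked nurse with acknowledgment-based escalation:

1. **Suppression** — discard when (a) every available nurse is beyond
   the reachable distance ``theta_x = (stand_up_time - reach_window) *
   nurse_speed`` (too_far), (b) urgency is below ``theta_u``
   (not_urgent), or (c) the resident's clinical priority is *low*, i.e.
   fully dependent with a stationed attendant (low_priority). Every
   discard is shadow-logged for audit.
2. **Delay** — a personalised normalised delay
   ``D = a1*(1 - u) + a2*r + a3*care_delay(c)`` (care_delay: high -> 0,
   mid -> 1), mapped to seconds by ``delay_scale``; alarms whose delay
   exceeds the acknowledgment horizon ``T_ack`` are discarded.
3. **Validation** — a pluggable priority backend maps the alarm context
   to a scalar priority in [0, 1] and a recommended nurse; the alert
   proceeds iff priority >= a (possibly dynamic) threshold tau.

Four strategies reproduce the ablation ladder: ``baseline`` notifies
every on-duty nurse for every event; ``rsd`` applies suppression +
delay and assigns the nearest available nurse; ``rsdv`` adds surrogate
validation at a fixed threshold; ``proposed`` runs the full pipeline
with the dynamic per-alarm threshold. The effective alert set A* is the
set of alarms that end up dispatched or escalated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, NamedTuple, Protocol, Sequence, runtime_checkable

from .context import AlarmCandidate, ClinicalPriority, NurseState

__all__ = [
    "Strategy",
    "Disposition",
    "SuppressionReason",
    "SuppressionThresholds",
    "DelayWeights",
    "TriageParams",
    "TriageDecision",
    "ShadowLogEntry",
    "TriageResult",
    "BackendResult",
    "PriorityBackend",
    "SurrogateBackend",
    "BackendContractError",
    "AckProvider",
    "AlwaysAck",
    "reachable_threshold",
    "suppress",
    "compute_delay",
    "delay_gate",
    "build_prompt",
    "validate",
    "dynamic_threshold",
    "dispatch_and_escalate",
    "run_triage",
]


class Strategy(str, Enum):
    BASELINE = "baseline"
    RSD = "rsd"
    RSDV = "rsdv"
    PROPOSED = "proposed"


class Disposition(str, Enum):
    SUPPRESSED = "suppressed"
    DELAY_DISCARDED = "delay_discarded"
    VALIDATION_DISCARDED = "validation_discarded"
    DISPATCHED = "dispatched"
    ESCALATED = "escalated"
    UNANSWERED = "unanswered"


class SuppressionReason(str, Enum):
    TOO_FAR = "too_far"
    NOT_URGENT = "not_urgent"
    LOW_PRIORITY = "low_priority"
    NONE = "none"


@dataclass(frozen=True)
class SuppressionThresholds:
    """theta_x (m), theta_u (urgency) and the reach window Delta-t (s)."""

    theta_x: float
    theta_u: float = 0.2
    reach_window: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_x < 0:
            raise ValueError("theta_x must be >= 0")
        if not 0.0 <= self.theta_u <= 1.0:
            raise ValueError("theta_u must lie in [0, 1]")
        if self.reach_window <= 0:
            raise ValueError("reach_window must be > 0")


@dataclass(frozen=True)
class DelayWeights:
    """Simplex weights (alpha) of the three delay terms."""

    urgency: float = 0.5
    workload: float = 0.25
    care: float = 0.25

    def __post_init__(self) -> None:
        vals = (self.urgency, self.workload, self.care)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError(f"delay weights must each lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"delay weights must sum to 1, got {sum(vals)}")


@dataclass(frozen=True)
class TriageParams:
    """Everything the engine needs beyond the alarms themselves."""

    theta_u: float = 0.2
    reach_window: float = 1.0  # seconds; Delta-t of the reach rule
    stand_up_time: float = 3.0  # seconds an unassisted stand-up takes
    nurse_speed: float = 1.2  # m/s nominal walking speed
    t_ack: float = 30.0  # acknowledgment horizon, seconds
    delay_scale: float = 10.0  # seconds per unit of normalised delay
    delay_weights: DelayWeights = field(default_factory=DelayWeights)
    surrogate_weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    tau_params: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.2)
    theta_x_override: float | None = None

    @property
    def theta_x(self) -> float:
        if self.theta_x_override is not None:
            return self.theta_x_override
        return reachable_threshold(self.stand_up_time, self.nurse_speed, self.reach_window).theta_x

    @property
    def thresholds(self) -> SuppressionThresholds:
        return SuppressionThresholds(
            theta_x=self.theta_x, theta_u=self.theta_u, reach_window=self.reach_window
        )


@dataclass
class TriageDecision:
    alarm: AlarmCandidate
    disposition: Disposition
    strategy: Strategy
    suppression_reason: SuppressionReason = SuppressionReason.NONE
    delay: float = 0.0  # normalised [0, 1]
    delay_s: float = 0.0
    priority: float | None = None
    tau: float | None = None
    assigned_nurse: str | None = None
    notified: tuple[str, ...] = ()
    ack_deadline: float | None = None

    def __post_init__(self) -> None:
        if (self.disposition is Disposition.SUPPRESSED) != (
            self.suppression_reason is not SuppressionReason.NONE
        ):
            raise ValueError("disposition=suppressed iff a suppression reason is set")
        if self.disposition in (Disposition.DISPATCHED, Disposition.ESCALATED) and not self.assigned_nurse:
            raise ValueError(f"{self.disposition.value} decisions must carry an assigned nurse")


@dataclass
class ShadowLogEntry:
    """Audit record of one suppressed or discarded alarm."""

    alarm_id: str
    timestamp: float
    reason: str
    urgency: float
    clinical: ClinicalPriority
    min_distance: float
    workload: float


@dataclass
class TriageResult:
    strategy: Strategy
    decisions: list[TriageDecision]
    shadow_log: list[ShadowLogEntry]
    notifications: dict[str, int]

    @property
    def effective(self) -> list[AlarmCandidate]:
        """A*: alarms dispatched or escalated."""
        return [
            d.alarm
            for d in self.decisions
            if d.disposition in (Disposition.DISPATCHED, Disposition.ESCALATED)
        ]


# ---------------------------------------------------------------------------
# Gates


class ReachResult(NamedTuple):
    theta_x: float
    degenerate: bool  # stand_up_time <= reach_window: nothing is reachable


def reachable_threshold(stand_up_time: float, nurse_speed: float, reach_window: float = 1.0) -> ReachResult:
    """Maximum reachable distance theta_x = (stand_up_time - Dt) * speed.

    The acceptable reaching time is the stand-up duration minus the reach
    window Dt; a nurse farther than theta_x cannot arrive in time. When
    stand_up_time <= reach_window nothing is reachable: theta_x = 0,
    flagged as degenerate rather than raised, so a caller can surface it.
    """
    if nurse_speed < 0:
        raise ValueError("nurse_speed must be >= 0")
    ta = stand_up_time - reach_window
    if ta <= 0:
        return ReachResult(0.0, True)
    return ReachResult(ta * nurse_speed, False)


def suppress(
    alarm: AlarmCandidate,
    thresholds: SuppressionThresholds,
    nurse_distance: float | None = None,
) -> tuple[bool, SuppressionReason]:
    """First gate: (keep, reason). Clauses checked in rule order.

    ``nurse_distance`` is the scalar reduction of the per-nurse map —
    the minimum over currently available nurses (an alarm is "too far"
    only when unreachable by everyone); defaults to the alarm's own
    minimum.
    """
    d = alarm.min_distance if nurse_distance is None else nurse_distance
    if d > thresholds.theta_x:
        return False, SuppressionReason.TOO_FAR
    if alarm.urgency < thresholds.theta_u:
        return False, SuppressionReason.NOT_URGENT
    if alarm.clinical is ClinicalPriority.LOW:
        return False, SuppressionReason.LOW_PRIORITY
    return True, SuppressionReason.NONE


_CARE_DELAY = {ClinicalPriority.HIGH: 0.0, ClinicalPriority.MID: 1.0, ClinicalPriority.LOW: 1.0}


def compute_delay(alarm: AlarmCandidate, weights: DelayWeights | None = None) -> float:
    """Second gate input: normalised delay D in [0, 1].

    ``D = a1*(1 - u) + a2*r + a3*care_delay(c)`` — maximally urgent
    alarms go out immediately; mid-priority residents tolerate a longer
    deferral than high-priority ones (low never reaches this gate: it is
    suppressed upstream, but encodes like mid for totality).
    """
    w = weights or DelayWeights()
    return (
        w.urgency * (1.0 - alarm.urgency)
        + w.workload * alarm.workload
        + w.care * _CARE_DELAY[alarm.clinical]
    )


def delay_gate(alarm: AlarmCandidate, delay_s: float, ack_window: float) -> bool:
    """Keep unless the scheduled delay strictly exceeds the ack horizon."""
    if delay_s < 0:
        raise ValueError("delay must be >= 0")
    return delay_s <= ack_window


def build_prompt(alarm: AlarmCandidate, roster: Sequence[NurseState]) -> str:
    """Deterministic natural-language serialisation of the alarm context.

    A fixed template over (t, x, u, c, r) plus per-nurse availability;
    identical alarms produce byte-identical prompts. This is the text a
    language-model validation backend would receive.
    """
    lines = [
        "Alert triage request for a long-term-care ward.",
        f"time_s={alarm.timestamp:.3f}",
        f"resident={alarm.profile.resident_id} care_level={alarm.profile.care_level} "
        f"assistance={list(alarm.profile.assistance)}",
        f"activity={alarm.source_event.activity_label.value if alarm.source_event else 'unknown'}",
        f"urgency={alarm.urgency:.4f}",
        f"clinical_priority={alarm.clinical.value}",
        f"ward_workload={alarm.workload:.4f}",
        "nurses:",
    ]
    for n in sorted(roster, key=lambda n: n.nurse_id):
        d = alarm.distances.get(n.nurse_id, float("inf"))
        lines.append(
            f"  - id={n.nurse_id} distance_m={d:.3f} busy={n.busy} "
            f"available={n.available} workload_index={n.workload_index}"
        )
    lines.append("Respond with a priority in [0,1] and the single best nurse id.")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Validation backends


class BackendContractError(RuntimeError):
    """A priority backend violated its contract (range or roster)."""


@dataclass
class BackendResult:
    priority: float
    recommended: str | None
    ranking: tuple[str, ...]  # available nurses, best first
    per_nurse: dict[str, float]


@runtime_checkable
class PriorityBackend(Protocol):
    def score(
        self, alarm: AlarmCandidate, roster: Sequence[NurseState], theta_x: float
    ) -> BackendResult: ...


class SurrogateBackend:
    """Deterministic stand-in for semantic validation.

    ``priority = w1*u + w2*clin(c) + w3*proximity + w4*(1 - r)`` with
    clin(high)=1, clin(mid)=0.5, clin(low)=0 and proximity =
    max(0, 1 - d/theta_x) at the nearest available nurse's distance.
    The recommended nurse maximises the same formula at that nurse's own
    distance; ties break by lower workload index, then lexicographic id.
    """

    _CLIN = {ClinicalPriority.HIGH: 1.0, ClinicalPriority.MID: 0.5, ClinicalPriority.LOW: 0.0}

    def __init__(self, weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)):
        self.weights = weights

    def _prio(self, alarm: AlarmCandidate, distance: float, theta_x: float) -> float:
        w1, w2, w3, w4 = self.weights
        prox = max(0.0, 1.0 - distance / theta_x) if theta_x > 0 else 0.0
        p = (
            w1 * alarm.urgency
            + w2 * self._CLIN[alarm.clinical]
            + w3 * prox
            + w4 * (1.0 - alarm.workload)
        )
        return float(min(1.0, max(0.0, p)))

    def score(
        self, alarm: AlarmCandidate, roster: Sequence[NurseState], theta_x: float
    ) -> BackendResult:
        avail = [n for n in roster if _is_available(n, alarm.timestamp)]
        per_nurse = {
            n.nurse_id: self._prio(alarm, alarm.distances.get(n.nurse_id, float("inf")), theta_x)
            for n in avail
        }
        order = sorted(
            avail, key=lambda n: (-per_nurse[n.nurse_id], n.workload_index, n.nurse_id)
        )
        ranking = tuple(n.nurse_id for n in order)
        min_d = min(
            (alarm.distances.get(n.nurse_id, float("inf")) for n in avail), default=float("inf")
        )
        priority = self._prio(alarm, min_d, theta_x) if avail else 0.0
        return BackendResult(
            priority=priority,
            recommended=ranking[0] if ranking else None,
            ranking=ranking,
            per_nurse=per_nurse,
        )


class PromptedBackend:
    """Adapter for an external language-model validation service.

    The caller injects ``complete``: a callable mapping a prompt string
    to a response containing ``priority=<float>`` and ``nurse=<id>``.
    Responses are range- and roster-checked like any other backend.
    This package ships no client; the deterministic surrogate is the
    default and the tested path, and nothing here claims to reproduce
    any particular model's behaviour.
    """

    def __init__(self, complete):
        if not callable(complete):
            raise TypeError("PromptedBackend needs a callable `complete(prompt) -> str`")
        self.complete = complete

    def score(
        self, alarm: AlarmCandidate, roster: Sequence[NurseState], theta_x: float
    ) -> BackendResult:
        import re

        text = self.complete(build_prompt(alarm, roster))
        m_p = re.search(r"priority\s*=\s*([0-9.]+)", text)
        m_n = re.search(r"nurse\s*=\s*(\S+)", text)
        if not m_p or not m_n:
            raise BackendContractError(f"unparseable backend response: {text!r}")
        priority = float(m_p.group(1))
        recommended = m_n.group(1)
        avail = [n for n in roster if _is_available(n, alarm.timestamp)]
        rest = sorted(
            (n.nurse_id for n in avail if n.nurse_id != recommended),
            key=lambda nid: (alarm.distances.get(nid, float("inf")), nid),
        )
        ranking = tuple([recommended] + rest) if recommended else tuple(rest)
        return BackendResult(
            priority=priority, recommended=recommended, ranking=ranking,
            per_nurse={nid: priority for nid in ranking},
        )


def _is_available(n: NurseState, t: float) -> bool:
    return n.available and not n.busy and t >= n.busy_until


def validate(
    alarm: AlarmCandidate,
    roster: Sequence[NurseState],
    backend: PriorityBackend,
    theta_x: float,
) -> BackendResult:
    """Run the backend and enforce its contract (range, roster membership)."""
    result = backend.score(alarm, roster, theta_x)
    if not 0.0 <= result.priority <= 1.0:
        raise BackendContractError(f"backend priority {result.priority} outside [0, 1]")
    roster_ids = {n.nurse_id for n in roster}
    if result.recommended is not None and result.recommended not in roster_ids:
        raise BackendContractError(f"backend recommended unknown nurse {result.recommended!r}")
    if not set(result.ranking) <= roster_ids:
        raise BackendContractError("backend ranking contains unknown nurses")
    return result


def dynamic_threshold(
    alarm: AlarmCandidate,
    theta_x: float,
    params: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.2),
    available_min_distance: float | None = None,
) -> float:
    """Context-dependent priority cutoff tau in [0, 1].

    ``tau = clamp(tau0 + b1*r + b2*d_min/theta_x - b3*[c = high], 0, 1)``:
    a busy ward and a distant nurse raise the bar, a high clinical
    priority lowers it.
    """
    tau0, b1, b2, b3 = params
    d = alarm.min_distance if available_min_distance is None else available_min_distance
    ratio = d / theta_x if theta_x > 0 else 1.0
    tau = tau0 + b1 * alarm.workload + b2 * ratio - b3 * (
        1.0 if alarm.clinical is ClinicalPriority.HIGH else 0.0
    )
    return float(min(1.0, max(0.0, tau)))


# ---------------------------------------------------------------------------
# Dispatch, acknowledgment, escalation


@runtime_checkable
class AckProvider(Protocol):
    def acknowledges(self, nurse_id: str, alarm: AlarmCandidate) -> tuple[bool, float]:
        """(acknowledged within the window?, latency in seconds)."""
        ...


class AlwaysAck:
    """Every nurse acknowledges instantly; the engine's default."""

    def acknowledges(self, nurse_id: str, alarm: AlarmCandidate) -> tuple[bool, float]:
        return True, 0.0


def dispatch_and_escalate(
    alarm: AlarmCandidate,
    ranking: Sequence[str],
    roster_map: Mapping[str, NurseState],
    ack: AckProvider,
    t_ack: float,
    notify_time: float,
) -> tuple[Disposition, str | None, tuple[str, ...]]:
    """Walk the ranking until someone acknowledges.

    First-ranked nurse acknowledging -> dispatched; a later one ->
    escalated; nobody -> the terminal unanswered state. The
    acknowledging nurse's workload index is incremented and they are
    locked (busy) until their acknowledgment time.
    """
    notified: list[str] = []
    waited = 0.0
    for rank, nurse_id in enumerate(ranking):
        notified.append(nurse_id)
        acked, latency = ack.acknowledges(nurse_id, alarm)
        if acked and latency <= t_ack:
            nurse = roster_map[nurse_id]
            nurse.workload_index += 1
            nurse.busy_until = max(nurse.busy_until, notify_time + waited + latency)
            dispo = Disposition.DISPATCHED if rank == 0 else Disposition.ESCALATED
            return dispo, nurse_id, tuple(notified)
        waited += t_ack
    return Disposition.UNANSWERED, None, tuple(notified)


# ---------------------------------------------------------------------------
# The full loop


def run_triage(
    alarms: Sequence[AlarmCandidate],
    roster: Sequence[NurseState],
    params: TriageParams | None = None,
    strategy: Strategy | str = Strategy.PROPOSED,
    backend: PriorityBackend | None = None,
    ack: AckProvider | None = None,
) -> TriageResult:
    """Process an alarm stream under one strategy; every alarm gets
    exactly one disposition and discards are shadow-logged.

    Alarms are processed in time order; simultaneous alarms go by
    descending urgency, then ascending resident id, and workload /
    availability updates apply sequentially so later assignments see
    earlier ones. Roster states are copied: the caller's roster is never
    mutated.
    """
    params = params or TriageParams()
    strategy = Strategy(strategy)
    backend = backend or SurrogateBackend(params.surrogate_weights)
    ack = ack or AlwaysAck()
    roster = [replace(n) for n in roster]
    roster_map = {n.nurse_id: n for n in roster}
    if not roster_map:
        raise ValueError("run_triage needs a non-empty roster")

    ordered = sorted(alarms, key=lambda a: (a.timestamp, -a.urgency, a.profile.resident_id))
    theta_x = params.theta_x
    thresholds = params.thresholds
    decisions: list[TriageDecision] = []
    shadow: list[ShadowLogEntry] = []
    notifications: dict[str, int] = {n.nurse_id: 0 for n in roster}

    def _shadow(alarm: AlarmCandidate, reason: str) -> None:
        shadow.append(
            ShadowLogEntry(
                alarm_id=alarm.alarm_id,
                timestamp=alarm.timestamp,
                reason=reason,
                urgency=alarm.urgency,
                clinical=alarm.clinical,
                min_distance=alarm.min_distance,
                workload=alarm.workload,
            )
        )

    for alarm in ordered:
        if strategy is Strategy.BASELINE:
            on_duty = [n.nurse_id for n in roster if n.available]
            for nid in on_duty:
                notifications[nid] += 1
                roster_map[nid].workload_index += 1
            nearest = min(on_duty, key=lambda nid: alarm.distances.get(nid, float("inf")))
            decisions.append(
                TriageDecision(
                    alarm=alarm,
                    disposition=Disposition.DISPATCHED,
                    strategy=strategy,
                    assigned_nurse=nearest,
                    notified=tuple(sorted(on_duty)),
                    ack_deadline=alarm.timestamp + params.t_ack,
                )
            )
            continue

        avail = [n for n in roster if _is_available(n, alarm.timestamp)]
        min_d = min(
            (alarm.distances.get(n.nurse_id, float("inf")) for n in avail), default=float("inf")
        )
        keep, reason = suppress(alarm, thresholds, min_d)
        if not keep:
            _shadow(alarm, reason.value)
            decisions.append(
                TriageDecision(
                    alarm=alarm,
                    disposition=Disposition.SUPPRESSED,
                    strategy=strategy,
                    suppression_reason=reason,
                )
            )
            continue

        delay = compute_delay(alarm, params.delay_weights)
        delay_s = delay * params.delay_scale
        if not delay_gate(alarm, delay_s, params.t_ack):
            _shadow(alarm, "unacceptable_delay")
            decisions.append(
                TriageDecision(
                    alarm=alarm,
                    disposition=Disposition.DELAY_DISCARDED,
                    strategy=strategy,
                    delay=delay,
                    delay_s=delay_s,
                )
            )
            continue

        priority: float | None = None
        tau: float | None = None
        if strategy in (Strategy.RSDV, Strategy.PROPOSED):
            result = validate(alarm, roster, backend, theta_x)
            priority = result.priority
            tau = (
                params.tau_params[0]
                if strategy is Strategy.RSDV
                else dynamic_threshold(alarm, theta_x, params.tau_params, min_d)
            )
            if priority < tau:
                _shadow(alarm, "low_validation_priority")
                decisions.append(
                    TriageDecision(
                        alarm=alarm,
                        disposition=Disposition.VALIDATION_DISCARDED,
                        strategy=strategy,
                        delay=delay,
                        delay_s=delay_s,
                        priority=priority,
                        tau=tau,
                    )
                )
                continue
            ranking = result.ranking
        else:  # rsd: nearest available nurse, no validation
            ranking = tuple(
                n.nurse_id
                for n in sorted(
                    avail,
                    key=lambda n: (
                        alarm.distances.get(n.nurse_id, float("inf")),
                        n.workload_index,
                        n.nurse_id,
                    ),
                )
            )

        notify_time = alarm.timestamp + delay_s
        dispo, assigned, notified = dispatch_and_escalate(
            alarm, ranking, roster_map, ack, params.t_ack, notify_time
        )
        for nid in notified:
            notifications[nid] += 1
        if dispo is Disposition.UNANSWERED:
            _shadow(alarm, "unanswered")
        decisions.append(
            TriageDecision(
                alarm=alarm,
                disposition=dispo,
                strategy=strategy,
                delay=delay,
                delay_s=delay_s,
                priority=priority,
                tau=tau,
                assigned_nurse=assigned,
                notified=notified,
                ack_deadline=notify_time + params.t_ack,
            )
        )

    return TriageResult(
        strategy=strategy, decisions=decisions, shadow_log=shadow, notifications=notifications
    )
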