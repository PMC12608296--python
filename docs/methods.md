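# Methods

## The problem

Conventional elderly-care monitoring notifies every nurse about every
detected event. In a long-term-care (LTC) ward this floods caregivers
with alerts that are false, unreachable (no one can arrive in time) or
unattainable (the resident already has an attendant), and the resulting
alarm fatigue is itself a safety hazard. `wardtriage` implements a
hybrid triage pipeline that suppresses, delays and validates alerts so
that only clinically warranted ones reach the single most suitable
nurse, together with a seeded ward simulator and a four-strategy
evaluation harness.

## The alarm model

Every detected anomaly becomes an alarm tuple

    a = (t, x, u, c, r)

with temporal context `t` (event timestamp plus the nominal nurse
walking speed), spatial context `x` (per-nurse centroid distances in
metres), urgency `u ∈ [0,1]`, clinical priority `c ∈ {high, mid, low}`,
and resource context `r ∈ [0,1]` (the busy fraction of the on-duty
roster). The effective alert set `A*` is the subset of alarms that pass
all three gates and end up dispatched or escalated.

### Anomaly detection

Abnormal behaviour means pre-fall conditions, chiefly sudden stand-up
attempts. A pluggable forecaster predicts each resident's hip-centre
vertical trajectory one step ahead; the abnormality score is the
absolute forecast residual `A(t) = |y(t) − ŷ(t)|`, and a frame is
flagged when `A(t)` strictly exceeds `τ_A`.

* **Forecaster contract.** Any object with `fit(timestamps, values)` /
  `predict(horizon)` qualifies. The default is a rolling least-squares
  linear extrapolation over a 25-frame window: deterministic,
  dependency-free, and exact on trajectories of polynomial degree ≤ 1,
  so a seated or uniformly moving person generates zero residual. The
  triage logic consumes only residuals, so recurrent-network or
  seasonal-decomposition backends can be registered without touching
  anything downstream; we deliberately treat the forecaster brand as
  interchangeable.
* **Threshold.** `τ_A = max(k · MAD, floor)` with `k = 3`, where the MAD
  is taken over a trailing 100-frame window of *signed* residuals
  (folding the residuals first would shrink the MAD by ≈ 30% and
  roughly quadruple the false-flag rate; an early version of this code
  did exactly that). For Gaussian noise this operating point sits at
  ≈ 2.0 robust standard deviations, i.e. an expected per-frame
  false-flag rate of ≈ 4.3%; individual seeded runs fluctuate roughly
  ± 1 percentage point around it. The absolute floor (0.5 px) keeps
  numerically quiet streams from flagging floating-point dust; an
  absolute-override mode replaces the MAD rule entirely. The threshold
  is infinite during warm-up (first `window + min_baseline` frames) so
  start-up transients never flag.
* **Episodes and labels.** Per-frame flags of one person within 4 s
  coalesce into one episode (a stand-up excursion spans rise, hold and
  sit-back, with quiet gaps shorter than that). An episode is labelled
  `stand_up_attempt` when the upward hip/shoulder speed anywhere in it
  exceeds 5% of the person's bounding-box height per second, else
  `other`. Nurses are never scored for anomalies.

### Motion features

Keypoints are consumed in pixel coordinates from an upstream pose
estimator; this package never touches video. A per-room calibration
supplies the frame rate `f` and a metres-per-pixel scale `s` (a required
input, not estimated). Per-keypoint speed is `s · f · Δp`; full-body
speed aggregates visible keypoints by arithmetic mean (median
available as a robust option), and a frame pair with zero visible
keypoints yields an explicit undefined-speed error, never a silent
zero. Inter-person distance is the planar Euclidean distance between
bounding-box centroids, scaled to metres before leaving the module —
suppression thresholds are metric. For a ceiling fisheye camera planar
centroid distance is geometrically approximate; we keep the convention
rather than model lens geometry.

### Urgency

`u = γ1·σ(v) + γ2·σ(a) + γ3·1[activity risky] + γ4·σ_f(flags)` with
weights `γ = (0.2, 0.2, 0.25, 0.35)` — recurrence weighs most, then the
activity class, with velocity and acceleration equal. The squashing `σ`
is the bounded ratio `v/(v + v0)` against the resident's baseline speed
(0.5 at baseline, parameter-free); flag counts saturate linearly at 3.
Acceleration is the first difference of body speed over consecutive
windows. The risky set defaults to {stand_up_attempt,
unstable_posture}. Each term lies in [0,1] and the weights sum to 1, so
`u` needs no post-hoc normalisation; it is monotone in every input.

### Clinical priority

From the care level CL (1–5) and the five per-activity assistance
levels AL (meals, bath, excretion, movement, dress-up; 1 = independent,
5 = full assistance), aggregated by worst case (`max`; `mean`
configurable):

* **low** — CL ∈ {4,5} and AL = 5: fully dependent, a stationed
  attendant is already beside them, so machine alerts are unattainable
  noise;
* **mid** — CL = 1 and AL = 1: fully independent, low fall risk;
* **high** — everything between: the mobile-but-impaired band that
  actually falls.

The mapping is total on the 5⁶ grid (exhaustively tested).

## The three gates

1. **Suppression** (first, cheapest, fully interpretable): discard when
   the *minimum* distance over currently available nurses exceeds
   `θ_x = (t_standup − Δt) · v_nurse` (too far for everyone; defaults
   3 s stand-up, Δt = 1 s reach window, 1.2 m/s walking speed, so
   θ_x = 2.4 m), when `u < θ_u` (default 0.2), or when `c = low`.
   Clauses are checked in that order; every discard is written to a
   shadow log for audit and threshold refinement. Using the minimum
   over nurses is the safety-first scalar reduction of the per-nurse
   distance map.
2. **Delay**: `D = α1·(1−u) + α2·r + α3·care_delay(c)` with
   `α = (0.5, 0.25, 0.25)` and `care_delay(high) = 0`,
   `care_delay(mid) = 1` (mid tolerates deferral; low never reaches
   this gate). `D ∈ [0,1]` is mapped to seconds by `delay_scale`
   (default 10 s — the delay formula is unitless, so a scale is a
   modelling choice). An alarm whose delay strictly exceeds the
   acknowledgment horizon `T_ack` (default 30 s; one parameter serves
   both the delay gate and the ack timer) is discarded.
3. **Validation**: a pluggable backend maps the alarm context and
   roster to a priority in [0,1] and a recommended nurse. The default
   **surrogate** is deterministic:
   `priority = 0.4·u + 0.3·clin(c) + 0.2·proximity + 0.1·(1−r)` with
   `clin(high)=1, clin(mid)=0.5` and
   `proximity = max(0, 1 − d/θ_x)`; the recommended nurse maximises the
   same formula at their own distance, ties broken by lower workload
   index then lexicographic id. The alert proceeds iff
   `priority ≥ τ`, where the dynamic threshold is
   `τ = clamp(0.3 + 0.2·r + 0.2·d_min/θ_x − 0.2·1[c=high], 0, 1)` — a
   busy ward and a distant nurse raise the bar, high clinical priority
   lowers it. Both the surrogate and the τ formula are this package's
   own constructions: they are pluggable, logged, and make no claim to
   reproduce the behaviour of any language-model validator. A
   `PromptedBackend` adapter exists for callers who inject a completion
   client; prompts are a fixed, byte-deterministic serialisation of the
   alarm tuple and roster.

**Dispatch and escalation.** The backend's ranking of available nurses
is walked until someone acknowledges within `T_ack`: first-ranked →
*dispatched*, later → *escalated*; an exhausted ranking is recorded as
the terminal *unanswered* state (the underlying procedure is silent on
exhaustion, so we added an explicit terminal state rather than loop).
The acknowledging nurse's workload index is incremented and they are
locked until their acknowledgment time, so simultaneous alarms —
processed in descending-urgency, then ascending-resident-id order — see
earlier assignments.

## Strategies

* `baseline` — notify-all: every on-duty nurse, every event.
* `rsd` — suppression + delay, nearest available nurse.
* `rsdv` — adds surrogate validation at the fixed threshold τ0 = 0.3.
* `proposed` — full pipeline with the dynamic per-alarm threshold.

All four replay the identical detected alarm stream, so differences are
attributable to triage alone.

## The ward simulator

The generator emulates a lunchtime LTC setting: 28 residents (6 high /
8 medium / 14 low care) seated across 3 dining rooms (6.4 m × 4.8 m at
s = 0.01 m/px), 4 nurses, session length drawn uniformly from 30–60
minutes, 5 fps (our choice; ample for a 3 s excursion at tractable
volume). Residents are 17-keypoint stick skeletons; stand-up attempts
are cosine-eased vertical excursions (0.45 m hip rise over 3 s, 2 s
hold, sit back) injected at tier-dependent Poisson rates (4 / 8 / 12
attempts per resident-hour for high / medium / low — dependent
residents rarely attempt to stand; independent ones do so often),
separated by ≥ 30 s per resident. Two nurses are stationed beside the
fully dependent residents and are permanently busy attending them; the
others roam all rooms on piecewise-constant-velocity waypoint tracks at
1.2 m/s with 2–10 s pauses.

Profiles are tier-typical: high = CL 4–5 with all AL 5; medium = CL 3
with AL 3–4; low = CL 1–2 with AL 1–2 *and at least one activity at
level 2* — a care-certified resident is never literally independent in
all five activities, so the `mid` clinical class does not occur in the
default ward (it is fully unit-tested on its own).

Two stochastic corruptions exist: per-keypoint Gaussian jitter
(`noise_sigma`, default 1 px) and acknowledgment behaviour (Bernoulli
ack with p = 0.9 and exponential latency, mean 5 s, seeded per
(nurse, alarm) pair so every strategy sees identical behaviour). The
package's **noiseless condition** turns both off — keypoint jitter and
ack failures are both noise sources, and parameter-recovery checks are
defined on the clean condition. One integer seed fixes everything;
identical (config, seed) runs are byte-identical.

**Ground-truth labels** are programmatic: an event is labelled with the
nearest free nurse whose distance at event time is within θ_x, and with
the no-alert class (`NaN`) when the resident is fully dependent with a
stationed attendant in the room or when nobody free can reach in time.
This is a declared proxy for human annotation of staff interventions,
not a claim of equivalence.

### What the simulator does and does not show

It exercises exactly the logic the pipeline depends on: vertical
excursions against a quiet baseline, metric geometry, tiered care
records, scripted availability, seeded acks. It does **not** model
occlusion, identity switches, fisheye distortion, postural sway,
nurse–resident interaction, or realistic ack psychology. Passing tests
therefore demonstrate correctness of the decision logic under the
stated model, not performance on real ward video. Known artefact:
keypoint jitter inflates the mean per-keypoint body speed (a folded-
noise bias), which raises the urgency velocity term on noisy streams;
real deployments would smooth keypoints first.

## Evaluation

Events are scored as a 5-class assignment problem (4 nurses + `NaN` =
"no alert sent"). Detected episodes match truth events of the same
resident when onset falls within the event span ± 2 s (greedy,
one-to-one); unmatched truth events predict `NaN`, unmatched episodes
enter with truth `NaN`. The notify-all baseline contributes one
(truth, notified-nurse) row per notification — four rows per event with
four nurses, which is what dilutes its per-class recall to ≈ 1/4 —
while single-assignment strategies contribute one row per event.
Escalated alarms are credited to the nurse who finally acknowledged.

Metrics: per-class precision / recall / F1 (0 and flagged when a class
has neither truth nor predictions, so macro averages are conservative —
note the two stationed nurses are structurally silent in the default
ward and anchor two zero F1 terms), accuracy, unweighted macro F1, and
one-vs-rest macro-averaged FPR / FNR (the multi-class reduction is our
convention). Accuracy is event-level, not frame-level. Alarm load is
per-nurse notifications relative to the baseline run (baseline ≡ 100%
by construction; zero-baseline nurses report undefined). The
four-strategy comparison runs on the identical detected stream and
slices by room and by day (session), with mean ± SD across slices.

## Numerical and degenerate-input choices

* Strict inequalities where the decision rules state them: flagging is
  `score > τ_A`; the delay gate discards only when the delay *exceeds*
  the horizon; validation passes at `priority ≥ τ`.
* `stand_up_time ≤ reach_window` makes θ_x = 0 and is flagged as
  degenerate (nothing reachable) rather than raised.
* θ_x = 0 makes the proximity term 0 and the distance ratio 1.
* An empty availability set gives an infinite minimum distance (the
  alarm suppresses as unreachable) and an empty ranking ends as
  *unanswered*.
* Simplex weight vectors are validated to sum to 1 within 1e-9.
* All weights/thresholds live in one frozen parameter object; every
  log is written with sorted keys so replays are byte-comparable.

## Problem sizes used in the shipped checks

The packaged verification runs ten seeded full-length sessions
(30–60 min, 28 residents, ≈ 190 events each) for the conservation and
assignment-recovery checks, a 7-session ablation in the acceptance
script, 1000-frame trajectories for detection power, and exhaustive
grids (1323 suppression cells, 5⁶ clinical combinations) for the rule
logic — sizes chosen so the full suite completes in well under a minute
of compute per session on a single core.

## Known limitations

* The surrogate validator and dynamic threshold are linear stand-ins;
  nothing here measures semantic reasoning quality.
* Workload context `r` is frozen at alarm assembly (scripted busy
  fraction); engine-induced locks affect availability and ranking but
  not the already-assembled `r` of later alarms.
* Per-frame anomaly scoring uses one vertical series per resident;
  lateral instability only reaches the `other` label.
* The γ, α, surrogate and τ weights are fixed domain choices, not
  learned; nurse fatigue and specialisation are out of scope.
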