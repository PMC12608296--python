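"""Forecast-residual anomaly detection on joint trajectories.

Abnormal behaviour here means pre-fall conditions — above all a sudden,
unassisted attempt to stand up. A forecaster predicts where a tracked
joint should be next; the absolute forecast residual ``A(t) = |y(t) -
yhat(t)|`` is the abnormality score, and a frame is flagged when the
score strictly exceeds a threshold ``tau_A``.

The forecaster is a pluggable contract (fit on a history window, predict
a horizon); the default is a rolling least-squares linear extrapolation,
which is deterministic and dependency-free. The framework downstream
only consumes residuals, so any contract-conforming backend can be
registered in its place.

``tau_A`` defaults to ``k * MAD`` of the residuals over a trailing
baseline window (k = 3), with an absolute floor so that near-noiseless
streams do not flag numerical dust; an absolute override is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from .motion import HIP_IDXS, SHOULDER_IDXS, KeypointFrame, PersonTrack, Role

__all__ = [
    "ActivityLabel",
    "TrajectorySeries",
    "ForecastResult",
    "AnomalyEvent",
    "Forecaster",
    "LinearTrendForecaster",
    "DetectionConfig",
    "forecast_trajectory",
    "residual_score",
    "flag_abnormal",
    "rolling_residuals",
    "rolling_threshold",
    "detect_events",
    "coalesce_events",
]


class ActivityLabel(str, Enum):
    STAND_UP_ATTEMPT = "stand_up_attempt"
    UNSTABLE_POSTURE = "unstable_posture"
    OTHER = "other"


@dataclass
class TrajectorySeries:
    """Ordered (timestamp, position) samples for one joint of one person."""

    person_id: str
    joint_id: str
    timestamps: np.ndarray
    values: np.ndarray  # (n,) scalar or (n, d) positions
    window_length: int = 2

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must align")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ForecastResult:
    horizon: int
    predicted: np.ndarray
    observed: np.ndarray | None = None

    @property
    def residuals(self) -> np.ndarray | None:
        """Observed minus predicted, defined only where both exist."""
        if self.observed is None:
            return None
        n = min(len(self.observed), len(self.predicted))
        return np.asarray(self.observed)[:n] - np.asarray(self.predicted)[:n]


@dataclass
class AnomalyEvent:
    timestamp: float
    person_id: str
    score: float
    tau: float
    activity_label: ActivityLabel = ActivityLabel.OTHER
    flagged: bool = True
    end_timestamp: float | None = None
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.end_timestamp is None:
            self.end_timestamp = self.timestamp
        self.activity_label = ActivityLabel(self.activity_label)


@runtime_checkable
class Forecaster(Protocol):
    """Contract every forecasting backend must satisfy."""

    def fit(self, timestamps: np.ndarray, values: np.ndarray) -> "Forecaster": ...

    def predict(self, horizon: int) -> np.ndarray:
        """Positions for the next ``horizon`` equally-spaced steps."""
        ...


class LinearTrendForecaster:
    """Least-squares line through the history window, extrapolated forward.

    Exact on trajectories that are polynomial of degree <= 1, so a still
    or uniformly moving person produces zero residual up to floating
    tolerance — no false events at any positive threshold.
    """

    def __init__(self) -> None:
        self._coef: np.ndarray | None = None  # (2, d): intercept, slope
        self._n = 0

    def fit(self, timestamps: np.ndarray, values: np.ndarray) -> "LinearTrendForecaster":
        y = np.atleast_1d(np.asarray(values, dtype=float))
        if y.ndim == 1:
            y = y[:, None]
        n = len(y)
        if n < 2:
            raise ValueError("linear forecaster needs at least 2 samples")
        x = np.arange(n, dtype=float)
        xm = x.mean()
        sxx = np.sum((x - xm) ** 2)
        slope = (x - xm) @ (y - y.mean(axis=0)) / sxx
        intercept = y.mean(axis=0) - slope * xm
        self._coef = np.vstack([intercept, slope])
        self._n = n
        return self

    def predict(self, horizon: int) -> np.ndarray:
        if self._coef is None:
            raise RuntimeError("predict called before fit")
        x = self._n - 1 + np.arange(1, horizon + 1, dtype=float)
        out = self._coef[0] + x[:, None] * self._coef[1]
        return out[:, 0] if out.shape[1] == 1 else out


def forecast_trajectory(
    series: TrajectorySeries, horizon: int, forecaster: Forecaster | None = None
) -> ForecastResult:
    """Fit the forecaster on the last ``window_length`` samples and predict.

    Raises a ``ValueError`` when the series is shorter than its declared
    window.
    """
    if len(series.values) < series.window_length:
        raise ValueError(
            f"series of length {len(series.values)} is shorter than "
            f"window_length {series.window_length}"
        )
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    fc = forecaster if forecaster is not None else LinearTrendForecaster()
    w = series.window_length
    fc.fit(series.timestamps[-w:], series.values[-w:])
    return ForecastResult(horizon=horizon, predicted=np.asarray(fc.predict(horizon)))


def residual_score(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Abnormality scores ``A(t) = |y(t) - yhat(t)|``, elementwise and >= 0.

    Vector-valued positions score as the Euclidean norm of the residual.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: observed {obs.shape} vs predicted {pred.shape}")
    resid = obs - pred
    if resid.ndim > 1:
        return np.linalg.norm(resid, axis=-1)
    return np.abs(resid)


def flag_abnormal(
    scores: Sequence[float],
    tau_a: float,
    timestamps: Sequence[float] | None = None,
    person_id: str = "",
) -> list[AnomalyEvent]:
    """Events for every score strictly above ``tau_a`` (ties are normal)."""
    if tau_a <= 0:
        raise ValueError("tau_a must be > 0")
    scores = np.asarray(scores, dtype=float)
    ts = np.asarray(timestamps, dtype=float) if timestamps is not None else np.arange(len(scores), dtype=float)
    idx = np.nonzero(scores > tau_a)[0]
    return [
        AnomalyEvent(timestamp=float(ts[i]), person_id=person_id, score=float(scores[i]),
                     tau=tau_a, frame_index=int(i))
        for i in idx
    ]


# ---------------------------------------------------------------------------
# Rolling per-frame detection


@dataclass
class DetectionConfig:
    """Knobs of the rolling detector.

    window_length / horizon are in frames; the threshold mode ``mad``
    sets tau_A = max(k * MAD(trailing residuals), tau_floor) per frame,
    while ``absolute`` uses tau_abs everywhere. ``stand_frac`` is the
    upward speed (as a fraction of bounding-box height per second) above
    which a flagged excursion is labelled a stand-up attempt.
    """

    window_length: int = 25
    horizon: int | None = None  # default: one second of frames
    tau_mode: str = "mad"
    k: float = 3.0
    tau_floor: float = 0.5  # pixels
    tau_abs: float = 5.0  # pixels, used when tau_mode == "absolute"
    baseline_window: int = 100  # frames of trailing residuals for the MAD
    min_baseline: int = 20
    stand_frac: float = 0.05
    episode_gap_s: float = 4.0

    def __post_init__(self) -> None:
        if self.tau_mode not in ("mad", "absolute"):
            raise ValueError(f"unknown tau_mode {self.tau_mode!r}")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")


def rolling_residuals(values: np.ndarray, window: int) -> np.ndarray:
    """One-step-ahead linear-forecast residuals (signed) for a scalar series.

    ``r[t] = y[t] - yhat[t]`` where yhat extrapolates the least-squares
    line over ``y[t-window:t]``. NaN while fewer than ``window`` points
    of history exist. The prediction is a fixed linear functional of the
    window, so the whole series is one sliding dot product.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    out = np.full(n, np.nan)
    if n <= window:
        return out
    x = np.arange(window, dtype=float)
    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    # weights of the one-step-ahead prediction yhat = sum_i w_i * y_i
    w = 1.0 / window + (window - xm) * (x - xm) / sxx
    windows = np.lib.stride_tricks.sliding_window_view(y, window)  # (n-window+1, window)
    preds = windows[:-1] @ w  # prediction for t = window .. n-1
    out[window:] = y[window:] - preds
    return out


def rolling_threshold(residuals: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Per-frame tau_A from trailing-window MAD of *signed* residuals.

    The MAD must be taken on the signed residuals (a scatter estimate);
    folding them first would shrink it and roughly quadruple the false-
    flag rate. Infinite during warm-up (fewer than ``min_baseline``
    finite trailing residuals) so start-up transients never flag.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if config.tau_mode == "absolute":
        return np.full(n, float(config.tau_abs))
    tau = np.full(n, np.inf)
    bw = config.baseline_window
    finite = np.isfinite(r)
    n_nan_head = int(np.argmax(finite)) if finite.any() else n
    # warm-up region: trailing window may be short or contain NaNs
    head_end = min(n, max(bw, n_nan_head + bw) + 1)
    for t in range(1, head_end):
        trail = r[max(0, t - bw):t]
        trail = trail[np.isfinite(trail)]
        if len(trail) >= config.min_baseline:
            med = np.median(trail)
            tau[t] = max(config.k * np.median(np.abs(trail - med)), config.tau_floor)
    if n > head_end:
        # steady state: every trailing window is fully finite
        windows = np.lib.stride_tricks.sliding_window_view(r, bw)
        windows = windows[head_end - bw:-1]  # trailing window for t = head_end .. n-1
        med = np.median(windows, axis=1)
        mad = np.median(np.abs(windows - med[:, None]), axis=1)
        tau[head_end:] = np.maximum(config.k * mad, config.tau_floor)
    return tau


def _vertical_series(track: PersonTrack) -> np.ndarray:
    """Hip-centre vertical (y) coordinate per frame; shoulder fallback."""
    for idxs in (HIP_IDXS, SHOULDER_IDXS):
        vis = track.visibility[:, list(idxs)]
        if vis.any():
            ys = track.keypoints[:, list(idxs), 1]
            with np.errstate(invalid="ignore"):
                out = np.where(vis.any(axis=1),
                               np.nansum(np.where(vis, ys, np.nan), axis=1) / np.maximum(vis.sum(axis=1), 1),
                               np.nan)
            return out
    return np.nanmean(track.keypoints[..., 1], axis=1)


def _as_tracks(stream: Iterable[KeypointFrame] | Sequence[PersonTrack]) -> list[PersonTrack]:
    stream = list(stream)
    if not stream:
        return []
    if isinstance(stream[0], PersonTrack):
        return stream  # type: ignore[return-value]
    by_person: dict[str, list[KeypointFrame]] = {}
    for f in stream:
        by_person.setdefault(f.person_id, []).append(f)
    return [PersonTrack.from_frames(sorted(fs, key=lambda f: f.timestamp)) for fs in by_person.values()]


def detect_events(
    stream: Iterable[KeypointFrame] | Sequence[PersonTrack],
    config: DetectionConfig | None = None,
    frame_rate: float | None = None,
) -> list[AnomalyEvent]:
    """Run forecast -> residual -> flag per resident; nurses never flag.

    Returns per-frame flagged events (coalesce with
    :func:`coalesce_events` to get one event per excursion), labelled
    stand-up attempt when the excursion's upward hip/shoulder speed
    exceeds ``stand_frac`` of the body-box height per second.
    """
    cfg = config or DetectionConfig()
    events: list[AnomalyEvent] = []
    for track in _as_tracks(stream):
        if track.role is not Role.RESIDENT:
            continue
        if len(track) <= cfg.window_length:
            continue
        y = _vertical_series(track)
        signed = rolling_residuals(y, cfg.window_length)
        resid = np.abs(signed)
        tau = rolling_threshold(signed, cfg)
        fr = frame_rate
        if fr is None:
            dts = np.diff(track.timestamps)
            fr = 1.0 / float(np.median(dts)) if len(dts) else 1.0
        h = cfg.horizon if cfg.horizon is not None else max(1, round(fr))
        with np.errstate(invalid="ignore"):
            flagged_idx = np.nonzero(np.nan_to_num(resid) > tau)[0]
        heights = track.bbox[:, 3] - track.bbox[:, 1]
        for i in flagged_idx:
            j = max(0, i - h)
            dt_span = track.timestamps[i] - track.timestamps[j]
            up_speed = (y[j] - y[i]) / dt_span if dt_span > 0 else 0.0  # y grows downward
            label = (
                ActivityLabel.STAND_UP_ATTEMPT
                if heights[i] > 0 and up_speed > cfg.stand_frac * heights[i]
                else ActivityLabel.OTHER
            )
            events.append(
                AnomalyEvent(
                    timestamp=float(track.timestamps[i]),
                    person_id=track.person_id,
                    score=float(resid[i]),
                    tau=float(tau[i]),
                    activity_label=label,
                    frame_index=int(track.frame_indices[i]),
                )
            )
    events.sort(key=lambda e: (e.timestamp, e.person_id))
    return events


def coalesce_events(events: Sequence[AnomalyEvent], gap_s: float = 4.0) -> list[AnomalyEvent]:
    """Merge per-frame flags of one person within ``gap_s`` into episodes.

    The episode keeps the onset timestamp, the maximum score, and the
    stand-up label if any member frame carried it (the onset frames of a
    rise often individually look like generic motion).
    """
    episodes: list[AnomalyEvent] = []
    by_person: dict[str, list[AnomalyEvent]] = {}
    for e in sorted(events, key=lambda e: (e.person_id, e.timestamp)):
        by_person.setdefault(e.person_id, []).append(e)
    for pid, evs in by_person.items():
        cur: list[AnomalyEvent] = [evs[0]]
        for e in evs[1:]:
            if e.timestamp - cur[-1].timestamp <= gap_s:
                cur.append(e)
            else:
                episodes.append(_merge(cur))
                cur = [e]
        episodes.append(_merge(cur))
    episodes.sort(key=lambda e: (e.timestamp, e.person_id))
    return episodes


def _merge(group: list[AnomalyEvent]) -> AnomalyEvent:
    best = max(group, key=lambda e: e.score)
    label = (
        ActivityLabel.STAND_UP_ATTEMPT
        if any(e.activity_label is ActivityLabel.STAND_UP_ATTEMPT for e in group)
        else best.activity_label
    )
    return AnomalyEvent(
        timestamp=group[0].timestamp,
        person_id=group[0].person_id,
        score=best.score,
        tau=best.tau,
        activity_label=label,
        end_timestamp=group[-1].timestamp,
        frame_index=group[0].frame_index,
    )
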