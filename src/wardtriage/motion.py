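"""Motion features from 2D pose keypoints and bounding boxes.

Keypoints arrive in pixel coordinates from an upstream pose estimator
(e.g. a YOLO-family pose model); this module never touches video. A
per-room :class:`CalibrationSpec` carries the frame rate ``f`` and the
metres-per-pixel scale ``s``; every speed or distance leaving this module
is in metric units (m/s, m).

Per-keypoint speed for a displacement of ``d`` pixels between consecutive
frames is ``v = s * f * d``. Full-body speed is an aggregate (mean by
default, median optionally) over the keypoints visible in both frames.
Inter-person distance is the Euclidean distance between bounding-box
centroids, scaled to metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Role",
    "CalibrationSpec",
    "KeypointFrame",
    "PersonTrack",
    "UndefinedSpeedError",
    "keypoint_displacement",
    "body_speed",
    "bbox_centroid",
    "interperson_distance",
]

# COCO-17 keypoint layout indices used throughout the package.
SHOULDER_IDXS = (5, 6)
HIP_IDXS = (11, 12)


class Role(str, Enum):
    """Who a tracked person is: caregiver or cared-for."""

    NURSE = "nurse"
    RESIDENT = "resident"


class UndefinedSpeedError(ValueError):
    """Raised when a body speed cannot be computed (no visible keypoints).

    Speed is never silently reported as zero when it is actually unknown:
    downstream urgency scoring must be able to tell "still" from "unseen".
    """


@dataclass(frozen=True)
class CalibrationSpec:
    """Camera/room calibration: frame rate (fps) and scale (m per pixel)."""

    frame_rate: float
    scale: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def inter_frame_dt(self) -> float:
        """Seconds between consecutive frames, 1/f."""
        return 1.0 / self.frame_rate


@dataclass
class KeypointFrame:
    """One person's pose in one frame.

    ``keypoints`` is an (N, 2) pixel array with a boolean ``visibility``
    mask of length N; ``bbox`` is (xmin, ymin, xmax, ymax) in pixels.
    Image convention: y grows downward, so standing up moves keypoints
    toward smaller y.
    """

    frame_index: int
    timestamp: float
    person_id: str
    role: Role
    keypoints: np.ndarray
    visibility: np.ndarray = field(default=None)  # type: ignore[assignment]
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 2 or self.keypoints.shape[1] != 2:
            raise ValueError("keypoints must be an (N, 2) array")
        if self.visibility is None:
            self.visibility = np.ones(len(self.keypoints), dtype=bool)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        if self.visibility.shape != (len(self.keypoints),):
            raise ValueError("visibility must be a length-N boolean vector")
        xmin, ymin, xmax, ymax = self.bbox
        if xmin > xmax or ymin > ymax:
            raise ValueError(f"invalid bbox {self.bbox}: min corner must not exceed max corner")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self.role = Role(self.role)


@dataclass
class PersonTrack:
    """A whole session of one person's frames as columnar arrays.

    The array form of a list of :class:`KeypointFrame`; streams of tens of
    thousands of frames are processed without materialising per-frame
    objects. Shapes: timestamps (n,), keypoints (n, N, 2), visibility
    (n, N), bbox (n, 4).
    """

    person_id: str
    role: Role
    frame_indices: np.ndarray
    timestamps: np.ndarray
    keypoints: np.ndarray
    visibility: np.ndarray
    bbox: np.ndarray

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        n = len(self.timestamps)
        if not (len(self.frame_indices) == len(self.keypoints) == len(self.visibility) == len(self.bbox) == n):
            raise ValueError("track arrays must share their leading dimension")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"timestamps must be strictly increasing for {self.person_id!r}")

    def __len__(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> KeypointFrame:
        """Materialise frame ``i`` as a :class:`KeypointFrame`."""
        return KeypointFrame(
            frame_index=int(self.frame_indices[i]),
            timestamp=float(self.timestamps[i]),
            person_id=self.person_id,
            role=self.role,
            keypoints=self.keypoints[i],
            visibility=self.visibility[i],
            bbox=tuple(float(v) for v in self.bbox[i]),
        )

    @classmethod
    def from_frames(cls, frames: Sequence[KeypointFrame]) -> "PersonTrack":
        if not frames:
            raise ValueError("cannot build a track from zero frames")
        pid = frames[0].person_id
        if any(f.person_id != pid for f in frames):
            raise ValueError("all frames in a track must share person_id")
        return cls(
            person_id=pid,
            role=frames[0].role,
            frame_indices=np.array([f.frame_index for f in frames], dtype=int),
            timestamps=np.array([f.timestamp for f in frames], dtype=float),
            keypoints=np.stack([f.keypoints for f in frames]),
            visibility=np.stack([f.visibility for f in frames]),
            bbox=np.array([f.bbox for f in frames], dtype=float),
        )

    def centroid(self, i: int) -> tuple[float, float]:
        """Bounding-box centroid at frame ``i``, in pixels."""
        return bbox_centroid(self.bbox[i])


def keypoint_displacement(frame_t: KeypointFrame, frame_t1: KeypointFrame) -> np.ndarray:
    """Per-keypoint pixel displacement between two consecutive frames.

    Element ``i`` is the Euclidean distance keypoint ``i`` travelled
    between ``frame_t`` and its successor ``frame_t1``; elements where the
    keypoint is invisible at either endpoint are NaN (missing).

    Raises
    ------
    ValueError
        If the frames belong to different persons or have a different
        number of keypoints.
    """
    if frame_t.person_id != frame_t1.person_id:
        raise ValueError(
            f"frames belong to different persons: {frame_t.person_id!r} vs {frame_t1.person_id!r}"
        )
    if len(frame_t.keypoints) != len(frame_t1.keypoints):
        raise ValueError("keypoint count differs between frames")
    disp = np.linalg.norm(frame_t1.keypoints - frame_t.keypoints, axis=1)
    missing = ~(frame_t.visibility & frame_t1.visibility)
    disp = disp.astype(float)
    disp[missing] = np.nan
    return disp


def body_speed(
    frames: Sequence[KeypointFrame],
    calib: CalibrationSpec,
    aggregate: str = "mean",
) -> float:
    """Full-body speed in m/s over a window of frames for one person.

    Per-keypoint speed between consecutive frames is ``s * f * d`` pixels
    converted to metres; the body speed of a frame pair is the ``mean``
    (or ``median``) over keypoints visible at both endpoints, and multi-
    pair windows are averaged over pairs.

    Raises
    ------
    ValueError
        If the window is shorter than 2 frames or mixes persons.
    UndefinedSpeedError
        If no frame pair has any visible keypoint.
    """
    if len(frames) < 2:
        raise ValueError("body_speed needs a window of at least 2 frames")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    reduce = np.nanmean if aggregate == "mean" else np.nanmedian
    pair_speeds = []
    for f0, f1 in zip(frames[:-1], frames[1:]):
        disp = keypoint_displacement(f0, f1)
        if np.all(np.isnan(disp)):
            continue
        pair_speeds.append(calib.scale * calib.frame_rate * float(reduce(disp)))
    if not pair_speeds:
        raise UndefinedSpeedError(
            f"no visible keypoints in any frame pair for person {frames[0].person_id!r}"
        )
    return float(np.mean(pair_speeds))


def bbox_centroid(bbox: Sequence[float]) -> tuple[float, float]:
    """Centroid of (xmin, ymin, xmax, ymax): the box's centre point, in pixels."""
    xmin, ymin, xmax, ymax = bbox
    return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


def interperson_distance(
    bbox_a: Sequence[float], bbox_b: Sequence[float], calib: CalibrationSpec
) -> float:
    """Euclidean distance between two bounding-box centroids, in metres.

    Symmetric; zero iff the centroids coincide. The pixel-space distance
    is scaled by ``calib.scale`` so thresholds downstream (which are in
    metres) compare like with like.
    """
    ca = np.asarray(bbox_centroid(bbox_a))
    cb = np.asarray(bbox_centroid(bbox_b))
    return float(np.linalg.norm(cb - ca)) * calib.scale
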