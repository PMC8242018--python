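"""Core data containers shared across the pipeline.

A recording session produces one :class:`TrackSeries` per camera view
(ventral camera sees the horizontal x-y plane, lateral camera sees the
vertical x-z plane) together with an :class:`IntensityTrace` of the
synchronization LED in that view.  After LED alignment and fusion the
session becomes a single :class:`Trajectory3D` at a uniform frame rate.

Coordinate convention: origin at a floor corner of the tank, z increasing
upward, units cm, frames 0-based.  Missing positions are NaN, never
silently dropped rows, so gap lengths stay measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHASE_QT = "QT"
PHASE_ES = "ES"

VENTRAL = "ventral"
LATERAL = "lateral"

#: coordinate axis names carried by each view
VIEW_AXES = {VENTRAL: ("x", "y"), LATERAL: ("x", "z")}


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus protocol: (phase label, duration in seconds) pairs.

    The canonical protocol alternates 30 s of quiescent time (QT) with
    30 s of electric stimulus (ES).  The 500 ms on/off duty cycle inside
    an ES phase is not modelled; motion statistics are per phase.
    """

    phases: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        for label, dur in self.phases:
            if label not in (PHASE_QT, PHASE_ES):
                raise ValueError(f"unknown phase label {label!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.phases))

    @classmethod
    def alternating(cls, qt_s: float = 30.0, es_s: float = 30.0,
                    n_cycles: int = 1) -> "StimulusSchedule":
        return cls(tuple([(PHASE_QT, qt_s), (PHASE_ES, es_s)] * n_cycles))

    def labels_for_frames(self, n_frames: int, fps: float,
                          offset_frames: int = 0) -> np.ndarray:
        """Phase label of each frame; frame f is at time (f+offset)/fps.

        Times beyond the schedule end are clamped to the last phase.
        """
        bounds = np.cumsum([d for _, d in self.phases])
        t = (np.arange(n_frames) + offset_frames) / fps
        idx = np.searchsorted(bounds, t, side="right")
        idx = np.minimum(idx, len(self.phases) - 1)
        labels = np.array([lab for lab, _ in self.phases], dtype=object)
        return labels[idx]


@dataclass
class TrackSeries:
    """One camera view's tracked 2D positions per frame, with gaps as NaN."""

    view: str
    frame: np.ndarray          # int, strictly increasing, contiguous
    time_s: np.ndarray
    c1: np.ndarray             # first coordinate (x in both views)
    c2: np.ndarray             # y (ventral) or z (lateral)
    fps: float

    def __post_init__(self) -> None:
        if self.view not in VIEW_AXES:
            raise ValueError(f"unknown view {self.view!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.frame = np.asarray(self.frame, dtype=np.int64)
        if len(self.frame) and not np.array_equal(
                np.diff(self.frame), np.ones(len(self.frame) - 1, dtype=np.int64)):
            raise ValueError("frame indices must be contiguous and increasing")
        for name in ("time_s", "c1", "c2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def axes(self) -> tuple[str, str]:
        return VIEW_AXES[self.view]

    def copy(self) -> "TrackSeries":
        return replace(self, frame=self.frame.copy(), time_s=self.time_s.copy(),
                       c1=self.c1.copy(), c2=self.c2.copy())


@dataclass
class IntensityTrace:
    """Per-frame scalar brightness of the sync LED in one view."""

    frame: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.frame) != len(self.intensity):
            raise ValueError("frame and intensity must have equal length")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class Trajectory3D:
    """Synchronized, calibrated 3D swim path at uniform frame rate.

    ``xyz`` is an (n, 3) array in cm; ``phase`` holds a per-frame label
    (QT/ES, or "" before labelling); ``interpolated`` marks frames whose
    position was filled rather than observed.
    """

    time_s: np.ndarray
    xyz: np.ndarray
    phase: np.ndarray
    interpolated: np.ndarray
    fps: float
    tank: tuple[float, float, float]
    x_consistency_rms: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.time_s)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must be (n, 3)")
        if len(self.phase) != n or len(self.interpolated) != n:
            raise ValueError("per-frame arrays must share one length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if any(d <= 0 for d in self.tank):
            raise ValueError("tank dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def copy(self) -> "Trajectory3D":
        return replace(self, time_s=self.time_s.copy(), xyz=self.xyz.copy(),
                       phase=self.phase.copy(),
                       interpolated=self.interpolated.copy())
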