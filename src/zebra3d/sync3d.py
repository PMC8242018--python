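"""LED synchronization, two-view fusion, gap interpolation and smoothing.

The two cameras start recording at slightly different times, so the rig
flashes an LED visible in both views; the first frame where each view's
LED intensity jumps above its baseline defines a common time origin.
After re-indexing both views to that origin the streams are fused into a
3D path — x, y from the ventral view, z from the lateral view, with the
lateral view's redundant x kept only as a consistency diagnostic — then
gaps left by tracking dropouts are linearly interpolated and the path is
smoothed with a short moving average.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (LATERAL, VENTRAL, IntensityTrace, StimulusSchedule,
                   TrackSeries, Trajectory3D)

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_WINDOW = 30
DEFAULT_K_SIGMA = 5.0
DEFAULT_MAX_GAP_FRAMES = 60
DEFAULT_SMOOTH_WINDOW = 10


class LedDetectionError(RuntimeError):
    pass


class SynchronizationError(RuntimeError):
    pass


class GapError(RuntimeError):
    pass


def detect_led_on(trace: IntensityTrace,
                  baseline_window: int = DEFAULT_BASELINE_WINDOW,
                  k_sigma: float = DEFAULT_K_SIGMA) -> int:
    """First frame whose intensity exceeds baseline mean + k_sigma * SD.

    The baseline is the first ``baseline_window`` frames; the LED must
    switch on after that window, otherwise the threshold is degenerate.
    """
    if len(trace) <= baseline_window:
        raise LedDetectionError("trace shorter than baseline window")
    base = trace.intensity[:baseline_window]
    threshold = base.mean() + k_sigma * base.std(ddof=0)
    above = np.nonzero(trace.intensity > threshold)[0]
    if len(above) == 0:
        raise LedDetectionError("no frame exceeds the LED threshold")
    onset = int(above[0])
    if onset < baseline_window:
        raise LedDetectionError(
            "LED-on inside the baseline window; threshold degenerate")
    return onset


def synchronize(ventral: TrackSeries, lateral: TrackSeries,
                led_v: int, led_l: int) -> tuple[TrackSeries, TrackSeries]:
    """Re-index both views so frame 0 is each view's LED-on frame.

    Both streams are truncated to the shorter common length, leaving two
    equal-length, frame-aligned series.
    """
    if not 0 <= led_v < len(ventral):
        raise SynchronizationError("ventral LED frame outside the series")
    if not 0 <= led_l < len(lateral):
        raise SynchronizationError("lateral LED frame outside the series")
    n = min(len(ventral) - led_v, len(lateral) - led_l)
    if n <= 0:
        raise SynchronizationError("no overlapping frames after alignment")

    def cut(s: TrackSeries, start: int) -> TrackSeries:
        frames = np.arange(n)
        return TrackSeries(s.view, frames, frames / s.fps,
                           s.c1[start:start + n].copy(),
                           s.c2[start:start + n].copy(), s.fps)

    return cut(ventral, led_v), cut(lateral, led_l)


def calibrate(series: TrackSeries,
              bounds_1: tuple[float, float], bounds_2: tuple[float, float],
              extent_1: float, extent_2: float) -> TrackSeries:
    """Affine pixel-to-cm map sending configured pixel bounds to [0, extent].

    Bounds come from rig configuration (the tank's image footprint), never
    from the fish's observed excursion.
    """
    out = series.copy()
    for coord, (lo, hi), extent in ((out.c1, bounds_1, extent_1),
                                    (out.c2, bounds_2, extent_2)):
        if hi == lo:
            raise ValueError("zero-width pixel bounds")
        coord[:] = (coord - lo) / (hi - lo) * extent
    return out


def fuse_3d(ventral: TrackSeries, lateral: TrackSeries,
            tank: tuple[float, float, float]) -> Trajectory3D:
    """Fuse synchronized, calibrated views into a 3D trajectory.

    x and y come from the ventral view and z from the lateral view; the
    lateral view's redundant x is only compared against the ventral x and
    reported as an RMS consistency diagnostic.  A frame missing in either
    view is missing (NaN) on that view's axes in the fusion.
    """
    if len(ventral) != len(lateral):
        raise ValueError("views must be synchronized to equal length")
    n = len(ventral)
    xyz = np.column_stack([ventral.c1, ventral.c2, lateral.c2])
    both = ~np.isnan(ventral.c1) & ~np.isnan(lateral.c1)
    rms = None
    if both.any():
        rms = float(np.sqrt(np.mean((ventral.c1[both] - lateral.c1[both]) ** 2)))
        logger.info("shared-axis consistency RMS: %.4g cm over %d frames",
                    rms, int(both.sum()))
    return Trajectory3D(np.arange(n) / ventral.fps, xyz,
                        np.full(n, "", dtype=object),
                        np.zeros(n, dtype=bool), ventral.fps, tank,
                        x_consistency_rms=rms)


def label_phases(traj: Trajectory3D, schedule: StimulusSchedule,
                 offset_frames: int = 0) -> Trajectory3D:
    """Attach per-frame phase labels; schedule time 0 is the session start.

    ``offset_frames`` is the trajectory's frame 0 expressed in schedule
    frames — after LED synchronization, pass the detected ventral LED-on
    frame if the protocol started with the recording rather than the LED.
    """
    out = traj.copy()
    out.phase = schedule.labels_for_frames(out.n_frames, out.fps,
                                           offset_frames=offset_frames)
    return out


def interpolate_missing(traj: Trajectory3D,
                        max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES
                        ) -> Trajectory3D:
    """Fill NaN gaps up to ``max_gap_frames`` by per-axis linear interpolation.

    Observed frames are preserved bit-exactly; filled frames get the
    ``interpolated`` flag.  A gap longer than the limit, or a missing
    first/last frame on any axis, raises :class:`GapError`.
    """
    out = traj.copy()
    n = out.n_frames
    idx = np.arange(n)
    for axis in range(3):
        col = out.xyz[:, axis]
        missing = np.isnan(col)
        if not missing.any():
            continue
        if missing[0] or missing[-1]:
            raise GapError("first and last frames must be observed on every axis")
        # gap runs
        starts = np.nonzero(missing & ~np.roll(missing, 1))[0]
        ends = np.nonzero(missing & ~np.roll(missing, -1))[0]
        for s, e in zip(starts, ends):
            if e - s + 1 > max_gap_frames:
                raise GapError(
                    f"gap of {e - s + 1} frames at frames {s}..{e} exceeds "
                    f"max_gap_frames={max_gap_frames}")
        col[missing] = np.interp(idx[missing], idx[~missing], col[~missing])
        out.interpolated |= missing
    return out


def smooth(traj: Trajectory3D,
           window: int = DEFAULT_SMOOTH_WINDOW) -> Trajectory3D:
    """Centered moving average per axis; edges use the truncated window.

    Phase labels and interpolation flags are untouched.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > traj.n_frames:
        raise ValueError("window longer than trajectory")
    out = traj.copy()
    df = pd.DataFrame(out.xyz)
    out.xyz = df.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out


def _trim_missing_ends(traj: Trajectory3D) -> tuple[Trajectory3D, int]:
    """Drop leading/trailing frames with any missing axis.

    Interpolation needs observed endpoints; dropout can hit the very
    first or last synchronized frame, so those edges are trimmed rather
    than guessed.  Returns the trimmed trajectory and the number of
    frames removed from the front.
    """
    observed = ~np.isnan(traj.xyz).any(axis=1)
    if not observed.any():
        raise GapError("no fully observed frame to anchor interpolation")
    first = int(np.argmax(observed))
    last = int(len(observed) - 1 - np.argmax(observed[::-1]))
    if first == 0 and last == len(observed) - 1:
        return traj, 0
    sl = slice(first, last + 1)
    trimmed = Trajectory3D(np.arange(last + 1 - first) / traj.fps,
                           traj.xyz[sl].copy(), traj.phase[sl].copy(),
                           traj.interpolated[sl].copy(), traj.fps, traj.tank,
                           x_consistency_rms=traj.x_consistency_rms)
    return trimmed, first


def reconstruct(ventral: TrackSeries, lateral: TrackSeries,
                led_v_trace: IntensityTrace, led_l_trace: IntensityTrace,
                tank: tuple[float, float, float],
                schedule: StimulusSchedule | None = None,
                schedule_starts_at_frame0: bool = True,
                baseline_window: int = DEFAULT_BASELINE_WINDOW,
                k_sigma: float = DEFAULT_K_SIGMA,
                max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
                smooth_window: int | None = None,
                ) -> tuple[Trajectory3D, dict]:
    """Full reconstruction chain: detect LED, sync, fuse, label, interpolate.

    ``schedule_starts_at_frame0`` states whether the stimulus protocol
    began at the cameras' frame 0 (labels then need the LED offset) or at
    the LED event itself.  Smoothing is applied only when
    ``smooth_window`` is given, so round-trip checks can stay exact.
    Returns the trajectory and a diagnostics dict (LED frames, recovered
    inter-camera offset, shared-axis RMS).
    """
    led_v = detect_led_on(led_v_trace, baseline_window, k_sigma)
    led_l = detect_led_on(led_l_trace, baseline_window, k_sigma)
    sv, sl = synchronize(ventral, lateral, led_v, led_l)
    traj = fuse_3d(sv, sl, tank)
    traj, trim_start = _trim_missing_ends(traj)
    if schedule is not None:
        offset = (led_v if schedule_starts_at_frame0 else 0) + trim_start
        traj = label_phases(traj, schedule, offset_frames=offset)
    if np.isnan(traj.xyz).any():
        traj = interpolate_missing(traj, max_gap_frames)
    if smooth_window is not None:
        traj = smooth(traj, smooth_window)
    diag = {"led_v": led_v, "led_l": led_l, "offset": led_l - led_v,
            "x_consistency_rms": traj.x_consistency_rms}
    return traj, diag
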