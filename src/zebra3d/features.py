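"""Trajectory segmentation and feature extraction for clustering.

A trajectory is cut into fixed-duration, phase-pure segments (windows
never straddle a QT/ES boundary).  Each segment yields two
representations:

* a raw spatiotemporal vector — the path resampled to ``n_resample``
  equal-time points, encoded as per-interval displacements (Delta x,
  Delta y, Delta z) plus the absolute depth profile (z values), i.e.
  translation-invariant in the horizontal plane while keeping the
  behaviorally meaningful top/bottom preference;
* a traditional kinematic profile (turn angle, turning rate, distance
  in top, average speed, total distance, time-in-top ratio) used for
  after-the-fact validation of discovered clusters, not as clustering
  input.

Vectors are PCA-reduced (centered, not variance-scaled — all columns are
in cm) to the smallest component count reaching a target cumulative
explained variance, then min-max rescaled into [0, 1] as the clustering
algorithm requires.  Fitted states transform held-out segments without
refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core import Trajectory3D

logger = logging.getLogger(__name__)

DEFAULT_N_RESAMPLE = 50
DEFAULT_CUM_VAR = 0.72

#: horizontal step shorter than this contributes zero turn angle
_MIN_TURN_STEP_CM = 1e-6

PROFILE_FIELDS = ("turn_angle", "turning_rate", "distance_top",
                  "average_speed", "distance_total", "time_top_ratio")


@dataclass
class Segment:
    """A fixed-duration, phase-pure window of one fish's 3D trajectory."""

    fish_id: int
    phase: str
    start_s: float
    duration_s: float
    xyz: np.ndarray            # (n_frames, 3) cm
    fps: float

    @property
    def n_frames(self) -> int:
        return len(self.xyz)


@dataclass(frozen=True)
class BehaviorProfile:
    """Traditional per-segment kinematic readouts.

    turn_angle      deg, mean absolute turn per interior step
    turning_rate    deg/s, summed absolute turning over the segment
    distance_top    cm travelled while in the tank's upper half
    average_speed   cm/s
    distance_total  cm (3D path length)
    time_top_ratio  fraction of frames at or above the top threshold
    """

    turn_angle: float
    turning_rate: float
    distance_top: float
    average_speed: float
    distance_total: float
    time_top_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS])


def segment_trajectory(traj: Trajectory3D, seg_len_s: float,
                       fish_id: int = 0) -> list[Segment]:
    """Cut each maximal constant-phase run into consecutive windows.

    Windows are ``seg_len_s`` long, non-overlapping, anchored at the
    run's start; a trailing remainder shorter than one window is
    dropped.  Raises if no phase run can host even one window.
    """
    if seg_len_s <= 0:
        raise ValueError("seg_len_s must be positive")
    seg_frames = int(round(seg_len_s * traj.fps))
    if seg_frames < 2:
        raise ValueError("segment too short for the frame rate")
    phase = traj.phase
    n = traj.n_frames
    segments: list[Segment] = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or phase[i] != phase[run_start]:
            run_len = i - run_start
            for w in range(run_len // seg_frames):
                s = run_start + w * seg_frames
                segments.append(Segment(
                    fish_id=fish_id, phase=str(phase[run_start]),
                    start_s=traj.time_s[s], duration_s=seg_len_s,
                    xyz=traj.xyz[s:s + seg_frames].copy(), fps=traj.fps))
            run_start = i
    if not segments:
        raise ValueError(
            f"no phase run long enough for {seg_len_s} s segments")
    return segments


def kinematic_profile(seg: Segment, top_threshold: float) -> BehaviorProfile:
    """Compute the six traditional kinematic parameters for one segment.

    Turn angles are measured between consecutive horizontal (x, y) step
    vectors; steps shorter than 1e-6 cm in the horizontal plane
    contribute zero turn.  "Top" is z >= ``top_threshold`` (typically
    half the tank height).
    """
    if seg.n_frames < 3:
        raise ValueError("need at least 3 frames for a kinematic profile")
    steps = np.diff(seg.xyz, axis=0)                    # (n-1, 3)
    step_len = np.linalg.norm(steps, axis=1)
    distance_total = float(step_len.sum())
    # rates use the time spanned by the steps, so constant-speed paths
    # report their speed exactly
    elapsed = (seg.n_frames - 1) / seg.fps
    average_speed = distance_total / elapsed

    h = steps[:, :2]
    h_len = np.linalg.norm(h, axis=1)
    a, b = h[:-1], h[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    degenerate = (h_len[:-1] < _MIN_TURN_STEP_CM) | (h_len[1:] < _MIN_TURN_STEP_CM)
    ang[degenerate] = 0.0
    abs_ang = np.abs(ang)

    in_top = seg.xyz[:, 2] >= top_threshold
    distance_top = float(step_len[in_top[:-1]].sum())
    return BehaviorProfile(
        turn_angle=float(abs_ang.mean()),
        turning_rate=float(abs_ang.sum() / elapsed),
        distance_top=distance_top,
        average_speed=float(average_speed),
        distance_total=distance_total,
        time_top_ratio=float(in_top.mean()),
    )


def spatiotemporal_vector(seg: Segment,
                          n_resample: int = DEFAULT_N_RESAMPLE) -> np.ndarray:
    """Fixed-length path encoding fed to PCA and clustering.

    The path is linearly resampled to ``n_resample`` equal-time points;
    the vector concatenates the (n_resample - 1) displacement triples
    with the n_resample absolute z values, length 4*n_resample - 3.
    """
    if seg.n_frames == 0:
        raise ValueError("empty segment")
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    t = np.arange(seg.n_frames, dtype=float)
    tq = np.linspace(0.0, seg.n_frames - 1, n_resample)
    resampled = np.column_stack(
        [np.interp(tq, t, seg.xyz[:, k]) for k in range(3)])
    disp = np.diff(resampled, axis=0)
    return np.concatenate([disp.ravel(), resampled[:, 2]])


def feature_matrix(segments: list[Segment],
                   n_resample: int = DEFAULT_N_RESAMPLE) -> np.ndarray:
    return np.array([spatiotemporal_vector(s, n_resample) for s in segments])


@dataclass
class PCAState:
    mean: np.ndarray
    components: np.ndarray         # (k, d)
    explained_variance_ratio: np.ndarray
    k: int
    n_fit_rows: int


def fit_pca(X: np.ndarray, target_cum_var: float = DEFAULT_CUM_VAR
            ) -> tuple[np.ndarray, PCAState]:
    """Center columns and keep the fewest components reaching the target.

    Returns the training scores and the fitted state; scores come from
    the same SVD that chose k, so re-transforming the training rows
    reproduces them exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not 0 < target_cum_var <= 1:
        raise ValueError("target_cum_var must be in (0, 1]")
    pca = PCA(n_components=None, svd_solver="full").fit(X)
    ratios = pca.explained_variance_ratio_
    if ratios.sum() <= 0 or not np.isfinite(ratios).all():
        raise ValueError("matrix has no variance to decompose")
    cum = np.cumsum(ratios)
    reach = np.nonzero(cum >= target_cum_var - 1e-12)[0]
    k = int(reach[0]) + 1 if len(reach) else len(ratios)
    state = PCAState(mean=pca.mean_.copy(), components=pca.components_[:k].copy(),
                     explained_variance_ratio=ratios.copy(), k=k,
                     n_fit_rows=X.shape[0])
    return transform_pca(state, X), state


def transform_pca(state: PCAState, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != state.mean.shape[0]:
        raise ValueError("column count does not match the fitted state")
    return (X - state.mean) @ state.components.T


@dataclass
class UnitScaler:
    """Min-max map of training columns onto [0, 1].

    Constant training columns map to 0.5; held-out values outside the
    training range are clipped into [0, 1] and the clips are counted.
    """

    col_min: np.ndarray
    col_range: np.ndarray          # 0 marks a constant column
    n_fit_rows: int
    n_clipped: int = field(default=0)

    def transform(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        const = self.col_range == 0
        safe = np.where(const, 1.0, self.col_range)
        out = (X - self.col_min) / safe
        out[:, const] = 0.5
        if clip:
            n_out = int(((out < 0) | (out > 1)).sum())
            if n_out:
                self.n_clipped += n_out
                logger.info("clipped %d out-of-range feature values", n_out)
            out = np.clip(out, 0.0, 1.0)
        return out


def rescale_unit(X: np.ndarray) -> tuple[np.ndarray, UnitScaler]:
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng < 1e-12, 0.0, rng)
    scaler = UnitScaler(col_min=lo, col_range=rng, n_fit_rows=X.shape[0])
    return scaler.transform(X, clip=False), scaler


def transform_unit(scaler: UnitScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X, clip=True)


@dataclass
class FeaturePipeline:
    """Fitted segment -> [0, 1] feature chain (resample, PCA, rescale).

    Fit on training segments only; ``transform`` pushes new segments
    through the stored state without refitting, preserving the
    train/test separation.
    """

    n_resample: int
    pca: PCAState
    scaler: UnitScaler

    @property
    def n_fit_rows(self) -> int:
        return self.pca.n_fit_rows

    @classmethod
    def fit(cls, segments: list[Segment],
            target_cum_var: float = DEFAULT_CUM_VAR,
            n_resample: int = DEFAULT_N_RESAMPLE
            ) -> tuple[np.ndarray, "FeaturePipeline"]:
        X = feature_matrix(segments, n_resample)
        scores, pca_state = fit_pca(X, target_cum_var)
        X01, scaler = rescale_unit(scores)
        return X01, cls(n_resample=n_resample, pca=pca_state, scaler=scaler)

    def transform(self, segments: list[Segment]) -> np.ndarray:
        X = feature_matrix(segments, self.n_resample)
        return transform_unit(self.scaler, transform_pca(self.pca, X))
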