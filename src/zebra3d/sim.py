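"""Synthetic two-view zebrafish tracking data with known ground truth.

The generator emulates the recording rig: one adult fish in a
20 x 20 x 20 cm tank filmed at 60 fps by a ventral camera (x-y) and a
lateral camera (x-z), under an alternating 30 s quiescent (QT) /
30 s electric-stimulus (ES) schedule.  Motion is a correlated random
walk whose parameters differ by phase, so ES segments carry an injected
motif (typically higher speed and broader turning) that the downstream
clustering should rediscover.  The two views are emitted with a
configurable frame offset, a shared LED-on event visible in both
intensity traces, and i.i.d. per-frame dropout, so the full
reconstruction chain is exercised end to end.

Everything is deterministic given (seed, fish_id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (LATERAL, PHASE_ES, PHASE_QT, VENTRAL, IntensityTrace,
                   StimulusSchedule, TrackSeries, Trajectory3D)

LED_BASELINE = 10.0
LED_ON_LEVEL = 200.0
LED_NOISE_SD = 1.0

#: vertical swim-speed amplitude, as a fraction of the phase's mean
#: speed: an agitated fish moves faster in all three dimensions, so
#: vertical excursions scale with the phase's overall activity
_VERTICAL_SPEED_FRAC = 0.35

#: persistence time of the vertical velocity (s); glides up or down last
#: about this long before reversing
_VERTICAL_VELOCITY_TAU_S = 0.5

#: initial depth band around mid-water, as a fraction of tank height
_INITIAL_DEPTH_BAND = 0.0

#: depth-keeping: vertical position mean-reverts toward the fish's
#: preferred depth at this rate (1/s), so depth excursions stay bounded
#: no matter how long the session runs
_DEPTH_REVERSION_PER_S = 0.5


@dataclass(frozen=True)
class MotionParams:
    """Phase-specific correlated-random-walk parameters.

    mean_speed        cm/s; mean of the gamma-distributed horizontal
                      per-step speed (vertical agitation scales with it).
    speed_dispersion  gamma shape parameter (larger = tighter around mean).
    turn_concentration  concentration of the heading perturbation; the
                      per-step turn is wrapped-normal with
                      sd = 1/sqrt(concentration) rad (0 = uniform heading).
    vertical_bias     cm/s drift toward the top (+) or bottom (-).
    """

    mean_speed: float = 3.0
    speed_dispersion: float = 2.0
    turn_concentration: float = 8.0
    vertical_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.speed_dispersion <= 0:
            raise ValueError("speed_dispersion must be > 0")
        if self.turn_concentration < 0:
            raise ValueError("turn_concentration must be >= 0")


def default_motion() -> dict[str, MotionParams]:
    """Study conditions: ES swims ~3x faster with broader turning than QT."""
    return {
        PHASE_QT: MotionParams(mean_speed=3.0, speed_dispersion=2.0,
                               turn_concentration=8.0, vertical_bias=0.0),
        PHASE_ES: MotionParams(mean_speed=9.0, speed_dispersion=2.0,
                               turn_concentration=2.0, vertical_bias=0.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated recording session."""

    n_fish: int = 10
    fps: float = 60.0
    tank: tuple[float, float, float] = (20.0, 20.0, 20.0)
    schedule: StimulusSchedule = field(
        default_factory=lambda: StimulusSchedule.alternating(30.0, 30.0, 1))
    motion: dict[str, MotionParams] = field(default_factory=default_motion)
    lateral_frame_offset: int = 0
    dropout_rate: float = 0.0
    led_on_frame: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if any(d <= 0 for d in self.tank):
            raise ValueError("tank dimensions must be positive")
        if not 0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5)")
        if self.lateral_frame_offset < 0:
            raise ValueError("lateral_frame_offset must be >= 0")
        if self.led_on_frame < 0:
            raise ValueError("led_on_frame must be >= 0")
        if self.schedule.total_duration <= 0:
            raise ValueError("schedule must have positive duration")
        for label in (PHASE_QT, PHASE_ES):
            if label not in self.motion:
                raise ValueError(f"motion parameters missing for {label}")


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([seed, *streams])


def _reflect(value: float, lo: float, hi: float) -> tuple[float, int]:
    """Fold a coordinate into [lo, hi] by specular reflection.

    Returns the folded value and the parity of reflections (odd parity
    means the travel direction along this axis flipped).
    """
    parity = 0
    span = hi - lo
    while value < lo or value > hi:
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
        parity ^= 1
        if span <= 0:          # degenerate, cannot happen with valid tanks
            break
    return value, parity


def simulate_trajectory(config: SimConfig, fish_id: int = 0) -> Trajectory3D:
    """Generate one fish's ground-truth 3D path as a correlated random walk.

    Per step, speed is gamma-distributed with the current phase's mean and
    shape, and the horizontal heading receives a wrapped-normal
    perturbation.  Vertically the fish keeps depth: its vertical velocity
    is a persistent (AR(1), ~0.5 s) process whose amplitude scales with
    the phase's mean speed — an agitated fish moves faster in all three
    dimensions — plus ``vertical_bias`` drift, while depth mean-reverts
    toward the starting (mid-water) depth so excursions stay bounded for
    arbitrarily long sessions.  A zero-speed phase is perfectly still.
    Walls reflect specularly, mirroring the heading, so the fish never
    sticks to a boundary.
    """
    fps = config.fps
    n = int(np.ceil(config.schedule.total_duration * fps))
    if n <= 0:
        raise ValueError("schedule yields no frames")
    phase = config.schedule.labels_for_frames(n, fps)

    rng = _rng(config.seed, 1, int(fish_id))
    L, W, H = config.tank
    pos = np.empty((n, 3))
    band = _INITIAL_DEPTH_BAND * H
    pos[0] = rng.uniform([0.0, 0.0, H / 2 - band], [L, W, H / 2 + band])
    theta = rng.uniform(-np.pi, np.pi)

    # per-step draws (step t moves frame t -> t+1, under phase[t])
    shape = np.empty(n - 1)
    scale = np.empty(n - 1)
    turn_sd = np.empty(n - 1)
    uniform_turn = np.zeros(n - 1, dtype=bool)
    vbias = np.empty(n - 1)
    vnoise_sd = np.empty(n - 1)
    for label, mp in config.motion.items():
        m = phase[:-1] == label
        shape[m] = mp.speed_dispersion
        scale[m] = mp.mean_speed / mp.speed_dispersion
        if mp.turn_concentration > 0:
            turn_sd[m] = 1.0 / np.sqrt(mp.turn_concentration)
        else:
            turn_sd[m] = 0.0
            uniform_turn[m] = True
        vbias[m] = mp.vertical_bias
        vnoise_sd[m] = _VERTICAL_SPEED_FRAC * mp.mean_speed

    speeds = rng.gamma(shape, scale)
    dthetas = rng.normal(0.0, turn_sd)
    dthetas[uniform_turn] = rng.uniform(-np.pi, np.pi, uniform_turn.sum())
    vz_innov = rng.normal(0.0, 1.0, n - 1)

    dt = 1.0 / fps
    x, y, z = pos[0]
    z_pref = pos[0, 2]
    rev = _DEPTH_REVERSION_PER_S
    # vertical velocity: AR(1) with ~_VERTICAL_VELOCITY_TAU_S persistence
    # and per-phase stationary amplitude vnoise_sd
    a_vz = float(np.exp(-dt / _VERTICAL_VELOCITY_TAU_S))
    b_vz = float(np.sqrt(1.0 - a_vz ** 2))
    v_z = 0.0
    for t in range(n - 1):
        theta += dthetas[t]
        v_z = a_vz * v_z + b_vz * vnoise_sd[t] * vz_innov[t]
        step = speeds[t] * dt
        x_new = x + step * np.cos(theta)
        y_new = y + step * np.sin(theta)
        z_new = z + (vbias[t] + v_z + rev * (z_pref - z)) * dt
        x_new, px = _reflect(x_new, 0.0, L)
        y_new, py = _reflect(y_new, 0.0, W)
        z_new, _ = _reflect(z_new, 0.0, H)
        if px:
            theta = np.pi - theta
        if py:
            theta = -theta
        x, y, z = x_new, y_new, z_new
        pos[t + 1] = (x, y, z)

    return Trajectory3D(
        time_s=np.arange(n) / fps, xyz=pos, phase=phase,
        interpolated=np.zeros(n, dtype=bool), fps=fps, tank=config.tank)


def _led_trace(n: int, on_frame: int, rng: np.random.Generator) -> IntensityTrace:
    intensity = rng.normal(LED_BASELINE, LED_NOISE_SD, n)
    if on_frame < n:
        intensity[on_frame:] = rng.normal(LED_ON_LEVEL, LED_NOISE_SD,
                                          n - on_frame)
    return IntensityTrace(frame=np.arange(n), intensity=intensity)


def project_views(traj: Trajectory3D, config: SimConfig, fish_id: int = 0
                  ) -> tuple[TrackSeries, TrackSeries, IntensityTrace, IntensityTrace]:
    """Render the 3D path as the two camera exports plus LED traces.

    The ventral view reports (x, y); the lateral view reports (x, z)
    delayed by ``lateral_frame_offset`` frames, its leading frames padded
    with the pre-path stationary position (frame 0).  Each view
    independently loses ``dropout_rate`` of its frames (NaN positions),
    and each LED trace steps from baseline to the on level at that view's
    LED-on frame.
    """
    n = traj.n_frames
    if abs(n - int(np.ceil(config.schedule.total_duration * config.fps))) > 0:
        raise ValueError("trajectory length inconsistent with config schedule")
    off = config.lateral_frame_offset
    rng = _rng(config.seed, 2, int(fish_id))

    vx = traj.xyz[:, 0].copy()
    vy = traj.xyz[:, 1].copy()
    lx = np.empty(n)
    lz = np.empty(n)
    lx[:off] = traj.xyz[0, 0]
    lz[:off] = traj.xyz[0, 2]
    m = n - off
    lx[off:] = traj.xyz[:m, 0]
    lz[off:] = traj.xyz[:m, 2]

    drop_v = rng.random(n) < config.dropout_rate
    drop_l = rng.random(n) < config.dropout_rate
    vx[drop_v] = np.nan
    vy[drop_v] = np.nan
    lx[drop_l] = np.nan
    lz[drop_l] = np.nan

    frames = np.arange(n)
    time_s = frames / config.fps
    ventral = TrackSeries(VENTRAL, frames, time_s, vx, vy, config.fps)
    lateral = TrackSeries(LATERAL, frames.copy(), time_s.copy(), lx, lz,
                          config.fps)
    led_v = _led_trace(n, config.led_on_frame, rng)
    led_l = _led_trace(n, config.led_on_frame + off, rng)
    return ventral, lateral, led_v, led_l


def simulate_session(config: SimConfig) -> list[dict]:
    """Simulate every fish in the session; one record per fish.

    Each record holds the ground-truth trajectory plus the two projected
    views and LED traces, keyed ``traj, ventral, lateral, led_v, led_l``.
    """
    out = []
    for fish in range(config.n_fish):
        traj = simulate_trajectory(config, fish)
        ventral, lateral, led_v, led_l = project_views(traj, config, fish)
        out.append({"fish_id": fish, "traj": traj, "ventral": ventral,
                    "lateral": lateral, "led_v": led_v, "led_l": led_l})
    return out
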