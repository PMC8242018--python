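"""Reconstruct a 3D swim path from the two synthetic camera views.

The lateral camera starts 17 frames late; the LED flash visible in both
views recovers that offset exactly, the views are fused (x, y from the
ventral view, z from the lateral one), 5% dropout gaps are linearly
interpolated, and the result is compared frame-by-frame against the
generator's ground truth.
"""

import numpy as np

from zebra3d import SimConfig, StimulusSchedule, project_views, simulate_trajectory
from zebra3d.sync3d import reconstruct

cfg = SimConfig(n_fish=1, schedule=StimulusSchedule.alternating(30, 30, 2),
                lateral_frame_offset=17, dropout_rate=0.05,
                led_on_frame=150, seed=42)
traj = simulate_trajectory(cfg, 0)
views = project_views(traj, cfg, 0)

rec, diag = reconstruct(*views, cfg.tank, schedule=cfg.schedule)
print(f"detected LED frames: ventral {diag['led_v']}, lateral {diag['led_l']}")
print(f"recovered camera offset: {diag['offset']} frames (configured "
      f"{cfg.lateral_frame_offset})")
print(f"shared-axis consistency RMS: {diag['x_consistency_rms']:.2e} cm "
      f"(0 = both cameras agree on x)")

offs = next(i for i in range(300)
            if np.allclose(rec.xyz[0], traj.xyz[i], atol=1e-6))
rmse = np.sqrt(np.mean((rec.xyz - traj.xyz[offs:offs + rec.n_frames]) ** 2))
print(f"RMSE vs ground truth after interpolation: {rmse:.4f} cm "
      f"({rec.interpolated.mean():.1%} of frames interpolated)")
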