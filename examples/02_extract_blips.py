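"""Learn the background and extract blips from a simulated scene.

Shows the full detection chain: pooled mean / mean-absolute-deviation
background over the learning scans, z-score thresholding, patch grouping,
and size filtering.  Prints per-scan blip counts and the properties of one
blip next to the matching ground truth.
"""

import math

from aeroscan import (BlipFilters, ClutterSpec, ExtractionParams, ScanMeta,
                      SceneConfig, TargetSpec, learn_background,
                      simulate_scene)
from aeroscan.blips import extract_blips

meta = ScanMeta(t0=0.0, n_pulses=256, n_samples=256, rate_hz=50e6,
                duration_s=2.4)
scene = SceneConfig(
    meta_template=meta, n_scans=10,
    targets=[TargetSpec(id=1, x0=200, y0=100, vx=8, vy=4, amplitude=150,
                        psf_sigma_r_m=4, psf_sigma_az_deg=1.5)],
    clutter=ClutterSpec(noise_mean=40, noise_scale=8), seed=7)
scans, truth = simulate_scene(scene)

params = ExtractionParams(z_thresh=4.0, learn_scans=3,
                          filters=BlipFilters(min_n_samples=4))
bg = learn_background(scans[:3], params.grid)
print(f"background learned from 3 scans: mean of m = {bg.m.mean():.1f}, "
      f"mean of d = {bg.d.mean():.2f} (digitizer units)")

for s_idx in range(3, 10):
    blips, bg = extract_blips(scans[s_idx], bg, params)
    print(f"scan {s_idx}: {len(blips)} blip(s)")
    if s_idx == 5:
        b = blips[0]
        row = truth[truth.scan == 5].iloc[0]
        err = math.hypot(b.x - row.x, b.y - row.y)
        print(f"  blip centroid ({b.x:7.1f}, {b.y:7.1f}) m, "
              f"{b.n_samples} samples, area {b.area_m2:.1f} m^2, "
              f"peak {b.int_max:.0f}")
        print(f"  truth          ({row.x:7.1f}, {row.y:7.1f}) m -> "
              f"centroid error {err:.1f} m")
# The centroid error should be well below the ~4 m cell size: the
# intensity-weighted centroid localizes the target to sub-cell precision.
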