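import math

import numpy as np
import pytest

from aeroscan import (Blip, ClutterSpec, ExtractionParams, BlipFilters,
                      Scan, ScanMeta, SceneConfig, TargetSpec,
                      learn_background, simulate_scene)


@pytest.fixture
def small_meta():
    return ScanMeta(t0=0.0, n_pulses=64, n_samples=48, rate_hz=50e6,
                    duration_s=2.0)


def make_blip(x, y, t, z=0.0, area=10.0, int_mean=100.0, n_samples=4):
    """Hand-built blip for tracking tests (cells are placeholders)."""
    return Blip(cells=[(0, 0, 100)], t=t, x=x, y=y, z=z,
                n_samples=n_samples, area_m2=area, perimeter_cells=4,
                int_mean=int_mean, int_max=int_mean * 1.2,
                angular_span_deg=1.0, radial_span_m=3.0)


@pytest.fixture
def blip_factory():
    return make_blip


def default_scene(n_scans=25, seed=3, n_pulses=1024, n_samples=512):
    """The reference validation scene: three constant-velocity point
    targets at amplitude 10x the noise scale over exponential clutter.

    The first 5 scans are the background learning period; 20 scans are
    processed.
    """
    meta = ScanMeta(t0=0.0, n_pulses=n_pulses, n_samples=n_samples,
                    rate_hz=50e6, duration_s=2.4)
    targets = [
        TargetSpec(id=1, x0=-500, y0=300, vx=10, vy=2, amplitude=80,
                   psf_sigma_r_m=4, psf_sigma_az_deg=0.7),
        TargetSpec(id=2, x0=400, y0=-600, vx=-6, vy=8, amplitude=80,
                   psf_sigma_r_m=4, psf_sigma_az_deg=0.7),
        TargetSpec(id=3, x0=100, y0=900, vx=4, vy=-9, amplitude=80,
                   psf_sigma_r_m=4, psf_sigma_az_deg=0.7),
    ]
    return SceneConfig(meta_template=meta, n_scans=n_scans, targets=targets,
                       clutter=ClutterSpec(noise_mean=40, noise_scale=8),
                       seed=seed)


SCENE_LEARN_SCANS = 5
SCENE_PARAMS = dict(z_thresh=4.0, learn_scans=SCENE_LEARN_SCANS)


@pytest.fixture(scope="session")
def reference_scene():
    """Simulated scene + extracted per-scan blips, shared across tests."""
    from aeroscan.blips import extract_blips

    cfg = default_scene()
    scans, truth = simulate_scene(cfg)
    params = ExtractionParams(filters=BlipFilters(min_n_samples=8),
                              **SCENE_PARAMS)
    bg = learn_background(scans[:SCENE_LEARN_SCANS], params.grid)
    per_scan = {}
    for s_idx in range(SCENE_LEARN_SCANS, cfg.n_scans):
        blips, bg = extract_blips(scans[s_idx], bg, params)
        per_scan[s_idx] = blips
    return {"config": cfg, "scans": scans, "truth": truth,
            "per_scan_blips": per_scan, "learn_scans": SCENE_LEARN_SCANS}
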