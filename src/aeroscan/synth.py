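"""Seeded synthetic radar scenes with known ground truth.

Generates sequences of polar scans that emulate what a blip-extraction and
tracking pipeline has to cope with in the field: a one-sided receiver noise
floor, spatially structured clutter (a sea-clutter azimuth sector with
inflated noise scale, a rain blob with an additive pedestal), and point
targets moving on smooth trajectories whose true positions and polar cells
are recorded per scan.

The noise model is a shifted exponential (Rayleigh-power-like): one-sided,
like real clutter intensity, and expressed directly in digitizer units so no
power calibration is involved.  Target amplitude is constant with range by
default (no 1/r^4 law) so detection tests decouple from radiometry; an
optional range power-law exponent is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scan import (PolarGeometry, Scan, ScanMeta, azimuth_of_pulse,
                   polar_to_xyz, range_of_sample, sample_range,
                   DigitizerProfile)


@dataclass
class TargetSpec:
    """A point target on a constant-velocity or constant-turn trajectory.

    Positions are metres east/north of the radar; amplitude is the peak
    sample value added above background, in digitizer units.  The Gaussian
    point-spread widths model pulse length (range) and beam width (azimuth).
    """

    id: int
    x0: float
    y0: float
    vx: float
    vy: float
    turn_rate_deg_s: float = 0.0
    amplitude: float = 200.0
    psf_sigma_r_m: float = 3.0
    psf_sigma_az_deg: float = 0.5
    range_power_exp: float = 0.0
    ref_range_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.psf_sigma_r_m <= 0 or self.psf_sigma_az_deg <= 0:
            raise ValueError("psf widths must be positive")


@dataclass
class ClutterSpec:
    """Background noise and structured clutter parameters (digitizer units).

    Each sample is noise_mean + Exponential(noise_scale), one-sided.  An
    optional sea sector (az_lo, az_hi, extra_scale) multiplies the noise
    scale inside an azimuth wedge; an optional rain blob (x, y, radius_m,
    extra_mean) adds a constant pedestal inside a disc.
    """

    noise_mean: float = 40.0
    noise_scale: float = 8.0
    sea_sector: Optional[tuple[float, float, float]] = None
    rain_blob: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class SceneConfig:
    meta_template: ScanMeta
    n_scans: int
    targets: list[TargetSpec] = field(default_factory=list)
    clutter: ClutterSpec = field(default_factory=ClutterSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


#: Ground-truth table columns, one row per (scan, target).
TRUTH_COLUMNS = ("scan", "target_id", "t", "x", "y", "row", "col", "in_range")


def _sector_mask_cols(meta: ScanMeta, az_lo: float, az_hi: float) -> np.ndarray:
    az = azimuth_of_pulse(np.arange(meta.n_pulses), meta)
    lo, hi = az_lo % 360.0, az_hi % 360.0
    if lo <= hi:
        return (az >= lo) & (az < hi)
    return (az >= lo) | (az < hi)


def gen_noise(meta: ScanMeta, clutter: ClutterSpec, seed) -> Scan:
    """Generate one scan of pure noise/clutter (no targets).

    value = round(clip(noise_mean + Exp(scale * sector multiplier)
    + additive terms, 0, 2**bits - 1)); the same seed always yields a
    bitwise-identical scan.
    """
    rng = np.random.default_rng(seed)
    shape = (meta.n_samples, meta.n_pulses)
    scale = np.full(shape, float(clutter.noise_scale))
    add = np.zeros(shape)
    if clutter.sea_sector is not None:
        az_lo, az_hi, extra = clutter.sea_sector
        cols = _sector_mask_cols(meta, az_lo, az_hi)
        scale[:, cols] *= extra
    if clutter.rain_blob is not None:
        bx, by, radius, extra_mean = clutter.rain_blob
        geom = PolarGeometry.from_meta(meta)
        r = range_of_sample(np.arange(meta.n_samples), geom)
        az = np.deg2rad(azimuth_of_pulse(np.arange(meta.n_pulses), meta))
        cx = r[:, None] * np.sin(az)[None, :]
        cy = r[:, None] * np.cos(az)[None, :]
        inside = (cx - bx) ** 2 + (cy - by) ** 2 <= radius ** 2
        add[inside] += extra_mean
    vmax = 2 ** meta.bits - 1
    raw = clutter.noise_mean + rng.exponential(1.0, size=shape) * scale + add
    data = np.round(np.clip(raw, 0, vmax)).astype(np.uint16)
    return Scan(meta=meta, data=data)


def target_position(spec: TargetSpec, t: float) -> tuple[float, float]:
    """Target position at time ``t`` seconds after the scene start.

    Zero turn rate gives straight constant-velocity motion; a nonzero turn
    rate gives a circular arc at constant speed (closed form).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = math.radians(spec.turn_rate_deg_s)
    if w == 0.0:
        return (spec.x0 + spec.vx * t, spec.y0 + spec.vy * t)
    s, c = math.sin(w * t), math.cos(w * t)
    x = spec.x0 + (spec.vx * s + spec.vy * (c - 1.0)) / w
    y = spec.y0 + (-spec.vx * (c - 1.0) + spec.vy * s) / w
    return (x, y)


def _polar_of_xy(x: float, y: float, meta: ScanMeta) -> tuple[float, float]:
    """(slant range m, azimuth deg) of a ground point, beam-plane geometry."""
    el = math.radians(meta.antenna.elev_deg)
    g = math.hypot(x, y)
    r = g / math.cos(el) if math.cos(el) > 1e-12 else math.inf
    az = math.degrees(math.atan2(x, y)) % 360.0
    return r, az


def _cell_of_polar(r: float, az: float, meta: ScanMeta,
                   geom: PolarGeometry) -> tuple[int, int, bool]:
    row = int(r // geom.dr_m)
    col = int(((az - meta.heading_deg) % 360.0) // geom.dtheta_deg) \
        % meta.n_pulses
    ok = 0 <= row < meta.n_samples
    return row, col, ok


def crossing_time(spec: TargetSpec, meta: ScanMeta, t0_rel: float,
                  n_iter: int = 4) -> float:
    """Time (relative to scene start) at which the beam crosses the target
    during the scan starting at ``t0_rel``.

    Solved by fixed-point iteration: position -> azimuth -> pulse time.
    Converges in a few steps for targets much slower than the beam sweep.
    """
    geom = PolarGeometry.from_meta(meta)
    t = t0_rel + meta.duration_s / 2.0
    for _ in range(n_iter):
        x, y = target_position(spec, t)
        _, az = _polar_of_xy(x, y, meta)
        j = ((az - meta.heading_deg) % 360.0) / geom.dtheta_deg
        t = t0_rel + (j % meta.n_pulses) * meta.duration_s / meta.n_pulses
    return t


def render_target(scan: Scan, pos: tuple[float, float], spec: TargetSpec,
                  t_pos: Optional[float] = None,
                  t0_rel: float = 0.0) -> bool:
    """Additively render a target into a scan (in place).

    Adds round(amplitude * exp(-dr^2/2sr^2 - dth^2/2sth^2)) to every cell
    within 3 sigma in range and azimuth, clipping at the bit-depth maximum;
    azimuth differences wrap across the 0/360 seam.  When ``t_pos`` is given
    the target is re-evaluated at each pulse's transmit time so fast targets
    smear across columns realistically.  Returns False (no-op) when the
    position falls beyond the maximum range.
    """
    if spec.amplitude == 0:
        return True
    meta = scan.meta
    geom = PolarGeometry.from_meta(meta)
    rmax = meta.n_samples * geom.dr_m
    r0, az0 = _polar_of_xy(pos[0], pos[1], meta)
    if not (0 <= r0 < rmax):
        return False
    vmax = 2 ** meta.bits - 1

    ncols3 = int(math.ceil(3.0 * spec.psf_sigma_az_deg / geom.dtheta_deg))
    speed = math.hypot(spec.vx, spec.vy)
    if t_pos is not None and r0 > 0:
        smear_deg = math.degrees(speed * meta.duration_s / (2 * math.pi * r0))
        ncols3 += int(math.ceil(smear_deg / geom.dtheta_deg)) + 1
    j0 = int(round(((az0 - meta.heading_deg) % 360.0) / geom.dtheta_deg))
    cols = (j0 + np.arange(-ncols3, ncols3 + 1)) % meta.n_pulses

    amp = spec.amplitude
    if spec.range_power_exp != 0.0 and r0 > 0:
        amp = amp * (spec.ref_range_m / r0) ** spec.range_power_exp

    rows_all = np.arange(meta.n_samples)
    r_centers = range_of_sample(rows_all, geom)
    data = scan.data
    for j in np.unique(cols):
        if t_pos is not None:
            tj = t0_rel + float(j) * meta.duration_s / meta.n_pulses
            xj, yj = target_position(spec, max(tj, 0.0))
            rj, azj = _polar_of_xy(xj, yj, meta)
            if not (0 <= rj < rmax):
                continue
        else:
            rj, azj = r0, az0
        theta_c = azimuth_of_pulse(int(j), meta)
        dth = ((theta_c - azj + 180.0) % 360.0) - 180.0
        if abs(dth) > 3.0 * spec.psf_sigma_az_deg:
            continue
        lo = max(0, int((rj - 3 * spec.psf_sigma_r_m) // geom.dr_m))
        hi = min(meta.n_samples, int((rj + 3 * spec.psf_sigma_r_m)
                                     // geom.dr_m) + 1)
        if hi <= lo:
            continue
        dr = r_centers[lo:hi] - rj
        g = np.round(amp * np.exp(-dr ** 2 / (2 * spec.psf_sigma_r_m ** 2)
                                  - dth ** 2
                                  / (2 * spec.psf_sigma_az_deg ** 2)))
        col = data[lo:hi, j].astype(np.int64) + g.astype(np.int64)
        data[lo:hi, j] = np.clip(col, 0, vmax).astype(data.dtype)
    return True


def simulate_scene(config: SceneConfig) -> tuple[list[Scan], pd.DataFrame]:
    """Simulate a scene: a list of scans plus a ground-truth table.

    Scan ``s`` starts at ``t0_template + s * duration_s``.  Each target is
    rendered at its beam-crossing time within each rotation (per-pulse
    timing), and the truth table records, per (scan, target): the crossing
    time ``t``, the true (x, y) at that time, the polar cell (row, col)
    containing it, and whether it lay inside the digitized range.  The same
    seed reproduces scans and truth bit for bit; a different seed changes
    only the noise, never the truth positions.
    """
    meta0 = config.meta_template
    geom = PolarGeometry.from_meta(meta0)
    children = np.random.SeedSequence(config.seed).spawn(config.n_scans)
    scans: list[Scan] = []
    rows = []
    for s in range(config.n_scans):
        t0_rel = s * meta0.duration_s
        meta = meta0.replace(t0=meta0.t0 + t0_rel)
        scan = gen_noise(meta, config.clutter, children[s])
        for spec in config.targets:
            tc = crossing_time(spec, meta, t0_rel)
            x, y = target_position(spec, tc)
            r, az = _polar_of_xy(x, y, meta)
            row, col, ok = _cell_of_polar(r, az, meta, geom)
            if ok:
                render_target(scan, (x, y), spec, t_pos=tc, t0_rel=t0_rel)
            rows.append((s, spec.id, meta0.t0 + tc, x, y,
                         row if ok else -1, col, ok))
        scans.append(scan)
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return scans, truth


def truth_to_csv(truth: pd.DataFrame, path) -> None:
    """Write a ground-truth table as CSV (scan,target_id,t,x,y,row,col,in_range)."""
    truth.to_csv(path, index=False)
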