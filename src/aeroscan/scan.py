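"""Core scan data model: digitizer profiles, scan metadata, polar geometry,
and static PPI (plan position indicator) rasterization.

A *scan* is one full rotation of a surveillance radar, digitized as a matrix
of unsigned integers with rows indexing range cells (distance from the radar)
and columns indexing pulses (azimuth).  Everything downstream — background
learning, blip extraction, tracking — consumes this container.

Conventions
-----------
* Rows = range cells, columns = pulses, both 0-based.  Range cell ``i``
  covers slant range ``[i*dr, (i+1)*dr)`` (half-open); geometry always uses
  the cell center.
* Azimuth is measured in degrees clockwise from true north (navigation
  convention); pulse 0 points at ``heading_deg``.
* Cartesian frame: x east, y north, z up from the datum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

#: Speed of light in vacuum (m/s); no atmospheric refraction correction.
C_M_PER_S = 299_792_458.0


@dataclass(frozen=True)
class DigitizerProfile:
    """Hard constraints of a radar digitizing card.

    Defaults describe a 12-bit card: samples in 0..4095, digitization rates
    between 5 and 60 Msamples/s, and at most 4 million samples per scan
    (pulses x samples-per-pulse).
    """

    bits: int = 12
    rate_min_hz: float = 5e6
    rate_max_hz: float = 60e6
    sample_budget: int = 4_000_000

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("bit depth must be >= 1")
        if not (0 < self.rate_min_hz <= self.rate_max_hz):
            raise ValueError("require 0 < rate_min_hz <= rate_max_hz")
        if self.sample_budget < 1:
            raise ValueError("sample budget must be >= 1")


DEFAULT_PROFILE = DigitizerProfile()


@dataclass(frozen=True)
class AntennaConfig:
    """Antenna and scanner geometry.

    elev_deg is the angle of the beam center above the horizontal;
    axis_tilt_deg is the scanner rotation axis tilt off vertical (recorded,
    not used in projection); height_m is antenna height above the datum.
    """

    beam_width_deg: float = 1.8
    beam_height_deg: float = 20.0
    elev_deg: float = 0.0
    axis_tilt_deg: float = 0.0
    height_m: float = 0.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.elev_deg <= 90.0):
            raise ValueError("elev_deg must be in [-90, 90]")
        if self.beam_width_deg <= 0 or self.beam_height_deg <= 0:
            raise ValueError("beam extents must be positive")


@dataclass
class ScanMeta:
    """Per-scan metadata: timing, digitization, geometry, geolocation.

    ``extras`` holds arbitrary additional key/value items so that archive
    round trips preserve metadata this library does not interpret.
    """

    t0: float
    n_pulses: int
    n_samples: int
    rate_hz: float
    bits: int = 12
    prf_hz: float = 2100.0
    pulse_len_s: float = 1e-7
    lat: Optional[float] = None
    lon: Optional[float] = None
    heading_deg: float = 0.0
    antenna: AntennaConfig = field(default_factory=AntennaConfig)
    duration_s: float = 2.4
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pulses < 1 or self.n_samples < 1:
            raise ValueError("n_pulses and n_samples must be >= 1")

    def replace(self, **kw) -> "ScanMeta":
        d = self.__dict__.copy()
        d.update(kw)
        return ScanMeta(**d)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d["antenna"] = asdict(self.antenna)
        d.update(self.extras)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMeta":
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kw = {k: v for k, v in d.items() if k in known}
        if "antenna" in kw and isinstance(kw["antenna"], dict):
            kw["antenna"] = AntennaConfig(**kw["antenna"])
        extras = {k: v for k, v in d.items() if k not in known}
        return cls(extras=extras, **kw)


@dataclass
class Scan:
    """One digitized rotation: metadata plus the sample matrix.

    data has shape (n_samples, n_pulses); values are unsigned integers in
    [0, 2**bits - 1].
    """

    meta: ScanMeta
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)


@dataclass(frozen=True)
class PolarGeometry:
    """Cell geometry derived from scan metadata.

    dr_m = c / (2 * rate_hz) is the range-cell depth (two-way travel);
    dtheta_deg = 360 / n_pulses is the azimuth step between pulses.
    """

    dr_m: float
    dtheta_deg: float

    @classmethod
    def from_meta(cls, meta: ScanMeta) -> "PolarGeometry":
        return cls(dr_m=C_M_PER_S / (2.0 * meta.rate_hz),
                   dtheta_deg=360.0 / meta.n_pulses)


def sample_range(profile: DigitizerProfile) -> tuple[int, int]:
    """Representable sample value range (0, 2**bits - 1) for a profile."""
    if profile.bits < 1:
        raise ValueError("invalid profile: bits < 1")
    return (0, 2 ** profile.bits - 1)


def validate_scan(scan: Scan, profile: DigitizerProfile) -> list[str]:
    """Check a scan against digitizer constraints.

    Returns one human-readable descriptor per violated constraint, in the
    fixed order: sample range, sample budget, digitization rate.  An empty
    list means the scan is valid.  Violations are values, not exceptions.
    """
    violations: list[str] = []
    lo, hi = sample_range(profile)
    data = scan.data
    if data.size and (int(data.min()) < lo or int(data.max()) > hi):
        violations.append(
            f"sample out of range [{lo},{hi}]: found values in "
            f"[{int(data.min())},{int(data.max())}]")
    product = scan.meta.n_pulses * scan.meta.n_samples
    if product > profile.sample_budget:
        violations.append(
            f"budget exceeded: {product} samples per scan > "
            f"{profile.sample_budget}")
    if not (profile.rate_min_hz <= scan.meta.rate_hz <= profile.rate_max_hz):
        violations.append(
            f"rate out of bounds: {scan.meta.rate_hz:g} Hz not in "
            f"[{profile.rate_min_hz:g},{profile.rate_max_hz:g}]")
    return violations


def range_of_sample(i, geom: PolarGeometry):
    """Slant range (m) of the center of range cell ``i`` (scalar or array)."""
    i = np.asarray(i)
    if np.any(i < 0):
        raise IndexError("range cell index out of bounds")
    out = (i + 0.5) * geom.dr_m
    return float(out) if out.ndim == 0 else out


def azimuth_of_pulse(j, meta: ScanMeta):
    """Azimuth (deg clockwise from north, in [0, 360)) of pulse column ``j``."""
    j = np.asarray(j)
    if np.any(j < 0) or np.any(j >= meta.n_pulses):
        raise IndexError("pulse index out of bounds")
    out = np.mod(meta.heading_deg + j * (360.0 / meta.n_pulses), 360.0)
    return float(out) if out.ndim == 0 else out


def polar_to_xyz(range_m, azimuth_deg, antenna: AntennaConfig):
    """Project (slant range, azimuth) to (x east, y north, z up) in metres.

    Ground range is range*cos(elev); z uses the beam-center elevation only —
    a single surveillance radar resolves no height within the beam, so z is
    the beam-center approximation above the datum.
    """
    range_m = np.asarray(range_m, dtype=float)
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    el = math.radians(antenna.elev_deg)
    g = range_m * math.cos(el)
    x = g * np.sin(az)
    y = g * np.cos(az)
    z = antenna.height_m + range_m * math.sin(el)
    if range_m.ndim == 0:
        return float(x), float(y), float(z)
    return x, y, z


@dataclass
class PPIRaster:
    """A square top-down raster of a scan.

    ``values`` holds raw sample values (0 where out of range); ``in_range``
    marks pixels whose center lies inside the scanned disc, so values stay
    pure sample units and no sentinel is baked into them.
    """

    values: np.ndarray
    in_range: np.ndarray
    rmax_m: float


def scan_to_ppi(scan: Scan, npix: int, rmax_m: float) -> PPIRaster:
    """Nearest-sample polar-to-cartesian scan conversion (static render).

    Each pixel center within rmax maps to the sample whose polar cell
    contains that (range, azimuth); the radar sits at the image center with
    north up and east right.
    """
    if npix < 2:
        raise ValueError("npix must be >= 2")
    if rmax_m <= 0:
        raise ValueError("rmax_m must be positive")
    meta = scan.meta
    geom = PolarGeometry.from_meta(meta)
    pix = 2.0 * rmax_m / npix
    xs = (np.arange(npix) + 0.5) * pix - rmax_m          # east, per column
    ys = rmax_m - (np.arange(npix) + 0.5) * pix          # north, per row
    X, Y = np.meshgrid(xs, ys)
    r = np.hypot(X, Y)
    az = np.mod(np.degrees(np.arctan2(X, Y)), 360.0)
    row = np.floor(r / geom.dr_m).astype(np.int64)
    col = np.floor(np.mod(az - meta.heading_deg, 360.0)
                   / geom.dtheta_deg).astype(np.int64) % meta.n_pulses
    ok = (r <= rmax_m) & (row < meta.n_samples)
    values = np.zeros((npix, npix), dtype=scan.data.dtype)
    values[ok] = scan.data[row[ok], col[ok]]
    return PPIRaster(values=values, in_range=ok, rmax_m=rmax_m)


def write_pgm(raster: PPIRaster, path, vmax: Optional[int] = None) -> None:
    """Write a PPI raster as an 8-bit binary PGM (P5).

    Sample values are rescaled linearly onto 0..255; out-of-range pixels
    render as 0.
    """
    v = raster.values.astype(np.float64)
    top = float(vmax) if vmax is not None else float(v.max()) or 1.0
    img = np.clip(np.round(v / top * 255.0), 0, 255).astype(np.uint8)
    img[~raster.in_range] = 0
    h, w = img.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
        fh.write(img.tobytes())
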