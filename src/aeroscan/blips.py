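"""Adaptive background model and blip extraction.

The detection scheme mimics how a human radar operator picks out moving
targets on a noisy display.  Over an initial learning period the program
accumulates, per rectangular "stats cell" (a user-defined window of samples
by pulses), a temporal mean ``m`` and mean absolute deviation ``d`` of
sample intensity: the *background*.  Each subsequent sample gets an
intensity z-score ``(x - m) / d`` against its cell's background; samples
whose z-score exceeds a user threshold are *hot*.  Hot samples are grouped
with adjacent hot samples (8-connectivity, wrapping across the 0/360 azimuth
seam) into *patches*; patches that pass user-defined filters (sample count,
PPI area, angular and radial span, or an arbitrary predicate) become
*blips* — putative biological targets.  The background can then be updated
with each scan, exponentially down-weighting older data at a user-chosen
decay rate, so slow changes in clutter are absorbed while transient targets
are not.

"Mean deviation" is implemented as the mean absolute deviation about the
mean; a standard-deviation estimator is available via ``estimator="std"``
without asserting that either is canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .scan import (PolarGeometry, Scan, ScanMeta, azimuth_of_pulse,
                   polar_to_xyz, range_of_sample)


# --------------------------------------------------------------------------
# stats cells

@dataclass(frozen=True)
class StatsCellGrid:
    """Window size for background statistics: samples (rows) x pulses (cols).

    When scan dimensions are not divisible by the cell dimensions, the last
    cell in each direction absorbs the remainder.
    """

    cell_rows: int = 8
    cell_cols: int = 8

    def __post_init__(self) -> None:
        if self.cell_rows < 1 or self.cell_cols < 1:
            raise ValueError("stats cell dimensions must be >= 1")

    def index_maps(self, n_samples: int, n_pulses: int
                   ) -> tuple[np.ndarray, np.ndarray, int, int]:
        """Per-row and per-column stats-cell indices plus grid shape."""
        n_cr = max(n_samples // self.cell_rows, 1)
        n_cc = max(n_pulses // self.cell_cols, 1)
        ri = np.minimum(np.arange(n_samples) // self.cell_rows, n_cr - 1)
        ci = np.minimum(np.arange(n_pulses) // self.cell_cols, n_cc - 1)
        return ri, ci, n_cr, n_cc


@dataclass
class BackgroundModel:
    """Per-stats-cell background: mean ``m`` and mean deviation ``d``."""

    grid: StatsCellGrid
    m: np.ndarray
    d: np.ndarray
    n_learned: int = 0
    estimator: str = "mad"

    def expand(self, n_samples: int, n_pulses: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast cell stats back onto the full scan shape."""
        ri, ci, _, _ = self.grid.index_maps(n_samples, n_pulses)
        return self.m[np.ix_(ri, ci)], self.d[np.ix_(ri, ci)]


def _cell_stats(data: np.ndarray, grid: StatsCellGrid, estimator: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and deviation per stats cell for a stack of scans.

    data: (n_scans, n_samples, n_pulses) or (n_samples, n_pulses); values
    within a cell are pooled across the stack.
    """
    if data.ndim == 2:
        data = data[None]
    _, n_samples, n_pulses = data.shape
    ri, ci, n_cr, n_cc = grid.index_maps(n_samples, n_pulses)
    cell_id = (ri[:, None] * n_cc + ci[None, :])
    flat_ids = np.broadcast_to(cell_id, data.shape).ravel()
    vals = data.astype(np.float64).ravel()
    n_cells = n_cr * n_cc
    counts = np.bincount(flat_ids, minlength=n_cells)
    sums = np.bincount(flat_ids, weights=vals, minlength=n_cells)
    m = sums / counts
    dev = np.abs(vals - m[flat_ids]) if estimator == "mad" \
        else (vals - m[flat_ids]) ** 2
    dsum = np.bincount(flat_ids, weights=dev, minlength=n_cells)
    d = dsum / counts
    if estimator != "mad":
        d = np.sqrt(d)
    return m.reshape(n_cr, n_cc), d.reshape(n_cr, n_cc)


def learn_background(scans: list[Scan], grid: StatsCellGrid,
                     estimator: str = "mad") -> BackgroundModel:
    """Learn the background from the first L scans.

    Pools all sample values within each stats cell across the learning
    scans; m is their mean and d the mean absolute deviation about m
    (or standard deviation for estimator="std").
    """
    if not scans:
        raise ValueError("need at least one learning scan")
    shapes = {s.data.shape for s in scans}
    if len(shapes) != 1:
        raise ValueError("learning scans must share one shape")
    stack = np.stack([s.data for s in scans])
    m, d = _cell_stats(stack, grid, estimator)
    return BackgroundModel(grid=grid, m=m, d=d, n_learned=len(scans),
                           estimator=estimator)


def zscore(x, m, d):
    """Intensity z-score of sample value(s) against cell background.

    d > 0 gives (x - m) / d; the degenerate d = 0 case yields +inf when
    x > m, 0 when x = m and -inf when x < m, so a constant background makes
    any brighter sample hot at any finite threshold.
    """
    x = np.asarray(x, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(d > 0, (x - m) / np.where(d > 0, d, 1.0),
                     np.where(x > m, np.inf,
                              np.where(x < m, -np.inf, 0.0)))
    return float(z) if z.ndim == 0 else z


def find_hot(scan: Scan, bg: BackgroundModel, z_thresh: float) -> np.ndarray:
    """Boolean mask of hot samples: z-score strictly above the threshold."""
    n_samples, n_pulses = scan.data.shape
    m, d = bg.expand(n_samples, n_pulses)
    return zscore(scan.data, m, d) > z_thresh


# --------------------------------------------------------------------------
# patches

@dataclass
class Patch:
    """A maximal 8-connected group of hot samples (azimuth wraps).

    cells are (row, col, value) triples; min_unwrapped_col is the starting
    column of the contiguous circular run the patch occupies (used for
    deterministic ordering and seam-safe centroids).
    """

    cells: list[tuple[int, int, int]]
    bbox: tuple[int, int, int, int]          # (row_min, col_min, row_max, col_max)
    min_unwrapped_col: int = 0

    def __len__(self) -> int:
        return len(self.cells)


def _unwrap_start(cols: np.ndarray, n_pulses: int) -> int:
    """Starting column of the contiguous circular run covering ``cols``.

    Found as the column after the largest circular gap in the sorted
    distinct columns; for a patch not crossing the seam this is simply the
    minimum column.
    """
    u = np.unique(cols)
    if len(u) == 1:
        return int(u[0])
    gaps = np.diff(np.append(u, u[0] + n_pulses))
    k = int(np.argmax(gaps))
    return int(u[(k + 1) % len(u)])


def group_patches(mask: np.ndarray,
                  scan: Optional[Scan] = None) -> list[Patch]:
    """Group hot samples into maximal 8-connected patches.

    Columns 0 and n_pulses-1 are adjacent (azimuth wraparound), including
    diagonally; there is no wraparound in range.  Output is sorted by
    (min row, min unwrapped column).
    """
    n_rows, n_cols = mask.shape
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    # union labels across the azimuth seam (incl. diagonal adjacency)
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if n_cols > 1:
        left, right = labels[:, 0], labels[:, -1]
        for r in range(n_rows):
            if left[r] == 0:
                continue
            for rr in (r - 1, r, r + 1):
                if 0 <= rr < n_rows and right[rr] != 0:
                    union(int(left[r]), int(right[rr]))
    roots = np.array([find(a) for a in range(n + 1)])
    merged = roots[labels]

    # group hot cells by merged label without a per-label image scan
    rows_all, cols_all = np.nonzero(merged)
    labs = merged[rows_all, cols_all]
    order = np.argsort(labs, kind="stable")
    rows_all, cols_all, labs = rows_all[order], cols_all[order], labs[order]
    bounds = np.flatnonzero(np.diff(labs)) + 1
    patches: list[Patch] = []
    for rows, cols in zip(np.split(rows_all, bounds),
                          np.split(cols_all, bounds)):
        if scan is not None:
            vals = scan.data[rows, cols]
        else:
            vals = np.zeros(len(rows), dtype=int)
        cells = [(int(r), int(c), int(v))
                 for r, c, v in zip(rows, cols, vals)]
        start = _unwrap_start(cols, n_cols)
        patches.append(Patch(
            cells=cells,
            bbox=(int(rows.min()), int(cols.min()),
                  int(rows.max()), int(cols.max())),
            min_unwrapped_col=start))
    patches.sort(key=lambda p: (p.bbox[0], p.min_unwrapped_col))
    return patches


# --------------------------------------------------------------------------
# blips

@dataclass
class Blip:
    """A filtered patch with raw cells retained plus summary properties."""

    cells: list[tuple[int, int, int]]
    t: float
    x: float
    y: float
    z: float
    n_samples: int
    area_m2: float
    perimeter_cells: int
    int_mean: float
    int_max: float
    angular_span_deg: float
    radial_span_m: float
    track_id: Optional[int] = None

    @property
    def azimuth_deg(self) -> float:
        return math.degrees(math.atan2(self.x, self.y)) % 360.0

    @property
    def range_m(self) -> float:
        """Ground range of the centroid."""
        return math.hypot(self.x, self.y)

    def props(self) -> dict:
        return {"t": self.t, "x": self.x, "y": self.y, "z": self.z,
                "n_samples": self.n_samples, "area_m2": self.area_m2,
                "perimeter_cells": self.perimeter_cells,
                "int_mean": self.int_mean, "int_max": self.int_max,
                "angular_span_deg": self.angular_span_deg,
                "radial_span_m": self.radial_span_m}


def blip_properties(patch: Patch, scan: Scan) -> Blip:
    """Summarize a patch into a blip.

    Area is the sum of polar cell areas r_i*dtheta*dr at each cell-center
    radius; spans count distinct rows/columns; the centroid is the
    intensity-weighted mean of cell-center (x, y); the timestamp is
    interpolated by mean (unwrapped) pulse column within the rotation.
    Perimeter counts patch cells with at least one 4-neighbour (azimuth
    wrapping) outside the patch.
    """
    meta = scan.meta
    geom = PolarGeometry.from_meta(meta)
    rows = np.array([c[0] for c in patch.cells])
    cols = np.array([c[1] for c in patch.cells])
    vals = np.array([c[2] for c in patch.cells], dtype=np.float64)
    n = len(patch.cells)

    dth_rad = math.radians(geom.dtheta_deg)
    r_c = range_of_sample(rows, geom)
    area = float(np.sum(r_c * dth_rad * geom.dr_m))

    n_distinct_cols = len(np.unique(cols))
    n_distinct_rows = len(np.unique(rows))
    angular_span = n_distinct_cols * geom.dtheta_deg
    radial_span = n_distinct_rows * geom.dr_m

    w = vals if vals.sum() > 0 else np.ones(n)
    az = azimuth_of_pulse(cols, meta)
    az = np.atleast_1d(az)
    x_c, y_c, _ = polar_to_xyz(r_c, az, meta.antenna)
    x_c, y_c = np.atleast_1d(x_c), np.atleast_1d(y_c)
    wsum = w.sum()
    cx = float((w * x_c).sum() / wsum)
    cy = float((w * y_c).sum() / wsum)
    r_bar = float((w * np.atleast_1d(r_c)).sum() / wsum)
    z = meta.antenna.height_m + r_bar * math.sin(
        math.radians(meta.antenna.elev_deg))

    cellset = {(r, c) for r, c, _ in patch.cells}
    n_pulses = meta.n_pulses
    perim = 0
    for r, c, _ in patch.cells:
        nbrs = ((r - 1, c), (r + 1, c),
                (r, (c - 1) % n_pulses), (r, (c + 1) % n_pulses))
        if any(nb not in cellset for nb in nbrs):
            perim += 1

    start = patch.min_unwrapped_col
    unwrapped = np.where(cols >= start, cols, cols + n_pulses)
    mean_col = float(unwrapped.mean())
    t = meta.t0 + mean_col * meta.duration_s / meta.n_pulses

    return Blip(cells=list(patch.cells), t=t, x=cx, y=cy, z=z,
                n_samples=n, area_m2=area, perimeter_cells=perim,
                int_mean=float(vals.mean()), int_max=float(vals.max()),
                angular_span_deg=angular_span, radial_span_m=radial_span)


@dataclass
class BlipFilters:
    """Closed bounds (each optional) plus an arbitrary predicate hook."""

    min_n_samples: Optional[int] = None
    max_n_samples: Optional[int] = None
    min_area_m2: Optional[float] = None
    max_area_m2: Optional[float] = None
    min_angular_span_deg: Optional[float] = None
    max_angular_span_deg: Optional[float] = None
    min_radial_span_m: Optional[float] = None
    max_radial_span_m: Optional[float] = None
    predicate: Optional[Callable[[Blip], bool]] = None

    def __post_init__(self) -> None:
        for attr in ("n_samples", "area_m2", "angular_span_deg",
                     "radial_span_m"):
            lo = getattr(self, f"min_{attr}")
            hi = getattr(self, f"max_{attr}")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"min_{attr} > max_{attr}")

    def passes(self, blip: Blip) -> bool:
        for attr in ("n_samples", "area_m2", "angular_span_deg",
                     "radial_span_m"):
            v = getattr(blip, attr)
            lo = getattr(self, f"min_{attr}")
            hi = getattr(self, f"max_{attr}")
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
        if self.predicate is not None and not self.predicate(blip):
            return False
        return True


def filter_blips(blips: list[Blip], filters: BlipFilters) -> list[Blip]:
    """Keep blips passing all bounds and the optional predicate (stable order)."""
    return [b for b in blips if filters.passes(b)]


@dataclass
class SectorRule:
    """Different processing for a wedge of the scanned volume.

    action "discard" drops data inside the sector entirely; "override"
    re-filters blips inside the sector with its own BlipFilters.  Azimuth
    interval is half-open [az_lo, az_hi) modulo 360; when two rules overlap,
    the first listed wins.
    """

    az_lo: float
    az_hi: float
    r_lo: float = 0.0
    r_hi: float = math.inf
    action: str = "discard"
    override_filters: Optional[BlipFilters] = None

    def __post_init__(self) -> None:
        if self.action not in ("discard", "override"):
            raise ValueError("action must be 'discard' or 'override'")
        if self.action == "override" and self.override_filters is None:
            raise ValueError("override rule needs override_filters")
        if (self.az_lo % 360.0) == (self.az_hi % 360.0):
            raise ValueError("azimuth interval empty mod 360")

    def contains(self, az_deg: float, r_m: float) -> bool:
        lo, hi = self.az_lo % 360.0, self.az_hi % 360.0
        az = az_deg % 360.0
        in_az = (lo <= az < hi) if lo < hi else (az >= lo or az < hi)
        return in_az and (self.r_lo <= r_m < self.r_hi)


def apply_sector_rules(blips: list[Blip], mask: Optional[np.ndarray],
                       sectors: list[SectorRule],
                       meta: Optional[ScanMeta] = None
                       ) -> tuple[list[Blip], Optional[np.ndarray]]:
    """Apply sector rules to a hot mask and/or a blip list.

    Discard sectors zero the mask inside the wedge and drop blips whose
    centroid falls inside; override sectors re-filter contained blips with
    their own criteria.  The first listed sector containing a blip wins.
    """
    if not sectors:
        return blips, mask
    if mask is not None:
        if meta is None:
            raise ValueError("meta required to map mask cells to sectors")
        geom = PolarGeometry.from_meta(meta)
        az = azimuth_of_pulse(np.arange(meta.n_pulses), meta)
        r = range_of_sample(np.arange(meta.n_samples), geom)
        mask = mask.copy()
        for rule in sectors:
            if rule.action != "discard":
                continue
            lo, hi = rule.az_lo % 360.0, rule.az_hi % 360.0
            in_az = ((az >= lo) & (az < hi)) if lo < hi \
                else ((az >= lo) | (az < hi))
            in_r = (r >= rule.r_lo) & (r < rule.r_hi)
            mask[np.ix_(in_r, in_az)] = False
    out: list[Blip] = []
    for b in blips:
        rule = next((s for s in sectors
                     if s.contains(b.azimuth_deg, b.range_m)), None)
        if rule is None:
            out.append(b)
        elif rule.action == "override":
            if rule.override_filters.passes(b):
                out.append(b)
        # discard: dropped
    return out, mask


# --------------------------------------------------------------------------
# background update & full pipeline step

def update_background(bg: BackgroundModel, scan: Scan, alpha: float,
                      exclude_hot: bool = False,
                      z_thresh: Optional[float] = None) -> BackgroundModel:
    """Exponentially-weighted background update from one scan.

    Per cell: m <- (1-alpha)*m + alpha*m_scan and likewise for d, where
    m_scan/d_scan are the single scan's cell statistics.  Hot samples are
    included by default; with exclude_hot=True, samples hot against the
    current background (at z_thresh) are left out of the scan statistics
    (cells going fully hot keep their previous stats).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return bg
    data = scan.data.astype(np.float64)
    n_samples, n_pulses = data.shape
    ri, ci, n_cr, n_cc = bg.grid.index_maps(n_samples, n_pulses)
    cell_id = ri[:, None] * n_cc + ci[None, :]
    flat_ids = cell_id.ravel()
    vals = data.ravel()
    if exclude_hot:
        if z_thresh is None:
            raise ValueError("z_thresh required with exclude_hot")
        keep = ~find_hot(scan, bg, z_thresh).ravel()
        flat_ids, vals = flat_ids[keep], vals[keep]
    n_cells = n_cr * n_cc
    counts = np.bincount(flat_ids, minlength=n_cells)
    sums = np.bincount(flat_ids, weights=vals, minlength=n_cells)
    ok = counts > 0
    m_scan = np.where(ok, sums / np.maximum(counts, 1), 0.0)
    if bg.estimator == "mad":
        dev = np.abs(vals - m_scan[flat_ids])
    else:
        dev = (vals - m_scan[flat_ids]) ** 2
    dsum = np.bincount(flat_ids, weights=dev, minlength=n_cells)
    d_scan = np.where(ok, dsum / np.maximum(counts, 1), 0.0)
    if bg.estimator != "mad":
        d_scan = np.sqrt(d_scan)
    m_scan = m_scan.reshape(n_cr, n_cc)
    d_scan = d_scan.reshape(n_cr, n_cc)
    okg = ok.reshape(n_cr, n_cc)
    m = np.where(okg, (1 - alpha) * bg.m + alpha * m_scan, bg.m)
    d = np.where(okg, (1 - alpha) * bg.d + alpha * d_scan, bg.d)
    return BackgroundModel(grid=bg.grid, m=m, d=d,
                           n_learned=bg.n_learned, estimator=bg.estimator)


@dataclass
class ExtractionParams:
    """All knobs of the blip extraction stage."""

    z_thresh: float = 4.0
    learn_scans: int = 5
    alpha: float = 0.05
    update_enabled: bool = True
    exclude_hot: bool = False
    grid: StatsCellGrid = field(default_factory=StatsCellGrid)
    filters: BlipFilters = field(default_factory=BlipFilters)
    sectors: list[SectorRule] = field(default_factory=list)
    estimator: str = "mad"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.learn_scans < 1:
            raise ValueError("learn_scans must be >= 1")
        if not math.isfinite(self.z_thresh):
            raise ValueError("z_thresh must be finite")


def extract_blips(scan: Scan, bg: BackgroundModel, params: ExtractionParams
                  ) -> tuple[list[Blip], BackgroundModel]:
    """One full extraction step on a scan.

    Composition: find_hot -> sector discards on the mask -> group_patches
    -> blip_properties -> filter_blips -> sector rules on blips -> optional
    background update.  Blips come back sorted by (timestamp, centroid
    azimuth).
    """
    mask = find_hot(scan, bg, params.z_thresh)
    _, mask = apply_sector_rules([], mask, params.sectors, scan.meta)
    patches = group_patches(mask, scan)
    # cheap pre-filter: n_samples equals |cells|, so size bounds can be
    # applied before the (more expensive) property computation without
    # changing the result of blip_properties -> filter_blips
    f = params.filters
    patches = [p for p in patches
               if (f.min_n_samples is None or len(p) >= f.min_n_samples)
               and (f.max_n_samples is None or len(p) <= f.max_n_samples)]
    blips = [blip_properties(p, scan) for p in patches]
    blips = filter_blips(blips, params.filters)
    blips, _ = apply_sector_rules(blips, None, params.sectors, scan.meta)
    if params.update_enabled:
        bg = update_background(bg, scan, params.alpha,
                               exclude_hot=params.exclude_hot,
                               z_thresh=params.z_thresh)
    blips.sort(key=lambda b: (b.t, b.azimuth_deg))
    return blips, bg
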