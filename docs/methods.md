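# Methods

This note documents the models and procedures implemented in `aeroscan`,
the parameters that matter, and the numerical and design choices made
where more than one reasonable option existed.

## Scan model and geometry

A scan is a matrix of unsigned integers, `n_samples` rows (range cells) ×
`n_pulses` columns (pulses), with per-scan metadata (start time, rotation
period, digitization rate, bit depth, antenna geometry, geolocation,
heading). Conventions, fixed once and used everywhere:

* Rows and columns are 0-based; range cell *i* covers slant range
  `[i·dr, (i+1)·dr)` with `dr = c/(2·rate_hz)` and
  `c = 299 792 458 m/s` (no atmospheric refraction). All geometry uses the
  cell center, with no within-cell interpolation.
* Azimuth is degrees clockwise from true north; pulse *j* points at
  `heading_deg + j·360/n_pulses (mod 360)`. Whether the radar's pulse 0 is
  a heading pulse or north is hardware-specific, so it is exposed as
  `heading_deg` rather than guessed.
* Cartesian: x east, y north, z above datum. A single surveillance radar
  has no height resolution within its beam, so
  `z = height_m + r·sin(elev_deg)` is the beam-center approximation.

The default digitizer profile describes a 12-bit card: samples in
0–4095, rates 5–60 Msamples/s, at most 4 million samples per scan
(pulses × samples per pulse). `validate_scan` reports violations as
values (range, budget, rate, in that order) rather than exceptions, so a
pipeline can decide what to do with a marginal archive.

PPI rendering is a static nearest-sample polar→cartesian map: each pixel
center within the display radius takes the value of the polar cell
containing its (range, azimuth). Out-of-disc pixels are carried in a
separate boolean mask so the raster itself stays in pure sample units.
Output is 8-bit binary PGM (values rescaled linearly), a format that
needs no imaging dependency.

## Background model and blip extraction

The detector mimics how a human operator distinguishes moving targets
from a stable clutter field:

1. **Learning.** For the first *L* scans (`learn_scans`, default 5),
   sample values are pooled per *stats cell* — a window of
   `cell_rows × cell_cols` samples×pulses (default 8×8; the last cell in
   each direction absorbs any remainder) — both spatially within the cell
   and temporally across the L scans. The pooled mean *m* and mean
   absolute deviation *d* about it form the background. Pooling across
   scans keeps *d* stable even for small L. "Deviation" is the mean
   absolute deviation by default; `estimator="std"` switches to the
   standard deviation without any other change, since either is a
   defensible spread estimate here.
2. **Scoring.** Each sample gets `z = (x − m)/d` against its cell. The
   degenerate `d = 0` case maps to +∞ / 0 / −∞ for x above / at / below
   the mean, so a constant background makes any brighter sample hot at
   any finite threshold. *Hot* requires strict inequality
   `z > z_thresh` (default 4).
3. **Grouping.** Hot samples form maximal 8-connected patches; columns 0
   and `n_pulses − 1` are adjacent (including diagonally) because azimuth
   wraps, while range does not wrap. Components are reported sorted by
   (min row, min unwrapped column); a seam-crossing patch is "unwrapped"
   starting after the largest circular gap in its column set, which also
   defines the mean column used for its timestamp.
4. **Properties.** Area is the sum of polar cell areas `r_i·dθ·dr` at
   each cell's center radius; spans count distinct rows/columns; the
   centroid is the intensity-weighted mean of cell-center (x, y); the
   perimeter counts cells with at least one 4-neighbour outside the
   patch; the timestamp interpolates the scan start time by mean pulse
   column, since the beam reaches different azimuths at different times
   within the rotation.
5. **Filtering.** Closed bounds on sample count, area, angular and radial
   span, plus an arbitrary predicate. With heavy-tailed clutter, the
   z-threshold alone always passes some single-sample speckle; the
   minimum-sample-count filter is the practical speckle rejector, chosen
   per scene at roughly half the expected target patch size.
   Sector rules apply different handling per wedge of the scanned volume:
   *discard* zeroes the mask and drops contained blips, *override*
   re-filters contained blips with sector-specific bounds; when rules
   overlap, the first listed wins.
6. **Update.** Per cell, `m ← (1−α)m + α·m_scan` and likewise for *d*,
   with `m_scan, d_scan` the single scan's cell statistics (α default
   0.05). Hot samples are included by default — the simplest contract,
   and harmless when targets occupy a tiny fraction of any stats cell —
   with an `exclude_hot` flag for strong-target scenes. A scan whose cell
   statistics equal the background is a fixed point for any α.

Blip counts are monotone non-increasing in the threshold only in the
sparse-detection regime (isolated targets); at thresholds low enough for
the hot mask to percolate, patches merge and the count can drop with
*falling* threshold instead. Tests and the validation scene operate in
the sparse regime, which is also the regime the detector is for.

## Trackers

Both linkers consume per-scan blip lists and produce tracks (time-ordered
blip sequences with per-scan indices); both are deterministic given their
tie-break seed, and no blip ever belongs to two active tracks.

**Feasibility.** A candidate (track, blip) link implies a speed
(3-D extension distance / Δt), a horizontal turning angle against the
track's last segment, and a relative change in blip area
(`rel_change_on="intensity"` switches to mean intensity). Links are kept
only when all three are within the inclusive user bounds
(`max_speed_mps`, `max_turn_deg`, `max_rel_change`). Extension distance
is 3-D Euclidean in exported (x, y, z).

**Nearest neighbour (NN).** Feasible pairs are assigned one-to-one so as
to minimize total extension distance at maximum cardinality, via optimal
rectangular bipartite assignment; exact ties between optimal matchings
are broken by a seeded infinitesimal perturbation (a reproducible "coin
toss"). Unmatched blips wait in a pool for up to `expiry_scans` and may
pair with a later unmatched blip (same feasibility, distance-optimal
matching) to seed a new two-blip track; tracks unextended for
`expiry_scans` complete.

**Gain.** For a track with at least two blips, the constant-velocity
prediction is `p̂ = p_last + v_last·Δt`; with `d = |p_blip − p̂|` and
`Δv = |v_new − v_last|`,

    gain = −w_prox·ln(1 + d/σ_p) − w_vel·ln(1 + Δv/σ_v)

bounded above by 0 (perfect prediction, unchanged velocity). Defaults
`w = 1`, `σ_p = 25 m`, `σ_v = 10 m/s` put the two log-scale terms on
comparable footing at bird-scale motion; `gain_min` (default −5) is the
feasibility floor, and a user hook can replace the function entirely.

**Multiframe correspondence (MFC).** Association is re-solved over a
sliding window of the last *k* scans (default 3): within a replay,
tracks with a defined velocity extend greedily in descending gain order
(conflicts resolved by first-come at higher gain; ties by track id, blip
azimuth, then seeded coin), and a second NN-style phase matches leftover
blips with single-blip seeds and pooled blips. Because the whole window
is re-associated on every new scan, links made earlier in the window can
break and re-attach as new evidence arrives; a link becomes permanent
when its scan slides out of the window, i.e. tracks are retroactively
correctable back *k* scans. The first two scans therefore bootstrap
exactly as NN. A track with no blip in the last *k* scans can no longer
be extended or corrected and completes; committed single-blip seeds that
never matured are dropped, and track ids are renumbered densely in
creation order when the run finalizes.

**Evaluation.** Against ground truth, an estimated link (two consecutive
blips of one track) is correct iff both blips lie within a match radius
of the same true target at their scans and those truth detections are on
consecutive scans. Precision = correct/estimated links (1.0 when no links
are claimed), recall = correct/truth links, purity = per-track
majority-target blip fraction averaged over tracks.

## Synthetic scenes

The generator produces what the detector and trackers must survive, in
digitizer units so no power calibration enters:

* **Noise:** per sample, `round(clip(noise_mean + Exp(noise_scale)))` —
  a shifted exponential, one-sided like real clutter intensity (a
  Rayleigh-amplitude field has exponential power). Defaults: mean 40,
  scale 8 on the 12-bit range.
* **Structured clutter:** an optional sea sector multiplying the noise
  scale inside an azimuth wedge, and a rain blob adding a constant
  pedestal inside a disc.
* **Targets:** point targets with Gaussian point-spread in range and
  azimuth (σ_r ≈ pulse-length scale, σ_az ≈ beam-width scale), moving in
  straight lines or constant-turn arcs. Amplitude is constant with range
  by default so detection studies decouple from radiometry; an optional
  range power-law exponent restores a decay if wanted. Each target is
  evaluated at each pulse's transmit time, so fast targets smear across
  columns and energy wraps correctly at the 0/360° seam.
* **Truth:** one row per (scan, target) with the beam-crossing time
  (solved by fixed-point iteration of position → azimuth → pulse time),
  the true (x, y) at that time, the polar cell containing it, and an
  in-range flag. Crossing-time truth is what the rendered blip physically
  shows; a scan-center convention would be off by up to half a rotation
  of target motion, which at bird speeds exceeds a range cell.
* **Seeding:** one seed per scene, with per-scan child streams derived
  through `numpy` seed sequences; the same seed reproduces scans and
  truth bit for bit, and a different seed changes only the noise.

What the simulator does **not** emulate: the radar range equation and
radar cross sections, antenna sidelobes, multipath, beam-height-dependent
detectability, sea/rain Doppler structure, or correlated clutter
textures. Passing detection tests on these scenes therefore demonstrates
the correctness of the extraction and linking machinery under calibrated
signal-to-clutter ratios, not field-performance on real clutter.

## Reference validation scene

The validation workloads (test suite and `scripts/acceptance.py`) use a
1024-pulse × 512-range-cell grid at 50 Msamples/s (dr ≈ 3 m, rotation
2.4 s), 5 learning + 20 processed scans, and three constant-velocity
targets of amplitude 80 — 10× the noise scale — with σ_r = 4 m,
σ_az = 0.7°. Extraction runs at z = 4 with a minimum patch size of 8
samples; tracking uses MFC with k = 3 and a 50 m/s speed bound. Measured
quantities: fraction of (scan, target) pairs whose nearest blip centroid
falls within one cell diagonal `√(dr² + (r·dθ)²)` of truth; fraction of
scans with exactly 3 blips; MFC link precision/recall and track purity at
a 20 m match radius; and the worst relative error of recovered mean track
speeds. These sizes keep the whole suite and the acceptance script within
tens of seconds on one CPU while leaving hundreds of link decisions to
score.

## Degenerate inputs and tie-breaking summary

* `d = 0` background cells: ±∞/0 z-scores as above.
* Zero-intensity patches: centroid weights fall back to uniform.
* Assignment ties: seeded perturbation, ~1e-9 of the cost scale —
  far below any physically meaningful distance difference.
* Greedy MFC ties: gain, then track id, then blip azimuth, then seeded
  coin.
* Overlapping sector rules: first listed wins.
* Pool blips and candidate links require strictly increasing timestamps.
* Archives: canonical JSON (sorted keys, minimal separators, shortest
  round-trip floats) makes byte-identical re-serialization the natural
  round-trip test; unknown keys at any level survive read→write.

## Known limitations

* The MFC window replay is greedy per scan within the window, not an
  exhaustive optimization over all window assignments; it inherits the
  non-iterative greedy character of multiframe point correspondence
  rather than guaranteeing the gain-optimal global solution.
* Track completion in MFC is tied to the window length *k* (a track that
  cannot be corrected anymore is finished); the NN tracker uses the
  separate `expiry_scans` for both pool and completion.
* No CFAR-style detector, no physical power calibration, no Kalman/IMM
  smoothing, no multiple-hypothesis tracking; blip z-coordinates are
  beam-center approximations, so "3-D" distances are effectively slant
  corrections, not height measurements.
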