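"""Headless processing manager: source -> stats -> blips -> tracks -> sinks.

Mirrors a media-player style radar workflow without a GUI: a configured
source (a simulated scene or an archive) is played through background
learning, blip extraction, optional tracking and one or more sinks, with
named *hooks* between stages.  A hook is a user function that receives the
stage payload and returns a (possibly modified) replacement; subsequent
stages consume whatever the hooks produced, so plugins can inject metadata,
veto blips, or log intermediate state.  By default a failing hook logs and
leaves the payload unchanged (robustness over strictness); strict mode
re-raises instead.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tomllib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import archive as archive_io
from .blips import (BackgroundModel, BlipFilters, ExtractionParams,
                    SectorRule, StatsCellGrid, apply_sector_rules,
                    blip_properties, filter_blips, find_hot, group_patches,
                    learn_background, update_background)
from .scan import (AntennaConfig, DigitizerProfile, Scan, ScanMeta,
                   scan_to_ppi, validate_scan, write_pgm)
from .synth import ClutterSpec, SceneConfig, TargetSpec, simulate_scene
from .tracking import (MFCTrackerState, NNTrackerState, TrackerParams,
                       finalize_mfc, finalize_nn, make_mfc_state,
                       make_nn_state, mfc_tracks, step_mfc, step_nn)

log = logging.getLogger(__name__)

HOOK_NAMES = ("SCAN_META", "SCAN_DATA", "POST_STATS", "POST_HOT",
              "POST_PATCHES", "POST_BLIPS", "POST_TRACK_STEP",
              "TRACK_COMPLETE", "SCAN_DONE")


class HookRegistry:
    """Ordered user extension points between pipeline stages."""

    def __init__(self) -> None:
        self._hooks: dict[str, list[Callable]] = {n: [] for n in HOOK_NAMES}

    def register(self, name: str, fn: Callable) -> None:
        if name not in self._hooks:
            raise KeyError(f"unknown hook {name!r}; valid: {HOOK_NAMES}")
        self._hooks[name].append(fn)

    def fire(self, name: str, payload, strict: bool = False):
        """Run registered functions in registration order, threading the
        payload through; with no hooks this is the identity."""
        if name not in self._hooks:
            raise KeyError(f"unknown hook {name!r}")
        for fn in self._hooks[name]:
            try:
                out = fn(payload)
            except Exception:
                if strict:
                    raise
                log.warning("hook %s:%s failed; payload unchanged",
                            name, getattr(fn, "__name__", fn),
                            exc_info=True)
                continue
            if out is None:
                if strict:
                    raise TypeError(
                        f"hook {name} returned None instead of a payload")
                log.warning("hook %s returned None; payload unchanged", name)
                continue
            payload = out
        return payload


def register_hook(registry: HookRegistry, name: str, fn: Callable) -> None:
    registry.register(name, fn)


def fire_hook(registry: HookRegistry, name: str, payload,
              strict: bool = False):
    return registry.fire(name, payload, strict=strict)


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Everything one processing run needs.

    source is a SceneConfig (simulate), or {"blipmovie": path}, or
    {"raw": path}.  sinks maps sink names (blipmovie, raw, blips_csv,
    tracks_csv, ppi_dir) to output paths; at least one is required.
    """

    source: object
    sinks: dict = field(default_factory=dict)
    profile: DigitizerProfile = field(default_factory=DigitizerProfile)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    tracker: str = "none"                  # none | nn | mfc
    tracker_params: TrackerParams = field(default_factory=TrackerParams)
    seed: int = 0
    log_level: str = "INFO"
    max_scans: Optional[int] = None
    strict_hooks: bool = False
    ppi_npix: int = 256
    ppi_rmax_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sinks:
            raise ValueError("at least one sink is required")
        if self.tracker not in ("none", "nn", "mfc"):
            raise ValueError("tracker must be none, nn or mfc")


def _build_meta(d: dict) -> ScanMeta:
    d = dict(d)
    if "antenna" in d and isinstance(d["antenna"], dict):
        d["antenna"] = AntennaConfig(**d["antenna"])
    return ScanMeta(**d)


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (parsed TOML or JSON)."""
    src = d["source"]
    if "scene" in src:
        sc = src["scene"]
        meta = _build_meta(sc["meta"])
        targets = [TargetSpec(**t) for t in sc.get("targets", [])]
        ck = dict(sc.get("clutter", {}))
        for key in ("sea_sector", "rain_blob"):
            if key in ck and ck[key] is not None:
                ck[key] = tuple(ck[key])
        clutter = ClutterSpec(**ck)
        source = SceneConfig(meta_template=meta,
                             n_scans=int(sc["n_scans"]),
                             targets=targets, clutter=clutter,
                             seed=int(sc.get("seed", d.get("seed", 0))))
    elif "blipmovie" in src:
        source = {"blipmovie": src["blipmovie"]}
    elif "raw" in src:
        source = {"raw": src["raw"]}
    else:
        raise ValueError("source must contain scene, blipmovie or raw")

    ex = dict(d.get("extraction", {}))
    if "grid" in ex:
        ex["grid"] = StatsCellGrid(**ex["grid"])
    if "filters" in ex:
        ex["filters"] = BlipFilters(**ex["filters"])
    if "sectors" in ex:
        ex["sectors"] = [SectorRule(**s) for s in ex["sectors"]]
    extraction = ExtractionParams(**ex)

    tr = d.get("tracker", {})
    tracker = tr.get("model", "none")
    tp = {k: v for k, v in tr.items() if k != "model"}
    tracker_params = TrackerParams(**tp)

    prof = DigitizerProfile(**d["profile"]) if "profile" in d \
        else DigitizerProfile()

    return PipelineConfig(
        source=source, sinks=dict(d["sinks"]), profile=prof,
        extraction=extraction, tracker=tracker,
        tracker_params=tracker_params, seed=int(d.get("seed", 0)),
        log_level=d.get("log_level", "INFO"),
        max_scans=d.get("max_scans"),
        strict_hooks=bool(d.get("strict_hooks", False)),
        ppi_npix=int(d.get("ppi_npix", 256)),
        ppi_rmax_m=d.get("ppi_rmax_m"))


def load_config(path) -> PipelineConfig:
    """Parse a TOML (or .json) pipeline configuration file."""
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path, "rb") as fh:
            return config_from_dict(json.load(fh))
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


# --------------------------------------------------------------------------
# running

@dataclass
class RunSummary:
    scans_processed: int = 0
    blips_found: int = 0
    tracks_completed: int = 0
    sink_paths: dict = field(default_factory=dict)
    ok: bool = True
    note: str = ""


def _load_source(config: PipelineConfig):
    """Returns (scans, truth_or_None) or raises for blipmovie passthrough."""
    if isinstance(config.source, SceneConfig):
        scans, truth = simulate_scene(config.source)
        return scans, truth
    if isinstance(config.source, dict) and "raw" in config.source:
        _, scans = archive_io.read_raw(config.source["raw"])
        return scans, None
    raise ValueError("unsupported source for scan processing")


def run_pipeline(config: PipelineConfig,
                 hooks: Optional[HookRegistry] = None) -> RunSummary:
    """Run one job to completion.

    The first learn_scans scans initialize the background and emit no
    blips; every later scan flows extract -> track -> sinks with hooks
    fired at each stage boundary.  Deterministic given config + seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    hooks = hooks or HookRegistry()
    strict = config.strict_hooks
    summary = RunSummary()

    if isinstance(config.source, dict) and "blipmovie" in config.source:
        return _run_from_blipmovie(config, hooks, summary)

    scans, _ = _load_source(config)
    if config.max_scans is not None:
        scans = scans[:config.max_scans]
    bad = [v for s in scans for v in validate_scan(s, config.profile)]
    if bad:
        raise ValueError(f"invalid source scans: {bad[0]}")

    params = config.extraction
    L = min(params.learn_scans, len(scans))
    bg = learn_background(scans[:L], params.grid, params.estimator)
    bg = hooks.fire("POST_STATS", bg, strict)

    if config.tracker == "nn":
        tstate = make_nn_state(config.tracker_params)
    elif config.tracker == "mfc":
        tstate = make_mfc_state(config.tracker_params)
    else:
        tstate = None

    movie_records = []
    all_blips: list = []
    ppi_dir = config.sinks.get("ppi_dir")
    if ppi_dir:
        os.makedirs(ppi_dir, exist_ok=True)

    for s_idx, scan in enumerate(scans):
        meta = hooks.fire("SCAN_META", scan.meta, strict)
        scan = Scan(meta=meta, data=scan.data)
        scan = hooks.fire("SCAN_DATA", scan, strict)
        if s_idx < L:
            continue

        mask = find_hot(scan, bg, params.z_thresh)
        mask = hooks.fire("POST_HOT", mask, strict)
        _, mask = apply_sector_rules([], mask, params.sectors, scan.meta)
        patches = group_patches(mask, scan)
        patches = hooks.fire("POST_PATCHES", patches, strict)
        f = params.filters
        patches = [p for p in patches
                   if (f.min_n_samples is None or len(p) >= f.min_n_samples)
                   and (f.max_n_samples is None or len(p) <= f.max_n_samples)]
        blips = [blip_properties(p, scan) for p in patches]
        blips = filter_blips(blips, params.filters)
        blips, _ = apply_sector_rules(blips, None, params.sectors, scan.meta)
        blips.sort(key=lambda b: (b.t, b.azimuth_deg))
        blips = hooks.fire("POST_BLIPS", blips, strict)
        if params.update_enabled:
            bg = update_background(bg, scan, params.alpha,
                                   exclude_hot=params.exclude_hot,
                                   z_thresh=params.z_thresh)
            bg = hooks.fire("POST_STATS", bg, strict)

        if tstate is not None:
            if config.tracker == "nn":
                step_nn(tstate, blips, s_idx, config.tracker_params)
            else:
                step_mfc(tstate, blips, s_idx, config.tracker_params)
            tstate = hooks.fire("POST_TRACK_STEP", tstate, strict)
            for t in tstate.completed_this_step:
                hooks.fire("TRACK_COMPLETE", t, strict)
                summary.tracks_completed += 1

        summary.blips_found += len(blips)
        all_blips.extend(blips)
        if "blipmovie" in config.sinks:
            movie_records.append(archive_io.scan_record(scan.meta, blips))
        if ppi_dir:
            geom_rmax = config.ppi_rmax_m or (
                scan.meta.n_samples
                * (299792458.0 / (2 * scan.meta.rate_hz)))
            raster = scan_to_ppi(scan, config.ppi_npix, geom_rmax)
            write_pgm(raster, os.path.join(ppi_dir, f"scan{s_idx:05d}.pgm"),
                      vmax=2 ** scan.meta.bits - 1)
        log.info("scan %d: hot=%d patches=%d blips=%d",
                 s_idx, int(np.count_nonzero(mask)), len(patches),
                 len(blips))
        hooks.fire("SCAN_DONE", {"scan_index": s_idx, "n_blips": len(blips)},
                   strict)
        summary.scans_processed += 1

    tracks = []
    if tstate is not None:
        if config.tracker == "nn":
            n_before = len(tstate.completed)
            tracks = finalize_nn(tstate)
        else:
            n_before = len(tstate.completed)
            tracks = finalize_mfc(tstate, config.tracker_params)
        for t in tracks[n_before:]:
            hooks.fire("TRACK_COMPLETE", t, strict)
        summary.tracks_completed = len(tracks)
        by_blip = {}
        for t in tracks:
            for b in t.blips:
                by_blip[id(b)] = t.id
        for b in all_blips:
            b.track_id = by_blip.get(id(b))

    try:
        if "blipmovie" in config.sinks:
            archive_io.write_blipmovie(movie_records,
                                       config.sinks["blipmovie"])
            summary.sink_paths["blipmovie"] = config.sinks["blipmovie"]
        if "raw" in config.sinks:
            archive_io.write_raw(scans, config.sinks["raw"])
            summary.sink_paths["raw"] = config.sinks["raw"]
        if "blips_csv" in config.sinks:
            archive_io.export_blips(all_blips, config.sinks["blips_csv"])
            summary.sink_paths["blips_csv"] = config.sinks["blips_csv"]
        if "tracks_csv" in config.sinks:
            archive_io.export_tracks(tracks, config.sinks["tracks_csv"])
            summary.sink_paths["tracks_csv"] = config.sinks["tracks_csv"]
        if ppi_dir:
            summary.sink_paths["ppi_dir"] = ppi_dir
    except OSError as exc:
        summary.ok = False
        summary.note = f"sink I/O failure, partial output: {exc}"
    return summary


def _run_from_blipmovie(config: PipelineConfig, hooks: HookRegistry,
                        summary: RunSummary) -> RunSummary:
    """Re-run an archived blipmovie: filter, optionally track, re-record.

    No extraction happens — blips come straight from the archive — so only
    blip-level stages and sinks apply.  A re-recorded movie contains a
    subset of the original blips with identical scan metadata.
    """
    strict = config.strict_hooks
    params = config.extraction
    _, records = archive_io.read_blipmovie(config.source["blipmovie"])
    if config.max_scans is not None:
        records = records[:config.max_scans]
    if config.tracker == "nn":
        tstate = make_nn_state(config.tracker_params)
    elif config.tracker == "mfc":
        tstate = make_mfc_state(config.tracker_params)
    else:
        tstate = None

    out_records = []
    all_blips: list = []
    for s_idx, rec in enumerate(records):
        meta = hooks.fire("SCAN_META", rec["meta"], strict)
        blips = [archive_io.blip_from_record(r) for r in rec["blips"]]
        blips = filter_blips(blips, params.filters)
        blips = hooks.fire("POST_BLIPS", blips, strict)
        if tstate is not None:
            if config.tracker == "nn":
                step_nn(tstate, blips, s_idx, config.tracker_params)
            else:
                step_mfc(tstate, blips, s_idx, config.tracker_params)
            tstate = hooks.fire("POST_TRACK_STEP", tstate, strict)
            for t in tstate.completed_this_step:
                hooks.fire("TRACK_COMPLETE", t, strict)
        summary.blips_found += len(blips)
        all_blips.extend(blips)
        out_records.append({**rec,
                            "blips": [archive_io.blip_to_record(b)
                                      for b in blips],
                            "meta": meta})
        summary.scans_processed += 1
        hooks.fire("SCAN_DONE", {"scan_index": s_idx,
                                 "n_blips": len(blips)}, strict)

    tracks = []
    if tstate is not None:
        n_before = len(tstate.completed)
        tracks = finalize_nn(tstate) if config.tracker == "nn" \
            else finalize_mfc(tstate, config.tracker_params)
        for t in tracks[n_before:]:
            hooks.fire("TRACK_COMPLETE", t, strict)
        summary.tracks_completed = len(tracks)
        by_blip = {id(b): t.id for t in tracks for b in t.blips}
        for b in all_blips:
            b.track_id = by_blip.get(id(b))
    try:
        if "blipmovie" in config.sinks:
            archive_io.write_blipmovie(out_records,
                                       config.sinks["blipmovie"])
            summary.sink_paths["blipmovie"] = config.sinks["blipmovie"]
        if "blips_csv" in config.sinks:
            archive_io.export_blips(all_blips, config.sinks["blips_csv"])
            summary.sink_paths["blips_csv"] = config.sinks["blips_csv"]
        if "tracks_csv" in config.sinks:
            archive_io.export_tracks(tracks, config.sinks["tracks_csv"])
            summary.sink_paths["tracks_csv"] = config.sinks["tracks_csv"]
    except OSError as exc:
        summary.ok = False
        summary.note = f"sink I/O failure, partial output: {exc}"
    return summary


def run_batch(config_paths: list) -> list[RunSummary]:
    """Run several jobs sequentially with isolated state.

    One failing job does not stop later jobs; failed jobs yield a summary
    with ok=False and the error in note.
    """
    out = []
    for path in config_paths:
        try:
            cfg = load_config(path)
            out.append(run_pipeline(cfg))
        except Exception as exc:
            log.error("job %s failed: %s", path, exc)
            out.append(RunSummary(ok=False, note=f"{path}: {exc}"))
    return out
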