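"""Archival containers and delimited-text exports.

Two archive kinds share one self-describing container: DEFLATE-compressed
(gzip) newline-delimited records in a canonical JSON serialization (keys
lexicographically sorted, no insignificant whitespace, shortest round-trip
float form).  Line 1 is the archive header; each further line is one scan.
Unknown keys at any level survive a read/write cycle untouched, which is
what makes the format forward and backward compatible: old readers ignore
new keys, new readers keep old files intact.

* **blipmovie** — per-scan metadata plus the extracted blips, each with its
  raw cells (row, col, value) and summary properties.  The compact archival
  record of an observation session.
* **rawscan** — full sample matrices, either dense (base64 of little-endian
  16-bit unsigned values, row-major) or sparse (only samples at or above a
  noise threshold, as triples), optionally restricted to an azimuth sector.

Exports are RFC-4180 CSV.
"""

from __future__ import annotations

import base64
import csv
import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .blips import Blip
from .scan import Scan, ScanMeta, azimuth_of_pulse
from .tracking import Track, track_stats

log = logging.getLogger(__name__)

SUPPORTED_VERSION = 1

BLIP_CSV_COLUMNS = ("ts", "x_m", "y_m", "z_m", "n_samples", "area_m2",
                    "perimeter_cells", "int_mean", "int_max",
                    "angular_span_deg", "radial_span_m", "track_id")

TRACK_CSV_COLUMNS = ("id", "n_blips", "t_start", "t_end", "mean_speed_mps",
                     "net_heading_deg", "straightness")


@dataclass
class ArchiveHeader:
    format: str
    version: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError("version must be >= 1")

    def to_dict(self) -> dict:
        d = {"format": self.format, "version": self.version}
        d.update(self.meta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchiveHeader":
        meta = {k: v for k, v in d.items() if k not in ("format", "version")}
        return cls(format=d["format"], version=int(d["version"]), meta=meta)


def _canon(obj) -> str:
    """Canonical JSON: sorted keys, minimal separators, shortest floats."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      allow_nan=False)


class ArchiveFormatError(ValueError):
    pass


def _read_lines(path) -> list[str]:
    try:
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return fh.read().splitlines()
    except (EOFError, OSError) as exc:
        raise ArchiveFormatError(f"truncated or unreadable archive: {exc}")


def _parse_line(line: str, lineno: int) -> dict:
    try:
        return json.loads(line)
    except json.JSONDecodeError as exc:
        raise ArchiveFormatError(f"malformed record at line {lineno}: {exc}")


def _check_header(d: dict, expect_format: str) -> ArchiveHeader:
    header = ArchiveHeader.from_dict(d)
    if header.format != expect_format:
        raise ArchiveFormatError(
            f"expected a {expect_format} archive, found {header.format!r}")
    if header.version > SUPPORTED_VERSION:
        log.warning("archive version %d newer than supported %d; "
                    "reading best-effort", header.version, SUPPORTED_VERSION)
    return header


# --------------------------------------------------------------------------
# blipmovies

def blip_to_record(blip: Blip) -> dict:
    return {"cells": [list(c) for c in blip.cells], "props": blip.props()}


def blip_from_record(rec: dict) -> Blip:
    props = rec["props"]
    known = {"t", "x", "y", "z", "n_samples", "area_m2", "perimeter_cells",
             "int_mean", "int_max", "angular_span_deg", "radial_span_m"}
    kw = {k: props[k] for k in known if k in props}
    return Blip(cells=[tuple(c) for c in rec["cells"]], **kw)


def scan_record(meta: ScanMeta, blips: Iterable[Blip]) -> dict:
    """Build one blipmovie record from scan metadata and its blips."""
    return {"meta": meta.to_dict(),
            "blips": [blip_to_record(b) for b in blips]}


def write_blipmovie(records: Iterable[dict], path,
                    header_meta: Optional[dict] = None) -> None:
    """Write a blipmovie: header line then one canonical record per scan.

    Records are open dicts ({"meta": {...}, "blips": [...]}) so that keys
    this library does not know about are preserved verbatim.
    """
    header = ArchiveHeader(format="blipmovie", version=SUPPORTED_VERSION,
                           meta=header_meta or {})
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(_canon(header.to_dict()) + "\n")
        for rec in records:
            fh.write(_canon(rec) + "\n")


def read_blipmovie(path) -> tuple[ArchiveHeader, list[dict]]:
    """Read a blipmovie; the exact inverse of write_blipmovie."""
    lines = _read_lines(path)
    if not lines:
        raise ArchiveFormatError("empty archive: no header line")
    header = _check_header(_parse_line(lines[0], 1), "blipmovie")
    records = [_parse_line(line, i + 2) for i, line in enumerate(lines[1:])]
    return header, records


# --------------------------------------------------------------------------
# raw scan archives

def _sector_cols(meta: ScanMeta, sector: tuple[float, float]) -> np.ndarray:
    az = azimuth_of_pulse(np.arange(meta.n_pulses), meta)
    lo, hi = sector[0] % 360.0, sector[1] % 360.0
    keep = ((az >= lo) & (az < hi)) if lo < hi else ((az >= lo) | (az < hi))
    return np.nonzero(keep)[0]


def write_raw(scans: Iterable[Scan], path,
              threshold: Optional[int] = None,
              sector: Optional[tuple[float, float]] = None,
              header_meta: Optional[dict] = None) -> None:
    """Write a raw scan archive.

    Dense mode (threshold None) stores each retained column block as base64
    of little-endian uint16, row-major.  With a threshold, sparse mode
    stores only (row, col, value) triples with value >= threshold.  With an
    azimuth sector (az_lo, az_hi), only columns whose azimuth falls inside
    are stored, together with their column indices so azimuth provenance is
    recoverable from the metadata.
    """
    header = ArchiveHeader(format="rawscan", version=SUPPORTED_VERSION,
                           meta=header_meta or {})
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(_canon(header.to_dict()) + "\n")
        for scan in scans:
            if scan.data.size and int(scan.data.max()) > 0xFFFF:
                raise ValueError("sample value exceeds 16-bit raw storage")
            rec: dict = {"meta": scan.meta.to_dict()}
            cols = None
            data = scan.data
            if sector is not None:
                cols = _sector_cols(scan.meta, sector)
                rec["cols"] = [int(c) for c in cols]
                data = data[:, cols]
            if threshold is None:
                dense = np.ascontiguousarray(data.astype("<u2"))
                rec["encoding"] = "dense"
                rec["data"] = base64.b64encode(dense.tobytes()).decode(
                    "ascii")
            else:
                rows, cidx = np.nonzero(data >= threshold)
                gcols = cols[cidx] if cols is not None else cidx
                rec["encoding"] = "sparse"
                rec["threshold"] = int(threshold)
                rec["cells"] = [[int(r), int(gc), int(data[r, ci])]
                                for r, gc, ci in zip(rows, gcols, cidx)]
            fh.write(_canon(rec) + "\n")


def read_raw(path) -> tuple[ArchiveHeader, list[Scan]]:
    """Read a raw archive back into full scans.

    Sparse records and sector-restricted records reconstruct with zeros in
    the positions that were not stored.
    """
    lines = _read_lines(path)
    if not lines:
        raise ArchiveFormatError("empty archive: no header line")
    header = _check_header(_parse_line(lines[0], 1), "rawscan")
    scans: list[Scan] = []
    for i, line in enumerate(lines[1:]):
        rec = _parse_line(line, i + 2)
        meta = ScanMeta.from_dict(rec["meta"])
        data = np.zeros((meta.n_samples, meta.n_pulses), dtype=np.uint16)
        if rec["encoding"] == "dense":
            try:
                buf = base64.b64decode(rec["data"], validate=True)
            except Exception as exc:
                raise ArchiveFormatError(
                    f"malformed base64 at line {i + 2}: {exc}")
            cols = rec.get("cols")
            ncols = len(cols) if cols is not None else meta.n_pulses
            block = np.frombuffer(buf, dtype="<u2").reshape(
                meta.n_samples, ncols)
            if cols is not None:
                data[:, np.asarray(cols, dtype=int)] = block
            else:
                data[:] = block
        elif rec["encoding"] == "sparse":
            for r, c, v in rec["cells"]:
                data[int(r), int(c)] = int(v)
        else:
            raise ArchiveFormatError(
                f"unknown encoding {rec['encoding']!r} at line {i + 2}")
        scans.append(Scan(meta=meta, data=data))
    return header, scans


# --------------------------------------------------------------------------
# delimited exports

def export_blips(blips: Iterable[Blip], path) -> None:
    """Export blips as RFC-4180 CSV with the fixed 12-column schema.

    track_id is written empty for untracked blips; tracked blips of one
    track share one id, and ids are dense positive integers in order of
    track creation.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BLIP_CSV_COLUMNS)
        for b in blips:
            w.writerow([repr(float(b.t)), repr(float(b.x)),
                        repr(float(b.y)), repr(float(b.z)),
                        b.n_samples, repr(float(b.area_m2)),
                        b.perimeter_cells, repr(float(b.int_mean)),
                        repr(float(b.int_max)),
                        repr(float(b.angular_span_deg)),
                        repr(float(b.radial_span_m)),
                        "" if b.track_id is None else b.track_id])


def export_tracks(tracks: Iterable[Track], path) -> None:
    """Export one summary row per track (see track_stats for definitions)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRACK_CSV_COLUMNS)
        for t in tracks:
            s = track_stats(t)
            w.writerow([s["id"], s["n_blips"], repr(float(s["t_start"])),
                        repr(float(s["t_end"])),
                        repr(float(s["mean_speed_mps"])),
                        repr(float(s["net_heading_deg"])),
                        repr(float(s["straightness"]))])
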