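"""Track-while-scan linking of blips across rotations.

Two linkers are provided:

* **NN** (nearest neighbour): each scan, feasible (track, blip) pairs —
  those whose implied speed, turning angle and relative change in blip area
  (or intensity) fall within user bounds — are assigned so as to minimize
  the total *extension distance* (3-D Euclidean distance from each track's
  last blip to its new blip), with exact ties settled by a seeded coin toss.
  Unmatched blips wait in a pool and may seed new two-blip tracks on a later
  scan, until their expiry age.

* **MFC** (multiframe correspondence): a non-iterative greedy algorithm
  over a sliding window of the last k scans.  The first two scans bootstrap
  with NN matching; thereafter candidate extensions are ranked by a *gain* —
  a weighted log-scale sum of proximity to the constant-velocity prediction
  and homogeneity of velocity — and accepted greedily without conflicts.
  Links within the window stay revisable (tracks can be broken and
  re-attached as new scans arrive); a link freezes once its scan slides out
  of the window, so tracks are retroactively corrected back k scans.
  The gain function is a pluggable hook.

Both linkers are deterministic given their tie-break seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .blips import Blip

_BIG = 1e12


@dataclass
class TrackerParams:
    """Feasibility bounds, gain weights and bookkeeping knobs.

    max_speed_mps / max_turn_deg / max_rel_change gate candidate links
    (all comparisons inclusive); expiry_scans bounds both the unmatched-blip
    pool age and NN track completion; k is the MFC window length; w_prox /
    w_vel weight the two gain components with scale constants sigma_p_m and
    sigma_v_mps; gain_min is the feasibility floor for MFC links.
    """

    max_speed_mps: float = 50.0
    max_turn_deg: float = 120.0
    max_rel_change: float = 2.0
    expiry_scans: int = 3
    k: int = 3
    w_prox: float = 1.0
    w_vel: float = 1.0
    sigma_p_m: float = 25.0
    sigma_v_mps: float = 10.0
    gain_min: float = -5.0
    rng_seed: int = 0
    rel_change_on: str = "area"        # "area" or "intensity"
    gain_fn: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.expiry_scans < 1:
            raise ValueError("expiry_scans must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.w_prox < 0 or self.w_vel < 0:
            raise ValueError("gain weights must be >= 0")
        if self.sigma_p_m <= 0 or self.sigma_v_mps <= 0:
            raise ValueError("gain sigmas must be positive")


@dataclass
class Track:
    """A time-ordered sequence of blips with the scan index of each."""

    id: int
    blips: list[Blip] = field(default_factory=list)
    scan_indices: list[int] = field(default_factory=list)
    state: str = "active"              # active | complete
    last_update_scan: int = -1


def _pos(b: Blip) -> np.ndarray:
    return np.array([b.x, b.y, b.z])


def _bearing_deg(dx: float, dy: float) -> float:
    return math.degrees(math.atan2(dx, dy)) % 360.0


def _rel_change(prev: Blip, new: Blip, on: str) -> float:
    a0 = prev.area_m2 if on == "area" else prev.int_mean
    a1 = new.area_m2 if on == "area" else new.int_mean
    return abs(a1 - a0) / a0 if a0 > 0 else (0.0 if a1 == a0 else math.inf)


def pair_features(track: Track, blip: Blip,
                  rel_change_on: str = "area"
                  ) -> tuple[float, float, float, float]:
    """(extension distance m, speed m/s, turn deg, relative change) for a
    candidate track extension.

    Distance is 3-D Euclidean from the track's last blip; turn is the
    absolute horizontal angle between the last track segment's heading and
    the candidate segment's heading (0 for single-blip tracks).
    """
    last = track.blips[-1]
    dt = blip.t - last.t
    if dt <= 0:
        raise ValueError("candidate blip must be later than track end")
    d = float(np.linalg.norm(_pos(blip) - _pos(last)))
    speed = d / dt
    turn = 0.0
    if len(track.blips) >= 2:
        prev = track.blips[-2]
        h0 = _bearing_deg(last.x - prev.x, last.y - prev.y)
        h1 = _bearing_deg(blip.x - last.x, blip.y - last.y)
        turn = abs(((h1 - h0 + 180.0) % 360.0) - 180.0)
    rel = _rel_change(last, blip, rel_change_on)
    return d, speed, turn, rel


def feasible_pairs(tracks: list[Track], blips: list[Blip],
                   params: TrackerParams
                   ) -> list[tuple[int, int, float]]:
    """(track index, blip index, extension distance) for all pairs whose
    speed, turn and relative change lie within the bounds (inclusive)."""
    out = []
    for ti, track in enumerate(tracks):
        for bi, blip in enumerate(blips):
            if blip.t <= track.blips[-1].t:
                continue
            d, speed, turn, rel = pair_features(track, blip,
                                                params.rel_change_on)
            if (speed <= params.max_speed_mps
                    and turn <= params.max_turn_deg
                    and rel <= params.max_rel_change):
                out.append((ti, bi, d))
    return out


def assign_min_cost(pairs: list[tuple], rng: np.random.Generator
                    ) -> list[tuple]:
    """Optimal one-to-one assignment over feasible pairs.

    Returns the subset of pairs forming a maximum-cardinality matching of
    minimum total cost; exact ties between optimal matchings are broken by
    a seeded infinitesimal perturbation (the "coin toss"), so the choice is
    uniform-ish but reproducible.
    """
    if not pairs:
        return []
    a_keys = sorted({p[0] for p in pairs})
    b_keys = sorted({p[1] for p in pairs})
    ai = {k: i for i, k in enumerate(a_keys)}
    bi = {k: i for i, k in enumerate(b_keys)}
    cost = np.full((len(a_keys), len(b_keys)), _BIG)
    for a, b, c in pairs:
        cost[ai[a], bi[b]] = min(cost[ai[a], bi[b]], c)
    finite = cost[cost < _BIG / 2]
    eps = 1e-9 * (1.0 + (finite.max() if finite.size else 1.0))
    pert = cost + rng.random(cost.shape) * eps
    rows, cols = linear_sum_assignment(pert)
    out = []
    for r, c in zip(rows, cols):
        if cost[r, c] < _BIG / 2:
            out.append((a_keys[r], b_keys[c], float(cost[r, c])))
    return out


# --------------------------------------------------------------------------
# nearest-neighbour tracker

@dataclass
class NNTrackerState:
    tracks: list[Track] = field(default_factory=list)
    completed: list[Track] = field(default_factory=list)
    pool: list[tuple[int, Blip]] = field(default_factory=list)
    next_id: int = 1
    scan_counter: int = -1
    completed_this_step: list[Track] = field(default_factory=list)
    rng: np.random.Generator = None  # type: ignore[assignment]


def make_nn_state(params: TrackerParams) -> NNTrackerState:
    return NNTrackerState(rng=np.random.default_rng(params.rng_seed))


def _seed_pairs(pool: list[tuple[int, Blip]], blips: list[Blip],
                remaining: list[int], params: TrackerParams
                ) -> list[tuple[int, int, float]]:
    pairs = []
    for pi, (_, pblip) in enumerate(pool):
        for bi in remaining:
            blip = blips[bi]
            dt = blip.t - pblip.t
            if dt <= 0:
                continue
            d = float(np.linalg.norm(_pos(blip) - _pos(pblip)))
            if (d / dt <= params.max_speed_mps
                    and _rel_change(pblip, blip, params.rel_change_on)
                    <= params.max_rel_change):
                pairs.append((pi, bi, d))
    return pairs


def step_nn(state: NNTrackerState, blips: list[Blip], scan_index: int,
            params: TrackerParams) -> NNTrackerState:
    """Advance the NN tracker by one scan (mutates and returns state).

    Matched tracks are extended; leftover blips first try to pair with
    pooled unmatched blips from recent scans (seeding new two-blip tracks),
    then join the pool themselves.  Pool entries older than expiry_scans
    are dropped; tracks unextended for expiry_scans complete.
    """
    state.scan_counter = scan_index
    state.completed_this_step = []
    state.pool = [(s, b) for (s, b) in state.pool
                  if scan_index - s <= params.expiry_scans]

    pairs = feasible_pairs(state.tracks, blips, params)
    matched_b: set[int] = set()
    for ti, bi, _ in assign_min_cost(pairs, state.rng):
        t = state.tracks[ti]
        t.blips.append(blips[bi])
        t.scan_indices.append(scan_index)
        t.last_update_scan = scan_index
        matched_b.add(bi)

    remaining = [i for i in range(len(blips)) if i not in matched_b]
    seed_pairs = _seed_pairs(state.pool, blips, remaining, params)
    used_pool: set[int] = set()
    for pi, bi, _ in assign_min_cost(seed_pairs, state.rng):
        ps, pblip = state.pool[pi]
        track = Track(id=state.next_id, blips=[pblip, blips[bi]],
                      scan_indices=[ps, scan_index],
                      last_update_scan=scan_index)
        state.next_id += 1
        state.tracks.append(track)
        used_pool.add(pi)
        matched_b.add(bi)

    state.pool = [e for i, e in enumerate(state.pool) if i not in used_pool]
    state.pool.extend((scan_index, blips[i]) for i in range(len(blips))
                      if i not in matched_b)

    still_active = []
    for t in state.tracks:
        if scan_index - t.last_update_scan >= params.expiry_scans:
            t.state = "complete"
            state.completed.append(t)
            state.completed_this_step.append(t)
        else:
            still_active.append(t)
    state.tracks = still_active
    return state


def finalize_nn(state: NNTrackerState) -> list[Track]:
    """Complete all remaining active tracks; return every track by id."""
    for t in state.tracks:
        t.state = "complete"
        state.completed.append(t)
        state.completed_this_step = state.completed_this_step + [t]
    state.tracks = []
    return sorted(state.completed, key=lambda t: t.id)


# --------------------------------------------------------------------------
# gain and the multiframe-correspondence tracker

def gain(track: Track, blip: Blip, params: TrackerParams) -> float:
    """Match quality of extending a track (>= 2 blips) with a blip.

    With constant-velocity prediction p_hat = p_last + v_last * dt,
    d = |p_blip - p_hat| and dv = |v_new - v_last|:

        gain = -w_prox * ln(1 + d / sigma_p) - w_vel * ln(1 + dv / sigma_v)

    Bounded above by 0 (perfect prediction, unchanged velocity).  A custom
    gain_fn(track, blip, params) in TrackerParams replaces this form.
    """
    if params.gain_fn is not None:
        return params.gain_fn(track, blip, params)
    if len(track.blips) < 2:
        raise ValueError("gain needs a track with at least 2 blips")
    p1, p2 = _pos(track.blips[-2]), _pos(track.blips[-1])
    t1, t2 = track.blips[-2].t, track.blips[-1].t
    dt_new = blip.t - t2
    if dt_new <= 0:
        raise ValueError("candidate blip must be later than track end")
    v_last = (p2 - p1) / (t2 - t1)
    p_hat = p2 + v_last * dt_new
    pb = _pos(blip)
    d = float(np.linalg.norm(pb - p_hat))
    v_new = (pb - p2) / dt_new
    dv = float(np.linalg.norm(v_new - v_last))
    return (-params.w_prox * math.log1p(d / params.sigma_p_m)
            - params.w_vel * math.log1p(dv / params.sigma_v_mps))


@dataclass
class _RepTrack:
    """A track as seen by one window replay: committed base + window blips."""

    base: Optional[Track]
    blips: list[Blip]
    scans: list[int]


@dataclass
class MFCTrackerState:
    frozen_tracks: list[Track] = field(default_factory=list)
    completed: list[Track] = field(default_factory=list)
    frozen_pool: list[tuple[int, Blip]] = field(default_factory=list)
    window: list[tuple[int, list[Blip]]] = field(default_factory=list)
    next_id: int = 1
    scan_counter: int = -1
    completed_this_step: list[Track] = field(default_factory=list)
    view: list[_RepTrack] = field(default_factory=list)


def make_mfc_state(params: TrackerParams) -> MFCTrackerState:
    return MFCTrackerState()


def _assoc_step(rep: list[_RepTrack], pool: list[tuple[int, Blip]],
                blips: list[Blip], scan_index: int,
                params: TrackerParams, rng: np.random.Generator) -> None:
    """One scan of gain-greedy association inside a replay (mutates rep/pool)."""
    used_b: set[int] = set()
    # phase 1: gain-ranked greedy extension of tracks with velocity
    cands = []
    for ri, r in enumerate(rep):
        if len(r.blips) < 2:
            continue
        fake = Track(id=0, blips=r.blips, scan_indices=r.scans)
        for bi, blip in enumerate(blips):
            if blip.t <= r.blips[-1].t:
                continue
            _, speed, turn, rel = pair_features(fake, blip,
                                                params.rel_change_on)
            if (speed > params.max_speed_mps or turn > params.max_turn_deg
                    or rel > params.max_rel_change):
                continue
            g = gain(fake, blip, params)
            if g >= params.gain_min:
                tid = r.base.id if r.base is not None else 10 ** 9 + ri
                cands.append((g, tid, blip.azimuth_deg, ri, bi))
    coins = rng.random(len(cands))
    order = sorted(range(len(cands)),
                   key=lambda i: (-cands[i][0], cands[i][1], cands[i][2],
                                  coins[i]))
    used_r: set[int] = set()
    for i in order:
        _, _, _, ri, bi = cands[i]
        if ri in used_r or bi in used_b:
            continue
        rep[ri].blips.append(blips[bi])
        rep[ri].scans.append(scan_index)
        used_r.add(ri)
        used_b.add(bi)

    # phase 2: NN-style matching for seeds (1-blip tracks and pooled blips)
    remaining = [i for i in range(len(blips)) if i not in used_b]
    pairs = []
    for ri, r in enumerate(rep):
        if len(r.blips) != 1 or ri in used_r:
            continue
        for bi in remaining:
            blip = blips[bi]
            dt = blip.t - r.blips[-1].t
            if dt <= 0:
                continue
            d = float(np.linalg.norm(_pos(blip) - _pos(r.blips[-1])))
            if (d / dt <= params.max_speed_mps
                    and _rel_change(r.blips[-1], blip,
                                    params.rel_change_on)
                    <= params.max_rel_change):
                pairs.append((("t", ri), bi, d))
    for pi, (_, pblip) in enumerate(pool):
        for bi in remaining:
            blip = blips[bi]
            dt = blip.t - pblip.t
            if dt <= 0:
                continue
            d = float(np.linalg.norm(_pos(blip) - _pos(pblip)))
            if (d / dt <= params.max_speed_mps
                    and _rel_change(pblip, blip, params.rel_change_on)
                    <= params.max_rel_change):
                pairs.append((("p", pi), bi, d))
    used_pool: set[int] = set()
    for (kind, idx), bi, _ in assign_min_cost(pairs, rng):
        if kind == "t":
            rep[idx].blips.append(blips[bi])
            rep[idx].scans.append(scan_index)
        else:
            ps, pblip = pool[idx]
            rep.append(_RepTrack(base=None, blips=[pblip, blips[bi]],
                                 scans=[ps, scan_index]))
            used_pool.add(idx)
        used_b.add(bi)

    pool[:] = [e for i, e in enumerate(pool) if i not in used_pool]
    pool.extend((scan_index, blips[i]) for i in range(len(blips))
                if i not in used_b)
    pool[:] = [(s, b) for (s, b) in pool
               if scan_index - s <= params.expiry_scans]


def _replay(state: MFCTrackerState, params: TrackerParams
            ) -> tuple[list[_RepTrack], list[tuple[int, Blip]]]:
    rng = np.random.default_rng(
        [abs(int(params.rng_seed)), state.scan_counter + 1])
    rep = [_RepTrack(base=t, blips=list(t.blips), scans=list(t.scan_indices))
           for t in state.frozen_tracks]
    pool = list(state.frozen_pool)
    for si, blips in state.window:
        _assoc_step(rep, pool, blips, si, params, rng)
    return rep, pool


def _commit_oldest(state: MFCTrackerState, rep: list[_RepTrack],
                   params: TrackerParams) -> None:
    """Freeze the links of the oldest window scan and drop it."""
    s0, blips0 = state.window.pop(0)
    assigned: set[int] = set()
    for r in rep:
        for q, sc in enumerate(r.scans):
            if sc != s0:
                continue
            assigned.add(id(r.blips[q]))
            if r.base is not None:
                r.base.blips.append(r.blips[q])
                r.base.scan_indices.append(s0)
                r.base.last_update_scan = s0
            elif q == 0:
                t = Track(id=state.next_id, blips=[r.blips[q]],
                          scan_indices=[s0], last_update_scan=s0)
                state.next_id += 1
                state.frozen_tracks.append(t)
                r.base = t
    for b in blips0:
        if id(b) not in assigned:
            state.frozen_pool.append((s0, b))
    state.frozen_pool = [(s, b) for (s, b) in state.frozen_pool
                         if state.scan_counter - s <= params.expiry_scans]


def step_mfc(state: MFCTrackerState, blips: list[Blip], scan_index: int,
             params: TrackerParams) -> MFCTrackerState:
    """Advance the MFC tracker by one scan (mutates and returns state).

    The new scan joins the correction window; links are recomputed greedily
    by gain over the whole window (so earlier window links may break and
    re-attach), the link of the scan sliding out of the window is frozen,
    and frozen tracks with no blip in the last k scans complete.
    """
    state.scan_counter = scan_index
    state.completed_this_step = []
    state.window.append((scan_index, list(blips)))
    rep, _ = _replay(state, params)
    if len(state.window) > params.k:
        _commit_oldest(state, rep, params)
        rep, _ = _replay(state, params)
    state.view = rep

    extended = {id(r.base) for r in rep
                if r.base is not None and len(r.blips) > len(r.base.blips)}
    still = []
    for t in state.frozen_tracks:
        if id(t) not in extended and \
                scan_index - t.last_update_scan >= params.k:
            if len(t.blips) >= 2:
                t.state = "complete"
                state.completed.append(t)
                state.completed_this_step.append(t)
        else:
            still.append(t)
    state.frozen_tracks = still
    state.view = [r for r in rep if r.base is None
                  or any(tt is r.base for tt in state.frozen_tracks)
                  or len(r.blips) > len(r.base.blips)]
    return state


def mfc_tracks(state: MFCTrackerState) -> list[Track]:
    """Current track view (committed prefixes plus revisable window links)."""
    out = []
    for r in state.view:
        if len(r.blips) < 2:
            continue
        tid = r.base.id if r.base is not None else 0
        out.append(Track(id=tid, blips=list(r.blips),
                         scan_indices=list(r.scans),
                         state="active",
                         last_update_scan=r.scans[-1]))
    return out


def finalize_mfc(state: MFCTrackerState, params: TrackerParams
                 ) -> list[Track]:
    """Commit every remaining window scan and complete all tracks.

    Tracks that never reached two blips are discarded (they are just
    unmatched blips).  Returns all tracks ordered by id.
    """
    while state.window:
        rep, _ = _replay(state, params)
        _commit_oldest(state, rep, params)
    newly = []
    for t in state.frozen_tracks:
        if len(t.blips) >= 2:
            t.state = "complete"
            state.completed.append(t)
            newly.append(t)
    state.completed_this_step = newly
    state.frozen_tracks = []
    state.view = []
    out = sorted(state.completed, key=lambda t: t.id)
    # committed seeds that never reached 2 blips are dropped, which can
    # leave id holes; renumber densely preserving creation order
    for i, t in enumerate(out, start=1):
        t.id = i
    return out


# --------------------------------------------------------------------------
# evaluation against ground truth

def track_stats(track: Track) -> dict:
    """Summary of one track: timing, mean speed, net heading, straightness.

    mean_speed is the mean of consecutive-pair speeds; net_heading the
    bearing from first to last blip; straightness = net displacement / path
    length (1 for a straight track, 0 for out-and-back).
    """
    bl = track.blips
    speeds, path = [], 0.0
    for a, b in zip(bl, bl[1:]):
        d = float(np.linalg.norm(_pos(b) - _pos(a)))
        path += d
        dt = b.t - a.t
        speeds.append(d / dt if dt > 0 else 0.0)
    net = float(np.linalg.norm(_pos(bl[-1]) - _pos(bl[0])))
    return {
        "id": track.id,
        "n_blips": len(bl),
        "t_start": bl[0].t,
        "t_end": bl[-1].t,
        "mean_speed_mps": float(np.mean(speeds)) if speeds else 0.0,
        "net_heading_deg": _bearing_deg(bl[-1].x - bl[0].x,
                                        bl[-1].y - bl[0].y),
        "straightness": net / path if path > 0 else 1.0,
    }


def evaluate_tracks(est_tracks: list[Track], truth, match_radius_m: float
                    ) -> tuple[float, float, float]:
    """(link precision, link recall, track purity) against ground truth.

    A recovered link (two consecutive blips of one estimated track) is
    correct iff both blips lie within match_radius of the same truth target
    at their scans and those truth detections are on consecutive scans.
    Precision is correct/estimated links (1.0 by convention when no links
    are claimed); recall is correct/truth links; purity is the per-track
    majority-target blip fraction averaged over tracks.
    """
    import pandas as pd  # local import keeps module import light

    if truth is None or len(truth) == 0:
        raise ValueError("empty ground truth")
    tdf = truth[truth["in_range"]]
    lookup: dict[tuple[int, int], tuple[float, float]] = {}
    for r in tdf.itertuples(index=False):
        lookup[(int(r.scan), int(r.target_id))] = (r.x, r.y)
    truth_links = 0
    for gid, grp in tdf.groupby("target_id"):
        scans = sorted(grp["scan"].astype(int))
        truth_links += sum(1 for a, b in zip(scans, scans[1:]) if b == a + 1)

    def match_target(blip: Blip, scan: int) -> Optional[int]:
        best, best_d = None, match_radius_m
        for (s, g), (tx, ty) in lookup.items():
            if s != scan:
                continue
            d = math.hypot(blip.x - tx, blip.y - ty)
            if d <= best_d:
                best, best_d = g, d
        return best

    est_links = correct = 0
    purities = []
    for track in est_tracks:
        assigns = [match_target(b, s)
                   for b, s in zip(track.blips, track.scan_indices)]
        for i in range(len(track.blips) - 1):
            est_links += 1
            s1, s2 = track.scan_indices[i], track.scan_indices[i + 1]
            g1, g2 = assigns[i], assigns[i + 1]
            if g1 is not None and g1 == g2 and s2 == s1 + 1:
                correct += 1
        if assigns:
            counts = pd.Series([a for a in assigns]).value_counts(
                dropna=True)
            top = int(counts.iloc[0]) if len(counts) else 0
            purities.append(top / len(assigns))
    precision = correct / est_links if est_links else 1.0
    recall = correct / truth_links if truth_links else 0.0
    purity = float(np.mean(purities)) if purities else 1.0
    return precision, recall, purity
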