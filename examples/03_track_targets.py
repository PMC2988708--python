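"""Link blips into tracks with the NN and MFC trackers and compare them.

Uses a hand-built crossing-targets instance: two point targets fly through
each other.  The nearest-neighbour linker, which only minimizes extension
distance, swaps the tracks at the crossing; the multiframe-correspondence
linker scores candidates by proximity to the constant-velocity prediction
plus velocity homogeneity and keeps them apart.
"""

import pandas as pd

from aeroscan import (Blip, TrackerParams, evaluate_tracks, finalize_mfc,
                      finalize_nn, make_mfc_state, make_nn_state, step_mfc,
                      step_nn, track_stats)


def blip(x, y, t):
    return Blip(cells=[(0, 0, 100)], t=t, x=x, y=y, z=0.0, n_samples=4,
                area_m2=10.0, perimeter_cells=4, int_mean=100.0,
                int_max=120.0, angular_span_deg=1.0, radial_span_m=3.0)


# A heads east at 8 m/s, B heads west at 8 m/s; they pass between scans 1-2
scans = [[blip(-12 + 8 * s, 0.0, float(s)),
          blip(12 - 8 * s, 0.5, float(s))] for s in range(5)]
truth = pd.DataFrame(
    [(s, 1, float(s), -12 + 8 * s, 0.0, 0, 0, True) for s in range(5)]
    + [(s, 2, float(s), 12 - 8 * s, 0.5, 0, 0, True) for s in range(5)],
    columns=["scan", "target_id", "t", "x", "y", "row", "col", "in_range"])

params = TrackerParams(max_speed_mps=100, max_turn_deg=180,
                       max_rel_change=10, k=3, rng_seed=0)

st = make_nn_state(params)
for s, blips in enumerate(scans):
    step_nn(st, blips, s, params)
nn = finalize_nn(st)
p, r, pu = evaluate_tracks(nn, truth, 1.0)
print(f"NN : {len(nn)} tracks, precision {p:.2f}, recall {r:.2f}, "
      f"purity {pu:.2f}")

st = make_mfc_state(params)
for s, blips in enumerate(scans):
    step_mfc(st, blips, s, params)
mfc = finalize_mfc(st, params)
p, r, pu = evaluate_tracks(mfc, truth, 1.0)
print(f"MFC: {len(mfc)} tracks, precision {p:.2f}, recall {r:.2f}, "
      f"purity {pu:.2f}")
for t in mfc:
    s = track_stats(t)
    print(f"  track {t.id}: {s['n_blips']} blips, "
          f"{s['mean_speed_mps']:.1f} m/s, heading "
          f"{s['net_heading_deg']:.0f} deg, straightness "
          f"{s['straightness']:.2f}")
# Purity 1.0 for MFC means every blip landed on its own target's track;
# the NN purity below 1.0 is the swap at the crossing.
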