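import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aeroscan import (BackgroundModel, BlipFilters, ExtractionParams,
                      PolarGeometry, Scan, ScanMeta, SectorRule,
                      StatsCellGrid, apply_sector_rules, blip_properties,
                      extract_blips, filter_blips, find_hot, group_patches,
                      learn_background, update_background, zscore)


def _meta(n_samples=16, n_pulses=16, **kw):
    kw.setdefault("duration_s", 2.0)
    return ScanMeta(t0=0.0, n_pulses=n_pulses, n_samples=n_samples,
                    rate_hz=50e6, **kw)


def _scan(arr, **kw):
    arr = np.asarray(arr, dtype=np.uint16)
    return Scan(_meta(arr.shape[0], arr.shape[1], **kw), arr)


# --------------------------------------------------------------------------
# background learning

def naive_pooled_stats(stack, grid):
    """Brute-force oracle: double loop over stats cells, pooling values
    across scans; mean and mean absolute deviation per cell."""
    n_scans, n_samples, n_pulses = stack.shape
    n_cr = max(n_samples // grid.cell_rows, 1)
    n_cc = max(n_pulses // grid.cell_cols, 1)
    m = np.zeros((n_cr, n_cc))
    d = np.zeros((n_cr, n_cc))
    for a in range(n_cr):
        r0 = a * grid.cell_rows
        r1 = (a + 1) * grid.cell_rows if a < n_cr - 1 else n_samples
        for b in range(n_cc):
            c0 = b * grid.cell_cols
            c1 = (b + 1) * grid.cell_cols if b < n_cc - 1 else n_pulses
            vals = stack[:, r0:r1, c0:c1].astype(float).ravel()
            m[a, b] = vals.mean()
            d[a, b] = np.abs(vals - vals.mean()).mean()
    return m, d


class TestLearnBackground:
    def test_constant_scans(self):
        scans = [_scan(np.full((8, 8), 100)) for _ in range(3)]
        bg = learn_background(scans, StatsCellGrid(4, 4))
        assert np.all(bg.m == 100) and np.all(bg.d == 0)
        assert bg.n_learned == 3

    def test_two_level_mean_deviation(self):
        scans = [_scan(np.full((4, 4), 90)), _scan(np.full((4, 4), 110))]
        bg = learn_background(scans, StatsCellGrid(2, 2))
        assert np.all(bg.m == 100) and np.all(bg.d == 10)

    @pytest.mark.parametrize("shape,cell", [((16, 16), (4, 4)),
                                            ((10, 14), (4, 4)),
                                            ((8, 8), (3, 5))])
    def test_matches_naive_oracle(self, shape, cell):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 400, (3, *shape))
        scans = [_scan(s) for s in stack]
        grid = StatsCellGrid(*cell)
        bg = learn_background(scans, grid)
        m, d = naive_pooled_stats(stack, grid)
        np.testing.assert_allclose(bg.m, m, rtol=1e-12)
        np.testing.assert_allclose(bg.d, d, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            learn_background([_scan(np.zeros((4, 4))),
                              _scan(np.zeros((4, 6)))], StatsCellGrid(2, 2))
        with pytest.raises(ValueError):
            learn_background([], StatsCellGrid(2, 2))


class TestZscore:
    def test_basics(self):
        assert zscore(100, 100, 10) == 0.0
        assert zscore(130, 100, 10) == 3.0

    def test_degenerate_deviation(self):
        assert zscore(101, 100, 0) == math.inf
        assert zscore(99, 100, 0) == -math.inf
        assert zscore(100, 100, 0) == 0.0


class TestFindHot:
    def test_background_scan_all_cold(self):
        scans = [_scan(np.full((8, 8), 100))]
        bg = learn_background(scans, StatsCellGrid(4, 4))
        assert not find_hot(scans[0], bg, 3.0).any()

    def test_single_outlier(self):
        rng = np.random.default_rng(1)
        base = rng.integers(90, 110, (8, 8))
        bg = learn_background([_scan(base)], StatsCellGrid(4, 4))
        data = base.copy()
        m, d = bg.expand(8, 8)
        data[3, 3] = int(m[3, 3] + 5 * d[3, 3]) + 1
        mask = find_hot(_scan(data), bg, 3.0)
        assert mask.sum() == 1 and mask[3, 3]

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 300, (3, 12, 12))
        grid = StatsCellGrid(3, 3)
        bg = learn_background([_scan(b) for b in base], grid)
        scan = _scan(rng.integers(0, 400, (12, 12)))
        mask = find_hot(scan, bg, 2.5)
        m, d = bg.expand(12, 12)
        for i in range(12):
            for j in range(12):
                assert mask[i, j] == (
                    zscore(scan.data[i, j], m[i, j], d[i, j]) > 2.5)


# --------------------------------------------------------------------------
# patches

def floodfill_components(mask):
    """BFS oracle for 8-connected components with azimuth wraparound."""
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, (c + dc) % n_cols
                        if (0 <= rr < n_rows and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            q.append((rr, cc))
            comps.append(frozenset(comp))
    return set(comps)


class TestGroupPatches:
    def test_single_cell(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        patches = group_patches(mask)
        assert len(patches) == 1 and len(patches[0]) == 1

    def test_seam_join(self):
        mask = np.zeros((8, 16), dtype=bool)
        mask[5, 0] = mask[5, 15] = True
        patches = group_patches(mask)
        assert len(patches) == 1 and len(patches[0]) == 2
        assert patches[0].min_unwrapped_col == 15

    def test_seam_join_diagonal(self):
        mask = np.zeros((8, 16), dtype=bool)
        mask[5, 0] = mask[6, 15] = True
        assert len(group_patches(mask)) == 1

    def test_matches_floodfill_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            mask = rng.random((16, 16)) < 0.35
            patches = group_patches(mask)
            got = {frozenset((r, c) for r, c, _ in p.cells)
                   for p in patches}
            assert got == floodfill_components(mask)

    def test_deterministic_order(self):
        rng = np.random.default_rng(4)
        mask = rng.random((16, 16)) < 0.2
        a = group_patches(mask)
        b = group_patches(mask)
        assert [p.cells for p in a] == [p.cells for p in b]
        keys = [(p.bbox[0], p.min_unwrapped_col) for p in a]
        assert keys == sorted(keys)


class TestBlipProperties:
    def test_single_cell_patch(self):
        data = np.zeros((16, 16), dtype=np.uint16)
        i, j = 5, 3
        data[i, j] = 200
        scan = _scan(data)
        geom = PolarGeometry.from_meta(scan.meta)
        mask = data > 0
        blip = blip_properties(group_patches(mask, scan)[0], scan)
        dth = math.radians(geom.dtheta_deg)
        assert blip.n_samples == 1
        assert blip.area_m2 == pytest.approx(
            (i + 0.5) * geom.dr_m ** 2 * dth)
        assert blip.perimeter_cells == 1
        assert blip.angular_span_deg == pytest.approx(geom.dtheta_deg)
        assert blip.radial_span_m == pytest.approx(geom.dr_m)
        assert blip.int_mean == blip.int_max == 200
        # timestamp interpolates by pulse column within the rotation
        assert blip.t == pytest.approx(j * 2.0 / 16)

    def test_square_block_symmetry(self):
        data = np.zeros((16, 16), dtype=np.uint16)
        data[4:6, 6:8] = 100
        scan = _scan(data)
        blip = blip_properties(group_patches(data > 0, scan)[0], scan)
        assert blip.n_samples == 4 and blip.perimeter_cells == 4
        geom = PolarGeometry.from_meta(scan.meta)
        from aeroscan import azimuth_of_pulse, polar_to_xyz, range_of_sample
        xs, ys = [], []
        for r, c, _ in [(4, 6, 0), (4, 7, 0), (5, 6, 0), (5, 7, 0)]:
            x, y, _ = polar_to_xyz(range_of_sample(r, geom),
                                   azimuth_of_pulse(c, scan.meta),
                                   scan.meta.antenna)
            xs.append(x)
            ys.append(y)
        assert blip.x == pytest.approx(np.mean(xs))
        assert blip.y == pytest.approx(np.mean(ys))

    def test_l_shape_perimeter_and_area(self):
        data = np.zeros((16, 16), dtype=np.uint16)
        cells = [(7, 7), (8, 7), (8, 8)]
        for r, c in cells:
            data[r, c] = 50
        scan = _scan(data)
        geom = PolarGeometry.from_meta(scan.meta)
        blip = blip_properties(group_patches(data > 0, scan)[0], scan)
        assert blip.perimeter_cells == 3
        expected_area = sum((r + 0.5) * geom.dr_m ** 2
                            * math.radians(geom.dtheta_deg)
                            for r, _ in cells)
        assert blip.area_m2 == pytest.approx(expected_area)


class TestFilters:
    def _blips(self):
        data = np.zeros((16, 16), dtype=np.uint16)
        singles = [(1, 1), (3, 5), (5, 9)]
        for r, c in singles:
            data[r, c] = 90
        data[8, 2:5] = 90     # two 3-cell blips
        data[11, 6:9] = 90
        scan = _scan(data)
        return [blip_properties(p, scan)
                for p in group_patches(data > 0, scan)]

    def test_no_bounds_identity(self):
        blips = self._blips()
        assert filter_blips(blips, BlipFilters()) == blips

    def test_min_samples(self):
        out = filter_blips(self._blips(), BlipFilters(min_n_samples=2))
        assert len(out) == 2
        assert all(b.n_samples == 3 for b in out)

    def test_matches_per_blip_recheck(self):
        rng = np.random.default_rng(5)
        blips = self._blips()
        for _ in range(20):
            f = BlipFilters(
                min_n_samples=int(rng.integers(0, 4)) or None,
                max_area_m2=float(rng.uniform(0, 50)),
                min_radial_span_m=float(rng.uniform(0, 5)))
            got = filter_blips(blips, f)
            expected = [b for b in blips if f.passes(b)]
            assert got == expected

    def test_predicate_hook(self):
        out = filter_blips(self._blips(),
                           BlipFilters(predicate=lambda b: b.n_samples == 1))
        assert len(out) == 3


class TestUpdateBackground:
    def _bg(self):
        return learn_background([_scan(np.full((8, 8), 100))],
                                StatsCellGrid(4, 4))

    def test_alpha_zero_identity(self):
        bg = self._bg()
        out = update_background(bg, _scan(np.full((8, 8), 200)), 0.0)
        assert np.all(out.m == 100) and np.all(out.d == 0)

    def test_alpha_one_single_scan_stats(self):
        bg = self._bg()
        scan = _scan(np.random.default_rng(6).integers(0, 200, (8, 8)))
        out = update_background(bg, scan, 1.0)
        fresh = learn_background([scan], bg.grid)
        np.testing.assert_allclose(out.m, fresh.m)
        np.testing.assert_allclose(out.d, fresh.d)

    @pytest.mark.parametrize("alpha,n", [(0.1, 7), (0.5, 4), (0.9, 12)])
    def test_geometric_convergence_closed_form(self, alpha, n):
        bg = self._bg()
        target = _scan(np.full((8, 8), 150))
        for _ in range(n):
            bg = update_background(bg, target, alpha)
        expected = (1 - alpha) ** n * 100 + (1 - (1 - alpha) ** n) * 150
        np.testing.assert_allclose(bg.m, expected, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
    def test_fixed_point(self, alpha):
        # updating with a scan whose stats equal the background is a no-op
        scan = _scan(np.random.default_rng(7).integers(50, 250, (8, 8)))
        bg = learn_background([scan], StatsCellGrid(4, 4))
        out = update_background(bg, scan, alpha)
        np.testing.assert_allclose(out.m, bg.m, rtol=1e-12)
        np.testing.assert_allclose(out.d, bg.d, rtol=1e-12)


class TestSectorRules:
    def _blips_and_mask(self):
        data = np.zeros((16, 16), dtype=np.uint16)
        data[5, 2] = 100    # azimuth 45 deg
        data[5, 10] = 100   # azimuth 225 deg
        scan = _scan(data)
        mask = data > 0
        blips = [blip_properties(p, scan)
                 for p in group_patches(mask, scan)]
        return blips, mask, scan.meta

    def test_empty_sector_list_identity(self):
        blips, mask, meta = self._blips_and_mask()
        out_b, out_m = apply_sector_rules(blips, mask, [], meta)
        assert out_b == blips and out_m is mask

    def test_discard_sector(self):
        blips, mask, meta = self._blips_and_mask()
        rules = [SectorRule(az_lo=180, az_hi=360, action="discard")]
        out_b, out_m = apply_sector_rules(blips, mask, rules, meta)
        assert all(b.azimuth_deg < 180 for b in out_b)
        assert len(out_b) == 1
        assert out_m[5, 10] == False and out_m[5, 2] == True  # noqa: E712

    def test_first_listed_sector_wins(self):
        blips, _, meta = self._blips_and_mask()
        rules = [SectorRule(az_lo=0, az_hi=90, action="override",
                            override_filters=BlipFilters()),
                 SectorRule(az_lo=0, az_hi=180, action="discard")]
        out_b, _ = apply_sector_rules(blips, None, rules, meta)
        # the 45-deg blip hits the permissive override first, so survives
        assert any(b.azimuth_deg < 90 for b in out_b)


class TestExtractBlips:
    def _learned(self):
        rng = np.random.default_rng(8)
        scans = [_scan(rng.integers(90, 110, (32, 32))) for _ in range(4)]
        bg = learn_background(scans, StatsCellGrid(8, 8))
        return scans, bg

    def test_background_scan_yields_nothing(self):
        scans, bg = self._learned()
        blips, _ = extract_blips(scans[0], bg,
                                 ExtractionParams(z_thresh=6.0,
                                                  update_enabled=False))
        assert blips == []

    def test_equals_manual_composition(self):
        scans, bg = self._learned()
        rng = np.random.default_rng(9)
        data = scans[0].data.copy()
        data[10:13, 20:23] += 200
        data[rng.integers(0, 32, 10), rng.integers(0, 32, 10)] += 150
        scan = _scan(data)
        params = ExtractionParams(z_thresh=3.0, update_enabled=False,
                                  grid=StatsCellGrid(8, 8),
                                  filters=BlipFilters(min_n_samples=2))
        got, _ = extract_blips(scan, bg, params)
        mask = find_hot(scan, bg, params.z_thresh)
        expected = [blip_properties(p, scan)
                    for p in group_patches(mask, scan)]
        expected = filter_blips(expected, params.filters)
        expected.sort(key=lambda b: (b.t, b.azimuth_deg))
        assert got == expected

    def test_hot_monotone_in_threshold(self):
        # isolated targets of staggered brightness: raising the threshold
        # can only remove detections, never create them (no patch merging)
        scans, bg = self._learned()
        data = scans[0].data.copy()
        data[4:6, 4:6] += 40
        data[12:14, 20:22] += 80
        data[24:26, 8:10] += 200
        scan = _scan(data)
        counts = []
        hots = []
        for z in (2.0, 4.0, 8.0, 16.0, 40.0):
            blips, _ = extract_blips(
                scan, bg, ExtractionParams(z_thresh=z,
                                           update_enabled=False,
                                           grid=StatsCellGrid(8, 8)))
            counts.append(len(blips))
            hots.append(int(find_hot(scan, bg, z).sum()))
        assert counts == sorted(counts, reverse=True)
        assert hots == sorted(hots, reverse=True)

    def test_blip_cells_subset_of_hot_mask(self):
        scans, bg = self._learned()
        data = scans[1].data.copy()
        data[4:7, 4:7] += 120
        scan = _scan(data)
        params = ExtractionParams(z_thresh=3.0, update_enabled=False,
                                  grid=StatsCellGrid(8, 8))
        blips, _ = extract_blips(scan, bg, params)
        mask = find_hot(scan, bg, params.z_thresh)
        for b in blips:
            for r, c, _ in b.cells:
                assert mask[r, c]


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_group_patches_partitions_hot_mask(seed):
    """Patches exactly partition the hot mask: disjoint and covering."""
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 12)) < 0.3
    patches = group_patches(mask)
    seen = set()
    for p in patches:
        for r, c, _ in p.cells:
            assert (r, c) not in seen
            seen.add((r, c))
    assert seen == set(zip(*np.nonzero(mask))) or (
        not mask.any() and not seen)
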