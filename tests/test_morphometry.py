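"""Morphometry tests: flattening, segmentation, pore detection accuracy,
porosity with the nuclear-exclusion rule, and deformability matching."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from fenestra import morphometry as morph
from fenestra.reconstruction import HeightMap, reconstruct_stack
from fenestra.synthetic import PhantomSpec, deformability_spec, generate_phantom


def _make_map(heights, pixel_size=25.0, load=170.0):
    heights = np.asarray(heights, dtype=float)
    return HeightMap(
        heights=heights,
        valid_mask=np.isfinite(heights),
        pixel_size=pixel_size,
        load_force=load,
    )


def synthetic_pore_map(d_true_nm=200.0, pixel_size=25.0, size=48, cell_h=300.0):
    """Single circular pore of known diameter in a flat membrane."""
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = size / 2.0 - 0.5
    r = np.hypot(xx - cx, yy - cy) * pixel_size
    h = np.where(r <= d_true_nm / 2.0, 0.0, cell_h)
    return _make_map(h, pixel_size)


@pytest.fixture(scope="module")
def analyzed_phantom(default_phantom):
    """Reconstruct, flatten and segment the shared noisy phantom once."""
    spec, truth, fv = default_phantom
    lo, hi = reconstruct_stack(fv, [170.0, 300.0])
    flo, fhi = morph.flatten(lo), morph.flatten(hi)
    thr = threshold_otsu(flo.heights[np.isfinite(flo.heights)])
    cell_mask, area = morph.segment_cell(flo, thr)
    cl = np.nanmedian(flo.heights[cell_mask])
    pk = np.nanpercentile(flo.heights, 99.5)
    nuclear = morph.detect_nuclear_region(flo, cl + 0.3 * (pk - cl))
    return spec, truth, flo, fhi, cell_mask, area, nuclear


class TestFlatten:
    def test_flat_map_unchanged(self):
        """An already-level map with an elliptical cell and a pore passes
        through flattening essentially untouched."""
        yy, xx = np.mgrid[0:48, 0:48]
        cell = ((xx - 24) / 20.0) ** 2 + ((yy - 24) / 20.0) ** 2 <= 1.0
        h = np.where(cell, 250.0, 0.0)
        h[(xx - 24) ** 2 + (yy - 24) ** 2 <= 9] = 0.0  # pore
        out = morph.flatten(_make_map(h))
        assert np.allclose(out.heights, h, atol=1.0)

    def test_per_line_tilt_removed_depths_preserved(self, analyzed_phantom):
        _, _, flo, _, cell_mask, _, _ = analyzed_phantom
        tilt = 0.08 * np.arange(flo.heights.shape[1])[None, :] * flo.pixel_size
        tilted = _make_map(flo.heights + tilt, flo.pixel_size)
        out = morph.flatten(tilted)
        diff = out.heights - flo.heights
        assert np.nanstd(diff) < 1.0

    def test_streak_rows_do_not_change_pore_count(self, analyzed_phantom):
        """Imprint-like streaks (offset scan lines) leave detection
        counts unchanged after flattening."""
        _, truth, flo, _, cell_mask, _, nuclear = analyzed_phantom
        streaked = flo.heights.copy()
        streaked[10] += 40.0
        streaked[33] -= 40.0
        out = morph.flatten(_make_map(streaked, flo.pixel_size))
        pores_ref = morph.detect_pores(flo, cell_mask, nuclear_mask=nuclear)
        pores_str = morph.detect_pores(out, cell_mask, nuclear_mask=nuclear)
        assert len(pores_str) == len(pores_ref)

    def test_fully_invalid_rejected(self):
        h = np.full((20, 20), np.nan)
        m = HeightMap(heights=h, valid_mask=np.zeros_like(h, dtype=bool),
                      pixel_size=25.0, load_force=170.0)
        with pytest.raises(ValueError):
            morph.flatten(m)

    def test_invalid_order_rejected(self, analyzed_phantom):
        _, _, flo, *_ = analyzed_phantom
        with pytest.raises(ValueError):
            morph.flatten(flo, order=3)


class TestSegmentation:
    def test_full_frame_cell_area(self):
        h = np.full((40, 40), 300.0)
        mask, area = morph.segment_cell(_make_map(h), 150.0)
        assert mask.all()
        assert area == pytest.approx(40 * 40 * 25.0**2 / 1e6)

    def test_phantom_cell_area_within_3pct(self, analyzed_phantom):
        _, truth, _, _, _, area, _ = analyzed_phantom
        assert area == pytest.approx(truth.cell_area_um2, rel=0.03)

    def test_empty_mask_rejected(self):
        h = np.zeros((20, 20))
        with pytest.raises(ValueError):
            morph.segment_cell(_make_map(h), 100.0)

    def test_flat_cell_has_no_nuclear_bulge(self):
        h = np.zeros((32, 32))
        h[4:28, 4:28] = 250.0
        mask = morph.detect_nuclear_region(_make_map(h), 400.0)
        assert not mask.any()

    def test_nuclear_bulge_overlaps_truth(self, analyzed_phantom):
        _, truth, _, _, _, _, nuclear = analyzed_phantom
        inter = (nuclear & truth.nuclear_mask).sum()
        union = (nuclear | truth.nuclear_mask).sum()
        assert inter / union >= 0.8


class TestDetectPores:
    def test_noiseless_count_matches_truth_exactly(self, noiseless_phantom):
        _, truth, fv = noiseless_phantom
        (lo,) = reconstruct_stack(fv, [170.0])
        flo = morph.flatten(lo)
        thr = threshold_otsu(flo.heights[np.isfinite(flo.heights)])
        cell_mask, _ = morph.segment_cell(flo, thr)
        pores = morph.detect_pores(flo, cell_mask)
        assert len(pores) == len(truth.pore_table)

    @pytest.mark.parametrize("pixel_size", [20.0, 25.0, 27.0])
    @pytest.mark.parametrize("d_true", [100.0, 200.0, 300.0])
    def test_single_pore_diameter_within_one_pixel(self, d_true, pixel_size):
        hmap = synthetic_pore_map(d_true, pixel_size)
        mask = np.ones(hmap.heights.shape, dtype=bool)
        pores = morph.detect_pores(hmap, mask)
        assert len(pores) == 1
        assert abs(pores[0].diameter_fast_axis_nm - d_true) <= pixel_size

    def test_empty_cell_gives_empty_list(self):
        h = np.zeros((32, 32))
        h[4:28, 4:28] = 300.0
        hmap = _make_map(h)
        mask, _ = morph.segment_cell(hmap, 150.0)
        assert morph.detect_pores(hmap, mask) == []

    def test_unknown_criterion_rejected(self):
        hmap = synthetic_pore_map()
        with pytest.raises(ValueError):
            morph.detect_pores(hmap, np.ones(hmap.heights.shape, bool), criterion="nope")

    def test_noisy_recovery_within_10pct(self, analyzed_phantom):
        spec, truth, flo, _, cell_mask, _, nuclear = analyzed_phantom
        pores = morph.detect_pores(flo, cell_mask, nuclear_mask=nuclear)
        res = morph.compute_porosity(pores, cell_mask, nuclear, flo.pixel_size)
        assert res.porosity_per_um2 == pytest.approx(truth.true_porosity, rel=0.10)


class TestPorosity:
    def test_simple_arithmetic(self):
        """10 pores on a 10 um^2 cell give exactly 1.0 fen./um^2."""
        pores = [
            morph.PoreRecord(100.0 * i, 100.0, 150.0, 200.0, 2e4, 1.0)
            for i in range(1, 11)
        ]
        mask = np.ones((80, 50), dtype=bool)  # 4000 px at 50 nm -> 10 um^2
        res = morph.compute_porosity(pores, mask, None, 50.0)
        assert res.cell_area_um2 == pytest.approx(10.0)
        assert res.porosity_per_um2 == pytest.approx(1.0)

    def test_nuclear_pores_excluded(self):
        nuclear = np.ones((40, 40), dtype=bool)
        cell = np.ones((40, 40), dtype=bool)
        pores = [morph.PoreRecord(500.0, 500.0, 150.0, 200.0, 2e4, 1.0)]
        res = morph.compute_porosity(pores, cell, nuclear, 25.0)
        assert res.porosity_per_um2 == 0.0
        assert res.n_excluded_nuclear == 1

    def test_exclusion_never_raises_porosity(self, analyzed_phantom):
        _, _, flo, _, cell_mask, _, nuclear = analyzed_phantom
        pores = morph.detect_pores(flo, cell_mask, nuclear_mask=nuclear)
        with_excl = morph.compute_porosity(pores, cell_mask, nuclear, flo.pixel_size)
        without = morph.compute_porosity(pores, cell_mask, None, flo.pixel_size)
        assert with_excl.porosity_per_um2 <= without.porosity_per_um2

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            morph.compute_porosity([], np.zeros((10, 10), bool), None, 25.0)

    def test_labyrinth_only_phantom_has_zero_porosity(self):
        spec = PhantomSpec(seed=6, n_sieve_plates=0, pores_per_plate=0,
                           labyrinth_pores=2, force_noise_sd=0.0)
        truth, fv = generate_phantom(spec)
        (lo,) = reconstruct_stack(fv, [170.0])
        flo = morph.flatten(lo)
        thr = threshold_otsu(flo.heights[np.isfinite(flo.heights)])
        cell_mask, _ = morph.segment_cell(flo, thr)
        cl = np.nanmedian(flo.heights[cell_mask])
        pk = np.nanpercentile(flo.heights, 99.5)
        nuclear = morph.detect_nuclear_region(flo, cl + 0.3 * (pk - cl))
        pores = morph.detect_pores(flo, cell_mask, nuclear_mask=nuclear)
        res = morph.compute_porosity(pores, cell_mask, nuclear, flo.pixel_size)
        assert res.porosity_per_um2 == 0.0
        assert res.n_excluded_nuclear == len(pores) > 0


class TestMatching:
    def _pores_at(self, coords):
        return [
            morph.PoreRecord(x, y, 200.0, 250.0, 3e4, 1.0) for x, y in coords
        ]

    def test_identical_lists_match_at_zero_distance(self):
        a = self._pores_at([(100, 100), (500, 500), (900, 300)])
        pairs, ul, uh = morph.match_pores(a, a, 75.0)
        assert len(pairs) == 3 and not ul and not uh
        assert all(p.centroid_distance_nm == 0 for p in pairs)
        assert all(p.fold_change == 1.0 for p in pairs)

    def test_offset_beyond_radius_matches_nothing(self):
        a = self._pores_at([(100, 100)])
        b = self._pores_at([(400, 400)])
        pairs, ul, uh = morph.match_pores(a, b, 75.0)
        assert pairs == [] and len(ul) == 1 and len(uh) == 1

    def test_count_conservation(self, analyzed_phantom):
        _, _, flo, fhi, cell_mask, _, nuclear = analyzed_phantom
        pl = morph.detect_pores(flo, cell_mask, nuclear_mask=nuclear)
        ph = morph.detect_pores(fhi, cell_mask, nuclear_mask=nuclear)
        pairs, ul, uh = morph.match_pores(pl, ph, 75.0)
        assert len(pairs) + len(ul) == len(pl)
        assert len(pairs) + len(uh) == len(ph)
        assert len(pairs) >= 0.95 * min(len(pl), len(ph))


class TestDeformability:
    def test_rigid_pores_unit_fold_change(self):
        a = [morph.PoreRecord(100, 100, 200.0, 250.0, 3e4, 1.0)]
        pairs, _, _ = morph.match_pores(a, a, 75.0)
        s = morph.deformability_summary(pairs)
        assert s.mean_fold_change == 1.0
        assert s.percent_enlargement == 0.0

    def test_swapping_maps_inverts_fold_change(self):
        lo = [morph.PoreRecord(100, 100, 200.0, 250.0, 3e4, 1.0)]
        hi = [morph.PoreRecord(100, 100, 260.0, 250.0, 3e4, 1.0)]
        fwd, _, _ = morph.match_pores(lo, hi, 75.0)
        rev, _, _ = morph.match_pores(hi, lo, 75.0)
        assert fwd[0].fold_change == pytest.approx(1 / rev[0].fold_change)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            morph.deformability_summary([])

    def test_programmed_enlargement_recovered(self):
        """A phantom programmed to 40% enlargement is recovered within
        5 percentage points from the 170/300 pN stack."""
        spec = deformability_spec(seed=21, target_enlargement_pct=40.0)
        truth, fv = generate_phantom(spec)
        lo, hi = reconstruct_stack(fv, [170.0, 300.0])
        flo, fhi = morph.flatten(lo), morph.flatten(hi)
        thr = threshold_otsu(flo.heights[np.isfinite(flo.heights)])
        cell_mask, _ = morph.segment_cell(flo, thr)
        kw = dict(d_range=(50.0, 1200.0), nuclear_mask=None)
        pl = morph.detect_pores(flo, cell_mask, **kw)
        ph = morph.detect_pores(fhi, cell_mask, **kw)
        pairs, _, _ = morph.match_pores(pl, ph, 3 * flo.pixel_size)
        s = morph.deformability_summary(pairs)
        assert s.n_pairs >= 5
        assert abs(s.percent_enlargement - 40.0) <= 5.0
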