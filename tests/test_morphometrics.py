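"""Morphometrics: sphericity oracles, overlap arithmetic, focus exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmorph import simgen
from ctmorph.morphometrics import (intensity_excluding_foci, measure_region,
                                   normalized_volume, overlap_percent)

ISO = (0.1, 0.1, 0.1)
CUBE_SPHERICITY = (np.pi / 6) ** (1 / 3)  # ~0.806


def digital_ball(radius_vox, vs=ISO):
    n = 2 * radius_vox + 7
    c = (n // 2) * vs[0]
    return simgen.render_blob((c,) * 3, (radius_vox * vs[0],) * 3, 0.0,
                              (n,) * 3, vs)


class TestMeasureRegion:
    def test_ball_volume_and_sphericity(self):
        mask = digital_ball(20)
        m = measure_region(mask, ISO)
        assert m.volume_um3 == pytest.approx(4 / 3 * np.pi * 8, rel=0.02)
        assert 0.95 <= m.sphericity <= 1.02

    def test_cube_sphericity_near_closed_form(self):
        side = 60
        cube = np.zeros((side + 10,) * 3, bool)
        cube[5:5 + side, 5:5 + side, 5:5 + side] = True
        m = measure_region(cube, ISO)
        assert m.sphericity == pytest.approx(CUBE_SPHERICITY, abs=0.02)

    def test_single_voxel_volume_exact(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        m = measure_region(mask, ISO)
        assert m.volume_um3 == pytest.approx(1e-3, rel=1e-12)
        assert m.sphericity <= 1.02

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty"):
            measure_region(np.zeros((5, 5, 5), bool), ISO)

    def test_disconnected_mask_raises(self):
        mask = np.zeros((5, 5, 9), bool)
        mask[2, 2, 1] = mask[2, 2, 7] = True
        with pytest.raises(ValueError, match="disconnected"):
            measure_region(mask, ISO)

    def test_sphericity_translation_invariant(self):
        mask = digital_ball(8)
        shifted = np.roll(mask, (2, 3, 1), axis=(0, 1, 2))
        a = measure_region(mask, ISO)
        b = measure_region(shifted, ISO)
        assert a.sphericity == pytest.approx(b.sphericity, rel=1e-6)

    def test_sphericity_stable_under_axis_rotation(self):
        # irregular blob on an isotropic grid: 90-degree rotations within 2%
        mask = simgen.render_blob((3,) * 3, (1.5, 1.0, 2.0), 0.6,
                                  (61, 61, 61), ISO, seed=3)
        base = measure_region(mask, ISO).sphericity
        for axes in ((0, 1), (1, 2), (0, 2)):
            rot = np.rot90(mask, axes=axes)
            assert measure_region(rot, ISO).sphericity == pytest.approx(
                base, rel=0.02)

    def test_ball_sphericity_approaches_one_with_radius(self):
        vals = [measure_region(digital_ball(r), ISO).sphericity
                for r in (5, 10, 20, 40)]
        for lo, hi in zip(vals, vals[1:]):
            assert hi >= lo - 0.02  # monotone within tolerance
        assert vals[-1] >= 0.97

    def test_mean_intensity_under_mask(self):
        mask = digital_ball(5)
        img = np.where(mask, 7.5, 0.0)
        m = measure_region(mask, ISO, intensity=img)
        assert m.mean_intensity == pytest.approx(7.5)


class TestVolumeArithmetic:
    def test_normalized_volume_basic(self):
        assert normalized_volume(30.0, 100.0) == pytest.approx(0.30)

    def test_combined_unpaired_homolog_volume(self):
        # unpaired homologs 12 and 18 µm³ in a 100 µm³ nucleus -> 0.30 combined
        assert normalized_volume(12.0 + 18.0, 100.0) == pytest.approx(0.30)

    def test_zero_object_volume(self):
        assert normalized_volume(0.0, 50.0) == 0.0

    def test_invalid_nuclear_volume_raises(self):
        with pytest.raises(ValueError):
            normalized_volume(1.0, 0.0)

    def test_ratio_above_one_warns_but_returns(self):
        with pytest.warns(UserWarning, match="normalized volume"):
            assert normalized_volume(120.0, 100.0) == pytest.approx(1.2)

    def test_component_volume_additivity(self):
        # disjoint components: voxel-count volumes add exactly
        shape = (20, 20, 44)
        a = simgen.render_blob((1.0, 1.0, 1.0), (0.6,) * 3, 0.0, shape, ISO)
        b = simgen.render_blob((1.0, 1.0, 3.0), (0.6,) * 3, 0.0, shape, ISO)
        union = a | b
        voxvol = np.prod(ISO)
        va = measure_region(a, ISO).volume_um3
        vb = measure_region(b, ISO).volume_um3
        assert va + vb == pytest.approx(union.sum() * voxvol, rel=1e-12)


class TestOverlap:
    def test_identical_masks_full_overlap(self):
        m = digital_ball(5)
        rec = overlap_percent(m, m, ISO)
        assert rec.overlap_of_a_pct == 100.0
        assert rec.overlap_of_b_pct == 100.0

    def test_disjoint_masks_zero_overlap(self):
        a = np.zeros((10, 10, 20), bool)
        b = np.zeros((10, 10, 20), bool)
        a[2:8, 2:8, 1:8] = True
        b[2:8, 2:8, 11:18] = True
        rec = overlap_percent(a, b, ISO)
        assert rec.overlap_of_a_pct == 0.0
        assert rec.overlap_of_b_pct == 0.0

    def test_constructed_counts(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:250] = True  # |A|=100, |B|=200, |A∩B|=50
        rec = overlap_percent(a, b, ISO)
        assert rec.overlap_of_a_pct == pytest.approx(50.0)
        assert rec.overlap_of_b_pct == pytest.approx(25.0)
        assert rec.intersection_volume_um3 == pytest.approx(50 * 1e-3)

    def test_absent_channel_flagged(self):
        a = digital_ball(4)
        rec = overlap_percent(a, np.zeros_like(a), ISO)
        assert not rec.defined
        assert np.isnan(rec.overlap_of_a_pct)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_intersection_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.6
        ab = overlap_percent(a, b, ISO)
        ba = overlap_percent(b, a, ISO)
        assert ab.intersection_volume_um3 == ba.intersection_volume_um3


class TestIntensityExcludingFoci:
    def _nucleus(self):
        shape = (40, 60, 60)
        mask = simgen.render_blob((4, 4.5, 4.5), (2.5,) * 3, 0.0, shape,
                                  (0.2, 0.15, 0.15))
        return shape, (0.2, 0.15, 0.15), mask

    def test_uniform_no_foci_exact_mean(self):
        shape, vs, mask = self._nucleus()
        img = np.where(mask, 2.0, 0.0)
        mean, foci = intensity_excluding_foci(img, mask, vs, k_foci=0)
        assert mean == pytest.approx(2.0, abs=0)
        assert foci == []

    def test_single_bright_focus_recovered_exactly(self):
        shape, vs, mask = self._nucleus()
        focus = simgen.render_blob((4, 4.5, 4.5), (0.4,) * 3, 0.0, shape, vs)
        img = np.where(mask, 1.0, 0.0)
        img[focus] = 5.0
        mean, foci = intensity_excluding_foci(img, mask, vs, k_foci=1)
        assert len(foci) == 1
        assert foci[0].volume_um3 == pytest.approx(
            focus.sum() * np.prod(vs))
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_two_foci_centroids_recovered(self):
        shape, vs, mask = self._nucleus()
        centers = [(4, 3.6, 3.6), (4, 5.4, 5.4)]
        img = np.where(mask, 1.0, 0.0)
        for c in centers:
            img[simgen.render_blob(c, (0.4,) * 3, 0.0, shape, vs)] = 4.0
        _, foci = intensity_excluding_foci(img, mask, vs, k_foci=2)
        assert len(foci) == 2
        got = sorted(f.centroid_um for f in foci)
        for g, c in zip(got, sorted(centers)):
            err_vox = np.linalg.norm([(gi - ci) / v
                                      for gi, ci, v in zip(g, c, vs)])
            assert err_vox < 2.0

    def test_fewer_foci_than_requested_is_not_an_error(self):
        shape, vs, mask = self._nucleus()
        img = np.where(mask, 1.0, 0.0)
        focus = simgen.render_blob((4, 4.5, 4.5), (0.4,) * 3, 0.0, shape, vs)
        img[focus] = 5.0
        _, foci = intensity_excluding_foci(img, mask, vs, k_foci=3)
        assert len(foci) == 1
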