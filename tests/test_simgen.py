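"""Simulator: geometry oracles, determinism, placement statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats
from skimage.measure import label as cc_label

from ctmorph import simgen
from ctmorph.simgen import (CrowdedFieldError, SimulationConfig, apply_optics,
                            generate_field, render_blob)

ISO = (0.1, 0.1, 0.1)


class TestRenderBlob:
    def test_sphere_volume_matches_closed_form(self):
        mask = render_blob((3, 3, 3), (2, 2, 2), 0.0, (61, 61, 61), ISO)
        vol = mask.sum() * 1e-3
        assert vol == pytest.approx(4 / 3 * np.pi * 8, rel=0.02)

    def test_zero_irregularity_is_exact_ellipsoid(self):
        semi = (1.2, 0.8, 1.5)
        center = (2.0, 2.0, 2.0)
        mask = render_blob(center, semi, 0.0, (41, 41, 41), ISO)
        zz, yy, xx = np.meshgrid(*[np.arange(41) * 0.1] * 3, indexing="ij")
        rho2 = sum(((g - c) / a) ** 2
                   for g, c, a in zip((zz, yy, xx), center, semi))
        assert np.array_equal(mask, rho2 <= 1.0)

    def test_irregular_blob_connected_and_volume_preserved(self):
        ref = render_blob((4, 4, 4), (2, 2, 2), 0.0, (81, 81, 81), ISO)
        for seed in range(5):
            mask = render_blob((4, 4, 4), (2, 2, 2), 1.0, (81, 81, 81), ISO,
                               seed=seed)
            assert cc_label(mask, connectivity=3).max() == 1
            assert mask.sum() == pytest.approx(ref.sum(), rel=0.10)

    def test_blob_exceeding_grid_raises(self):
        with pytest.raises(ValueError, match="exceeds grid"):
            render_blob((1, 1, 1), (2, 2, 2), 0.0, (30, 30, 30), ISO)

    def test_invalid_semi_axes_raise(self):
        with pytest.raises(ValueError):
            render_blob((1, 1, 1), (0, 1, 1), 0.0, (30, 30, 30), ISO)


class TestApplyOptics:
    def test_noise_off_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 2, (10, 10, 10))
        out = apply_optics(img, (0, 0, 0), 0.0, 0.0, voxel_size=ISO)
        np.testing.assert_allclose(out, img, rtol=1e-6)

    def test_seeded_determinism(self):
        img = np.full((20, 20, 20), 1.5)
        a = apply_optics(img, (0.2, 0.1, 0.1), 100, 2.0, seed=5, voxel_size=ISO)
        b = apply_optics(img, (0.2, 0.1, 0.1), 100, 2.0, seed=5, voxel_size=ISO)
        np.testing.assert_array_equal(a, b)

    def test_poisson_preserves_mean(self):
        img = np.full((50, 50, 50), 1.3)  # 1.25e5 voxels
        out = apply_optics(img, (0, 0, 0), 200, 0.0, seed=1, voxel_size=ISO)
        assert out.mean() == pytest.approx(1.3, rel=0.01)

    def test_blur_uses_physical_units(self):
        # a point source blurred with anisotropic voxel sizes must spread
        # farther (in voxels) along the finer-sampled axis
        img = np.zeros((41, 41, 41), np.float32)
        img[20, 20, 20] = 1.0
        out = apply_optics(img, (0.4, 0.4, 0.4), 0, 0,
                           voxel_size=(0.4, 0.1, 0.1))
        z_profile = out[:, 20, 20]
        x_profile = out[20, 20, :]
        z_spread = (z_profile > z_profile.max() / 2).sum()
        x_spread = (x_profile > x_profile.max() / 2).sum()
        assert x_spread > 2 * z_spread


class TestGenerateField:
    def test_single_nucleus_territory_fraction(self):
        cfg = SimulationConfig(
            field_shape=(60, 60, 60), voxel_size=ISO, n_nuclei=1,
            nucleus_radius_um=2.0, nucleus_radius_jitter=0.0,
            channel_names=("dna", "chr2"), territory_volume_fraction=0.3,
            territory_irregularity=0.0, pairing_fraction=1.0,
            paired_mode_merged_prob=1.0, psf_sigma_um=(0, 0, 0),
            photon_scale=0.0, read_noise_sd=0.0, seed=4)
        _, truth_labels, truth = generate_field(cfg)
        assert len(truth.nuclei) == 1
        assert len(truth.signals) == 1
        ratio = (truth.signals.volume_um3.iloc[0]
                 / truth.nuclei.volume_um3.iloc[0])
        assert 0.28 <= ratio <= 0.32
        # truth labels agree with the truth table voxel counts
        voxvol = np.prod(ISO)
        assert (truth_labels["chr2"].labels > 0).sum() * voxvol == \
            pytest.approx(truth.signals.volume_um3.iloc[0])

    def test_bit_identical_output_for_same_seed(self):
        cfg = SimulationConfig(field_shape=(16, 120, 120),
                               voxel_size=(0.3, 0.15, 0.15), n_nuclei=4,
                               nucleus_radius_um=1.4, seed=9,
                               territory_volume_fraction=0.03,
                               read_noise_sd=2.0)
        f1, tl1, t1 = generate_field(cfg)
        f2, tl2, t2 = generate_field(cfg)
        np.testing.assert_array_equal(f1.data, f2.data)
        np.testing.assert_array_equal(tl1["dna"].labels, tl2["dna"].labels)
        pd.testing.assert_frame_equal(t1.nuclei, t2.nuclei)
        pd.testing.assert_frame_equal(t1.pairing, t2.pairing)

    def test_degenerate_pairing_fraction_all_paired(self):
        cfg = SimulationConfig(
            field_shape=(18, 520, 520), voxel_size=(0.3, 0.15, 0.15),
            n_nuclei=100, nucleus_radius_um=1.4,
            territory_volume_fraction=0.03, pairing_fraction=1.0,
            psf_sigma_um=(0, 0, 0), photon_scale=0.0, seed=2)
        _, _, truth = generate_field(cfg)
        assert len(truth.pairing) == 100
        assert (truth.pairing.status == "paired").all()

    def test_signals_lie_inside_their_nucleus(self, small_noisy_field):
        _, _, truth_labels, truth = small_noisy_field
        nuc = truth_labels["dna"].labels
        sig = truth_labels["chr2"].labels
        owners = nuc[sig > 0]
        assert (owners > 0).all()

    def test_truth_states_respect_distance_rule(self, small_noisy_field):
        cfg, _, _, truth = small_noisy_field
        thr = cfg.pairing_distance_um
        paired = truth.pairing[truth.pairing.status == "paired"]
        unpaired = truth.pairing[truth.pairing.status == "unpaired"]
        assert (paired.distance_um <= thr + 1e-9).all()
        assert (unpaired.distance_um > 1.5 * thr - 1e-9).all()

    def test_crowded_field_raises(self):
        cfg = SimulationConfig(field_shape=(20, 80, 80),
                               voxel_size=(0.3, 0.15, 0.15), n_nuclei=40,
                               nucleus_radius_um=1.5,
                               max_placement_attempts=50, seed=0)
        with pytest.raises(CrowdedFieldError):
            generate_field(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(territory_volume_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(pairing_fraction=-0.1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(voxel_size=(0, 0.1, 0.1)).validate()


class TestTruthConsistency:
    def test_nucleus_voxel_volume_matches_analytic(self):
        # >= 20 voxels per radius: radius 2 µm at 0.1 µm voxels
        cfg = SimulationConfig(
            field_shape=(70, 70, 70), voxel_size=ISO, n_nuclei=1,
            nucleus_radius_um=2.0, nucleus_radius_jitter=0.1,
            channel_names=("dna", "chr2"), territory_volume_fraction=0.1,
            psf_sigma_um=(0, 0, 0), photon_scale=0.0, seed=3)
        _, _, truth = generate_field(cfg)
        row = truth.nuclei.iloc[0]
        assert row.volume_um3 == pytest.approx(row.volume_analytic_um3,
                                               rel=0.05)

    def test_pairing_frequency_within_binomial_interval(self):
        # 1000 nuclei across noiseless fields; placement statistics only
        statuses = []
        for seed in range(4):
            cfg = SimulationConfig(
                field_shape=(18, 560, 560), voxel_size=(0.3, 0.15, 0.15),
                n_nuclei=250, nucleus_radius_um=1.4,
                territory_volume_fraction=0.03, pairing_fraction=0.7,
                psf_sigma_um=(0, 0, 0), photon_scale=0.0, seed=seed)
            _, _, truth = generate_field(cfg)
            statuses.extend(truth.pairing.status.tolist())
        n = len(statuses)
        assert n == 1000
        k = sum(s == "paired" for s in statuses)
        lo, hi = sp_stats.binom.interval(0.99, n, 0.7)
        assert lo <= k <= hi
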