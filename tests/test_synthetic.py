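"""Synthetic-experiment generator: determinism, couplings, and contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nitroscan import io as nio
from nitroscan import spectral, structural
from nitroscan.doseresp import fit_curve
from nitroscan.synthetic import (
    ExperimentConfig, TraitCurve, generate_experiment, generate_traits,
    write_experiment,
)


class TestConfig:
    def test_defaults_total_84_plants(self):
        assert ExperimentConfig().n_plants == 84

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ExperimentConfig(doses_ppm=(0, 40), replicates_per_dose=(3, 3))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            ExperimentConfig(doses_ppm=(20, 40), replicates_per_dose=(1, 3))

    def test_non_concave_biomass_curve_rejected(self):
        curves = {
            "TRN": TraitCurve.from_peak(-0.12, 150, 60),
            "NO3": TraitCurve.from_peak(-0.02, 150, 10),
            "DW": TraitCurve(a=0.1, b=1.0, c=5.0),  # convex: no interior peak
        }
        with pytest.raises(ValueError, match="concave"):
            ExperimentConfig(trait_curves=curves)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, small_config):
        a = generate_experiment(small_config)
        b = generate_experiment(small_config)
        for pa, pb in zip(a, b):
            assert pa.traits == pb.traits
            np.testing.assert_array_equal(pa.image, pb.image)
            np.testing.assert_array_equal(pa.true_leaf_mask, pb.true_leaf_mask)
            np.testing.assert_array_equal(pa.cloud.xyz, pb.cloud.xyz)
            np.testing.assert_array_equal(pa.cloud.colors, pb.cloud.colors)

    def test_traits_fast_path_matches_full_generator(self, small_config, small_plants):
        df = generate_traits(small_config)
        full = pd.DataFrame(
            [{"plant_id": p.plant_id, "dose_ppm": p.dose_ppm,
              "TRN": p.traits.TRN, "NO3": p.traits.NO3, "DW": p.traits.DW}
             for p in small_plants]
        )
        pd.testing.assert_frame_equal(df, full)


class TestTraitStructure:
    def test_zero_noise_traits_equal_the_curve(self):
        cfg = ExperimentConfig(
            doses_ppm=(20, 160, 800), replicates_per_dose=(2, 2, 2),
            noise_sd={"TRN": 0.0, "NO3": 0.0, "DW": 0.0},
        )
        df = generate_traits(cfg)
        for name in ("TRN", "NO3", "DW"):
            expected = cfg.trait_curves[name](df["dose_ppm"].to_numpy())
            np.testing.assert_allclose(df[name].to_numpy(), expected, rtol=0, atol=0)

    def test_group_means_converge_to_curves(self):
        """Group means are unbiased estimates of the configured curves: most
        of the nine simultaneous checks fall within 2 SE and none strays far
        (multiplicity makes a strict all-within-2-SE check over-sensitive)."""
        n = 200
        cfg = ExperimentConfig(doses_ppm=(20, 160, 800), replicates_per_dose=(n, n, n),
                               seed=11)
        df = generate_traits(cfg)
        z_scores = []
        for name in ("TRN", "NO3", "DW"):
            sd = cfg.noise_sd[name]
            for dose, group in df.groupby("dose_ppm")[name]:
                expected = float(cfg.trait_curves[name](dose))
                # truncation at zero never triggers at these means
                z_scores.append(abs(group.mean() - expected) / (sd / np.sqrt(n)))
        z_scores = np.array(z_scores)
        assert np.count_nonzero(z_scores <= 2.0) >= 7
        assert z_scores.max() <= 4.0

    def test_greenness_increases_with_nitrogen(self):
        cfg = ExperimentConfig(
            doses_ppm=(20, 150), replicates_per_dose=(6, 6),
            noise_sd={"TRN": 0.0, "NO3": 0.0, "DW": 0.0},
            leaf_color_jitter=0.0,
        )
        plants = generate_experiment(cfg)
        greens = {}
        for p in plants:
            refl = spectral.calibrate(p.image, p.dark_frame, p.white_frame)
            greens.setdefault(p.dose_ppm, []).append(
                refl.band(1)[p.true_leaf_mask].mean())
        assert np.mean(greens[150.0]) > np.mean(greens[20.0])

    def test_canopy_grows_with_biomass(self):
        cfg = ExperimentConfig(
            doses_ppm=(20, 150), replicates_per_dose=(4, 4),
            noise_sd={"TRN": 0.0, "NO3": 0.0, "DW": 0.0}, geometry_jitter=0.0,
        )
        plants = generate_experiment(cfg)
        by_dose = {20.0: [], 150.0: []}
        for p in plants:
            canopy = p.cloud.select(p.true_plant_point_ids)
            f = structural.extract_features(canopy)
            by_dose[p.dose_ppm].append((f.ht, f.cv))
        low = np.mean(by_dose[20.0], axis=0)
        high = np.mean(by_dose[150.0], axis=0)
        assert high[0] > low[0] and high[1] > low[1]


class TestGeneratedArtifacts:
    def test_leaf_mask_nonempty_and_in_bounds(self, small_plants, small_config):
        for p in small_plants:
            assert p.true_leaf_mask.shape == (small_config.image_size,) * 2
            assert p.true_leaf_mask.any()

    def test_plant_points_strict_subset(self, small_plants):
        for p in small_plants:
            assert 0 < len(p.true_plant_point_ids) < len(p.cloud)

    def test_mask_indices_equal_direct_leaf_pixel_computation(self, small_plants):
        p = small_plants[0]
        refl = spectral.calibrate(p.image, p.dark_frame, p.white_frame)
        fv = spectral.compute_indices(refl, p.true_leaf_mask)
        leaf = refl.data[p.true_leaf_mask]
        exg_direct = np.mean(2 * leaf[:, 1] - leaf[:, 0] - leaf[:, 2])
        assert fv["ExG"] == pytest.approx(exg_direct, abs=1e-12)

    def test_injected_noise_is_exactly_what_denoising_removes(self, small_plants):
        for p in small_plants:
            keep = structural.density_keep_mask(p.cloud, grid_edge=0.01, min_count=4)
            removed = np.flatnonzero(~keep)
            np.testing.assert_array_equal(np.sort(removed),
                                          np.sort(p.true_noise_point_ids))


class TestClosedLoop:
    def test_group_mean_refit_recovers_configured_peak(self):
        # curve peaking at 150 ppm, 11 replicates per dose, seed 1
        cfg = ExperimentConfig(seed=1, replicates_per_dose=(11,) * 8)
        assert cfg.trait_curves["DW"].peak_dose_ppm == pytest.approx(150.0)
        df = generate_traits(cfg)
        means = df.groupby("dose_ppm")["DW"].mean().reset_index()
        fit = fit_curve(means["dose_ppm"], means["DW"])
        assert fit.peak_type == "interior-max"
        assert abs(fit.peak_dose_ppm - 150.0) <= 10.0


class TestRoundTrip:
    def test_write_experiment_round_trips(self, small_plants, tmp_path):
        manifest = write_experiment(small_plants[:2], tmp_path)
        assert manifest.exists()
        p = small_plants[0]
        img = nio.read_raster(tmp_path / "images" / f"{p.plant_id}.tif")
        np.testing.assert_allclose(img, p.image, rtol=1e-6)
        mask = nio.read_mask(tmp_path / "images" / f"{p.plant_id}_mask.png")
        np.testing.assert_array_equal(mask, p.true_leaf_mask)
        cloud = nio.load_point_cloud(tmp_path / "clouds" / f"{p.plant_id}.ply")
        assert len(cloud) == len(p.cloud)
        np.testing.assert_allclose(cloud.xyz, p.cloud.xyz, atol=1e-5)
        # PLY colors quantized to uint8
        np.testing.assert_allclose(cloud.colors, p.cloud.colors, atol=1.0)

    def test_xyzrgb_text_round_trips(self, small_plants, tmp_path):
        p = small_plants[0]
        path = tmp_path / "cloud.xyz"
        nio.save_point_cloud(p.cloud, path)
        back = nio.load_point_cloud(path)
        np.testing.assert_allclose(back.xyz, p.cloud.xyz, atol=1e-5)
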