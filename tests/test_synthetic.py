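import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from limbicvbm import (ClinicalScoreSpec, SyntheticConfig,
                       extract_roi_mean, generate_clinical_scores,
                       generate_cohort, simulate_seed_network)
from conftest import small_config, small_regions


def _region_mean(cohort, name):
    stack = cohort.stack()
    return extract_roi_mean(stack, cohort.region_mask(name))


class TestDeterministicLimits:
    def test_no_noise_no_effects_gives_smoothed_baseline(self):
        cfg = small_config(noise_sd=0.0, atrophy_fraction=0.0,
                           age_slope_control=0.0, age_slope_pd=0.0,
                           covariance_amplitude=0.0)
        cohort = generate_cohort(cfg)
        # constant baseline is invariant under normalised smoothing
        np.testing.assert_allclose(cohort.volumes, cfg.baseline, atol=1e-12)

    def test_same_seed_is_bit_identical(self):
        a = generate_cohort(small_config(seed=11))
        b = generate_cohort(small_config(seed=11))
        np.testing.assert_array_equal(a.volumes, b.volumes)
        assert a.subjects.equals(b.subjects)
        assert a.visits.equals(b.visits)

    def test_smoothing_conserves_image_sum(self):
        # noiseless patient volume: total GM equals baseline*V minus the
        # planted reduction, exactly (wrap smoothing conserves the sum)
        cfg = small_config(noise_sd=0.0, age_slope_control=0.0,
                           age_slope_pd=0.0, covariance_amplitude=0.0,
                           n_control=2, n_pd=2)
        cohort = generate_cohort(cfg)
        region = cohort.truth["region_masks"]["amygdala_R"]
        expected = cfg.baseline * np.prod(cfg.shape) - \
            cfg.atrophy_fraction * cfg.baseline * region.sum()
        np.testing.assert_allclose(cohort.volumes[-1].sum(), expected,
                                   rtol=1e-9)


class TestPlantedEffectsRecoverable:
    def test_atrophy_group_difference(self):
        cfg = small_config(n_control=60, n_pd=60, seed=5,
                           covariance_amplitude=0.0)
        cohort = generate_cohort(cfg)
        means = _region_mean(cohort, "amygdala_R")
        g = cohort.subjects["group"].to_numpy()
        diff = means[g == "control"].mean() - means[g == "pd"].mean()
        # analytic expectation from the truth record: the smoothed
        # indicator attenuates the region-mean effect
        region = cohort.truth["region_masks"]["amygdala_R"]
        atten = gaussian_filter(region.astype(float), cfg.sigma_voxels,
                                mode="wrap")[region].mean()
        expected = cohort.truth["atrophy_reduction"] * atten
        sem = means[g == "control"].std(ddof=1) / np.sqrt((g == "control").sum())
        assert diff == pytest.approx(expected, abs=2 * sem * np.sqrt(2))

    def test_age_slopes_recovered_by_ols(self):
        cfg = small_config(n_control=120, n_pd=120, seed=9,
                           atrophy_fraction=0.0, covariance_amplitude=0.0)
        cohort = generate_cohort(cfg)
        means = _region_mean(cohort, "hippocampus_R")
        region = cohort.truth["region_masks"]["hippocampus_R"]
        atten = gaussian_filter(region.astype(float), cfg.sigma_voxels,
                                mode="wrap")[region].mean()
        g = cohort.subjects["group"].to_numpy()
        ages = cohort.subjects["age"].to_numpy()
        for label, truth in (("control", cfg.age_slope_control),
                             ("pd", cfg.age_slope_pd)):
            sel = g == label
            x = ages[sel] - ages[sel].mean()
            slope = (x @ (means[sel] - means[sel].mean())) / (x @ x)
            resid_sd = np.std(means[sel] - slope * x, ddof=2)
            sem = resid_sd / np.sqrt((x @ x))
            assert slope == pytest.approx(truth * atten, abs=2 * sem)


class TestCovarianceStructure:
    def test_loading_matches_large_sample_oracle(self):
        """Generator seed-network correlation at loading 0.6, n = 200,
        versus a standalone large-sample re-simulation of the same
        voxel-level model (default 32^3 geometry)."""
        cfg = SyntheticConfig(n_control=200, n_pd=2, seed=21,
                              loading_control=0.6, atrophy_fraction=0.0,
                              age_slope_control=0.0, age_slope_pd=0.0)
        cohort = generate_cohort(cfg)
        g = (cohort.subjects["group"] == "control").to_numpy()
        seed_m = _region_mean(cohort, "amygdala_R_seed")[g]
        net_m = _region_mean(cohort, "thalamus")[g]
        r_vol = np.corrcoef(seed_m, net_m)[0, 1]

        # independent Monte-Carlo oracle: re-simulate the stated per-voxel
        # model subject by subject and take region means
        rng = np.random.default_rng(123)
        seed_mask = cohort.truth["region_masks"]["amygdala_R_seed"]
        net_mask = cohort.truth["region_masks"]["thalamus"]
        lam, amp = 0.6, cfg.covariance_amplitude
        n_mc = 3000
        s_mc = np.empty(n_mc)
        n_mc_vals = np.empty(n_mc)
        for i in range(n_mc):
            z, w = rng.standard_normal(2)
            vol = np.full(cfg.shape, cfg.baseline)
            vol[seed_mask] += amp * z
            vol[net_mask] += amp * (lam * z + np.sqrt(1 - lam ** 2) * w)
            vol += rng.normal(0.0, cfg.noise_sd, cfg.shape)
            vol = gaussian_filter(vol, cfg.sigma_voxels, mode="wrap")
            s_mc[i] = vol[seed_mask].mean()
            n_mc_vals[i] = vol[net_mask].mean()
        r_oracle = np.corrcoef(s_mc, n_mc_vals)[0, 1]
        assert r_vol == pytest.approx(r_oracle, abs=0.1)

    def test_scalar_marginal_correlation_equals_loading(self):
        rng = np.random.default_rng(5)
        s, n, g = simulate_seed_network(50_000, 50_000, 0.6, 0.0, 1.0,
                                        0.0, rng)
        r0 = np.corrcoef(s[g == 0], n[g == 0])[0, 1]
        r1 = np.corrcoef(s[g == 1], n[g == 1])[0, 1]
        assert r0 == pytest.approx(0.6, abs=0.01)
        assert r1 == pytest.approx(0.0, abs=0.01)


class TestClinicalScores:
    def test_zero_correlation_calibration(self):
        spec = ClinicalScoreSpec("s", corr_with_seed=0.0)
        hits = 0
        for i in range(100):
            rng = np.random.default_rng(3000 + i)
            seed_vals = rng.standard_normal(300)
            score = generate_clinical_scores(seed_vals, spec, None, rng)
            if abs(np.corrcoef(seed_vals, score)[0, 1]) < 0.15:
                hits += 1
        assert hits >= 95

    def test_noiseless_limit_is_perfectly_correlated(self, rng):
        spec = ClinicalScoreSpec("s", corr_with_seed=0.5)
        seed_vals = rng.standard_normal(50)
        score = generate_clinical_scores(seed_vals, spec, None, rng,
                                         noise_sd=0.0)
        assert abs(np.corrcoef(seed_vals, score)[0, 1]) == pytest.approx(
            1.0, abs=1e-12)

    def test_requested_correlation_recovered(self, rng):
        spec = ClinicalScoreSpec("s", corr_with_seed=-0.3)
        seed_vals = rng.standard_normal(300)
        score = generate_clinical_scores(seed_vals, spec, None, rng)
        assert np.corrcoef(seed_vals, score)[0, 1] == pytest.approx(-0.3,
                                                                    abs=0.1)

    def test_unit_correlation_is_rejected(self):
        with pytest.raises(ValueError):
            ClinicalScoreSpec("s", corr_with_seed=1.0)


class TestConfigContracts:
    def test_invalid_configs_error(self):
        with pytest.raises(ValueError):
            small_config(n_control=1)
        with pytest.raises(ValueError):
            small_config(noise_sd=-0.1)
        with pytest.raises(ValueError):
            small_config(loading_pd=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(shape=(8, 8, 8))  # default regions off-grid

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=42, noise_sd=0.2)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_truth_record_contents(self):
        cohort = generate_cohort(small_config())
        truth = cohort.truth
        assert set(truth["region_masks"]) == {r.name for r in
                                              small_regions()}
        assert truth["age_slopes"]["pd"] == pytest.approx(-0.004434)
        assert len(truth["latent"]) == cohort.stack().n_subjects

    def test_save_writes_loadable_tree(self, tmp_path):
        from limbicvbm import BrainMask, load_cohort
        import pandas as pd
        cohort = generate_cohort(small_config(n_control=3, n_pd=3),
                                 out_dir=tmp_path)
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        mask = BrainMask.load(tmp_path / "mask.nii")
        stack = load_cohort(manifest, mask)
        np.testing.assert_allclose(stack.values, cohort.stack().values,
                                   atol=1e-12)
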