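"""Tests for the toy and simulated-MEG generators."""

import numpy as np
import pytest
from scipy import stats

from decodemap import (
    MegSimConfig,
    ToyConfig,
    compute_cerf,
    cosine_similarity,
    dipole_topography,
    erf_waveform,
    evaluate_lambda,
    hemispherical_layout,
    make_toy,
    oob_partitions,
    simulate_meg,
    toy_bayes_accuracy,
    toy_population_direction,
)

TOY_COV = np.array([[1.02, -0.3], [-0.3, 0.15]])


class TestToy:
    def test_seed_reproducibility(self):
        d1, _ = make_toy(ToyConfig(n_per_class=50, seed=4))
        d2, _ = make_toy(ToyConfig(n_per_class=50, seed=4))
        np.testing.assert_array_equal(d1.trials, d2.trials)

    def test_empirical_noise_covariance(self):
        data, _ = make_toy(ToyConfig(n_per_class=100_000, seed=2))
        noise = data.trials - data.labels[:, None] * np.array([1.5, 0.0])
        emp = np.cov(noise.T)
        assert np.max(np.abs(emp - TOY_COV)) < 0.02

    def test_population_direction_and_bayes(self):
        np.testing.assert_allclose(
            toy_population_direction(), [0.4472135955, 0.894427191],
            atol=1e-9,
        )
        assert toy_bayes_accuracy() == pytest.approx(0.9897, abs=1e-4)

    def test_true_map_is_first_axis(self):
        _, true_map = make_toy(ToyConfig(n_per_class=10, seed=0))
        np.testing.assert_array_equal(true_map.weights, [1.0, 0.0])

    def test_nonpd_covariance_rejected(self):
        with pytest.raises(ValueError):
            ToyConfig(noise_covariance=[[1.0, 2.0], [2.0, 1.0]])


class TestDipoleTopography:
    def setup_method(self):
        self.sensors = hemispherical_layout(64, radius_cm=12.0)
        self.pos = np.array([-4.7, -3.7, 5.3])

    def test_radial_dipole_is_silent(self):
        topo = dipole_topography(self.pos, self.pos, self.sensors)
        assert np.max(np.abs(topo)) < 1e-12

    def test_linearity_in_moment(self):
        t1 = dipole_topography(self.pos, [1, 1, 0], self.sensors, moment=1.0)
        t2 = dipole_topography(self.pos, [1, 1, 0], self.sensors, moment=2.0)
        np.testing.assert_allclose(t2, 2.0 * t1, rtol=1e-12)

    def test_tangential_dipole_two_lobes(self):
        topo = dipole_topography(self.pos, [1, 1, 0], self.sensors)
        assert topo.max() > 0 and topo.min() < 0
        # signed extrema sit on opposite sides of the dipole: the in/out
        # field lobes straddle the dipole location
        peak = self.sensors[np.argmax(topo)]
        trough = self.sensors[np.argmin(topo)]
        assert np.linalg.norm(peak - trough) > 1.0

    def test_sensor_inside_rejected(self):
        inner = np.array([[0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            dipole_topography(self.pos, [1, 0, 0], inner)


class TestErfWaveform:
    def setup_method(self):
        self.cfg = MegSimConfig(seed=0)
        self.t = self.cfg.times_ms()

    def test_peak_latencies_without_jitter(self):
        w = erf_waveform(self.cfg)
        assert abs(self.t[np.argmax(w)] - 150.0) <= 1000.0 / self.cfg.srate_hz
        assert abs(self.t[np.argmin(w)] - 250.0) <= 1000.0 / self.cfg.srate_hz

    def test_half_cycle_supports(self):
        w = erf_waveform(self.cfg)
        # 3 Hz half-cycle spans 166.7 ms around 150; 5 Hz spans 100 around 250
        outside = (self.t < 150.0 - 166.67 / 2 - 1e-9) | (
            (self.t > 150.0 + 166.67 / 2) & (self.t < 250.0 - 50.0)
        ) | (self.t > 250.0 + 50.0)
        assert np.allclose(w[outside], 0.0)

    def test_amplitudes_follow_spectral_law(self):
        w = erf_waveform(self.cfg)
        assert w.max() == pytest.approx(1.0 / 3.0, rel=1e-3)
        assert w.min() == pytest.approx(-1.0 / 5.0, rel=1e-3)


class TestSimulateMeg:
    def test_shapes_and_labels(self, small_meg):
        cfg = small_meg.config
        assert small_meg.dataset.trials.shape == (
            2 * cfg.epochs_per_class, cfg.n_channels * cfg.n_times
        )
        assert small_meg.dataset.labels.sum() == 0

    def test_default_config_feature_count(self):
        cfg = MegSimConfig()
        assert cfg.n_channels * cfg.n_times == 10200
        assert 2 * cfg.epochs_per_class == 500

    def test_bit_reproducible(self):
        cfg = MegSimConfig(epochs_per_class=5, n_channels=8, n_times=100, seed=9)
        a = simulate_meg(cfg)
        b = simulate_meg(cfg)
        np.testing.assert_array_equal(a.dataset.trials, b.dataset.trials)

    def test_true_map_is_topography_outer_waveform(self, small_meg):
        outer = np.outer(small_meg.leadfield_topography,
                         small_meg.erf_waveform).ravel()
        outer /= np.linalg.norm(outer)
        np.testing.assert_allclose(small_meg.true_map.weights, outer,
                                   atol=1e-12)

    def test_negative_class_has_no_locked_effect(self, small_meg):
        neg = small_meg.dataset.trials[small_meg.dataset.labels == -1]
        se = neg.std(axis=0, ddof=1) / np.sqrt(neg.shape[0])
        frac_large = np.mean(np.abs(neg.mean(axis=0)) > 3.0 * se)
        assert frac_large < 0.02  # ~0.3% expected by chance

    def test_cerf_truth_alignment_improves_as_noise_vanishes(self):
        cosines = []
        for scale in (2.0, 1.0, 0.5, 0.0):
            sim = simulate_meg(
                MegSimConfig(epochs_per_class=30, n_channels=16, n_times=100,
                             white_noise_scale=scale,
                             background_scale=scale, seed=21)
            )
            cosines.append(
                cosine_similarity(compute_cerf(sim.dataset).map, sim.true_map)
            )
        assert cosines == sorted(cosines)
        assert cosines[-1] > 0.95

    def test_decoding_beats_chance_at_default_noise(self, small_meg):
        data = small_meg.dataset
        plan = oob_partitions(data.n, 10, seed=5)
        row = evaluate_lambda(data, 10.0, plan, compute_cerf(data))
        n_events = sum(
            len(oob) for _, oob in plan.partitions
        )
        # one-sided binomial: observed OOB accuracy vs chance 0.5
        successes = int(round((1.0 - row.epe) * n_events))
        pval = stats.binomtest(successes, n_events, 0.5,
                               alternative="greater").pvalue
        assert pval < 0.01

    def test_eta_tilde_overestimates_eta_with_positive_rank_correlation(
        self, small_meg
    ):
        """The cERF-based interpretability tracks, and overestimates, the
        exact one across the grid (reduced-scale replication)."""
        from decodemap import select_model

        data = small_meg.dataset
        table = select_model(
            data, [1.0, 5.0, 10.0, 25.0, 50.0], m=15, seed=13,
            true_map=small_meg.true_map, fit_full=False,
        )
        df = table.to_dataframe().dropna(subset=["eta_tilde"])
        assert (df.eta_tilde >= df.eta_true).mean() > 0.5
        rho = stats.spearmanr(df.eta_tilde, df.eta_true).statistic
        assert rho > 0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            MegSimConfig(background_freq_range_hz=(1.0, 200.0))
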