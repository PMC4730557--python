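"""Generators: planted amplitudes, determinism, and error behaviour."""

import numpy as np
import pytest

from rsfa.bands import band_sd
from rsfa.cardiac import IbiSeries
from rsfa.exceptions import InvalidConfigError
from rsfa.fluctuation import compute_rsfa
from rsfa.simulate import (
    GeneratorConfig,
    default_region_labels,
    generate_cohort,
    make_event_table,
    masks_from_labels,
    simulate_physio,
    simulate_rest_bold,
    simulate_sensors,
    simulate_task_bold,
)
from rsfa.simulate.physio import simulate_beat_times
from rsfa.task import fit_task_glm, task_regressor


@pytest.fixture(scope="module")
def quiet_config():
    """All structured noise off: what remains is the planted signal."""
    return GeneratorConfig(
        n_participants=4,
        seed=5,
        grid_shape=(16, 8, 2),
        n_volumes=250,
        drift_linear_sd=0.0,
        drift_quad_sd=0.0,
        motion_coupling_sd=0.0,
        white_noise_sd=0.0,
        task_noise_sd=0.0,
    )


class TestRestBold:
    def test_null_voxel_constant_when_everything_zeroed(self, quiet_config):
        cfg = GeneratorConfig(**{**quiet_config.__dict__, "rest_fluct_sd": 0.0})
        cohort = generate_cohort(cfg)
        run = simulate_rest_bold(cohort.iloc[0], cfg)
        masks = masks_from_labels(default_region_labels(cfg.grid_shape))
        null_series = run.data[masks["null"]]
        assert np.ptp(null_series, axis=-1).max() < 1e-12

    def test_doubling_v_doubles_vascular_fluctuation_sd(self, quiet_config):
        cohort = generate_cohort(quiet_config)
        p = cohort.iloc[0].copy()
        masks = masks_from_labels(default_region_labels(quiet_config.grid_shape))
        sd1 = compute_rsfa(simulate_rest_bold(p, quiet_config)).values[masks["vascular"]]
        p["V"] = 2 * p["V"]
        sd2 = compute_rsfa(simulate_rest_bold(p, quiet_config)).values[masks["vascular"]]
        np.testing.assert_allclose(sd2, 2 * sd1, rtol=1e-6)

    def test_planted_fluctuation_sd_recovered_within_5pct(self, small_config, small_cohort,
                                                          region_masks):
        p = small_cohort.iloc[1]
        rsfa = compute_rsfa(simulate_rest_bold(p, small_config))
        target = small_config.rest_fluct_sd * p["V"]
        vals = rsfa.values[region_masks["vascular"]]
        assert abs(vals.mean() / target - 1) < 0.05

    def test_region_labels_partition_grid(self):
        labels = default_region_labels((16, 16, 8))
        masks = masks_from_labels(labels)
        total = (
            masks["gm_mask"].sum() + masks["wm_mask"].sum() + masks["csf_mask"].sum()
        )
        assert total == labels.size

    def test_label_shape_mismatch_rejected(self, quiet_config):
        cohort = generate_cohort(quiet_config)
        with pytest.raises(Exception):
            simulate_rest_bold(cohort.iloc[0], quiet_config, labels=np.zeros((2, 2, 2), int))


class TestTaskBold:
    def test_noiseless_beta_equals_planted_amplitude(self, quiet_config):
        """Closed-form OLS on the known design recovers N*V to 1e-6."""
        cohort = generate_cohort(quiet_config)
        p = cohort.iloc[2]
        events = make_event_table(quiet_config)
        run = simulate_task_bold(p, events, quiet_config)
        masks = masks_from_labels(default_region_labels(quiet_config.grid_shape))
        # independent oracle: project the neural-region mean series on the
        # HRF-convolved design by explicit least squares
        series = run.data[masks["neural"]].mean(axis=0)
        reg = task_regressor(events, quiet_config.n_volumes, quiet_config.tr)
        x = np.column_stack([np.ones_like(reg), reg])
        beta = np.linalg.lstsq(x, series, rcond=None)[0][1]
        expected = quiet_config.task_amplitude * p["N"] * p["V"]
        assert beta == pytest.approx(expected, abs=1e-6)
        # and the packaged GLM agrees
        bm = fit_task_glm(run, events)
        np.testing.assert_allclose(bm.values[masks["neural"]], expected, atol=1e-6)

    def test_same_seed_identical_volumes(self, quiet_config):
        cohort = generate_cohort(quiet_config)
        events = make_event_table(quiet_config)
        r1 = simulate_task_bold(cohort.iloc[0], events, quiet_config)
        r2 = simulate_task_bold(cohort.iloc[0], events, quiet_config)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_event_beyond_run_end_rejected(self, quiet_config):
        cohort = generate_cohort(quiet_config)
        events = make_event_table(quiet_config)
        events.loc[0, "onset_s"] = quiet_config.n_volumes * quiet_config.tr + 10
        with pytest.raises(InvalidConfigError):
            simulate_task_bold(cohort.iloc[0], events, quiet_config)


class TestPhysio:
    def test_no_modulation_constant_ibis(self):
        beats = simulate_beat_times(
            np.random.default_rng(0), 120, 1.0, 0.0, 0.0, 0.1, 0.25, 0.0, 0.4
        )
        ibis = np.diff(beats) * 1000
        np.testing.assert_allclose(ibis, 1000.0, atol=1e-9)

    def test_outlier_rate_expectation(self):
        """~2% of 300 beats displaced on average (binomial expectation)."""
        counts = []
        for s in range(20):
            beats = simulate_beat_times(
                np.random.default_rng(s), 300, 1.0, 0.0, 0.0, 0.1, 0.25, 0.02, 0.4
            )
            ibis = np.diff(beats) * 1000
            counts.append(np.count_nonzero(np.abs(ibis - 1000) > 100))
        # each displaced beat perturbs two intervals
        assert 2 * 300 * 0.02 * 0.5 < np.mean(counts) < 2 * 300 * 0.02 * 2

    def test_excessive_modulation_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_beat_times(np.random.default_rng(0), 120, 1.0, 0.7, 0.5, 0.1, 0.25, 0, 0)

    def test_waveform_duration_and_truth_returned(self, small_config, small_cohort):
        wave, beats_ms = simulate_physio(small_cohort.iloc[0], small_config)
        assert wave.duration_s == pytest.approx(small_config.physio_duration)
        assert np.all(np.diff(beats_ms) > 0)
        IbiSeries.from_beat_times(beats_ms)  # valid series


class TestSensors:
    def test_flat_channels_when_base_sd_zero(self, small_cohort):
        cfg = GeneratorConfig(n_participants=8, seed=1, sensor_base_sd=0.0,
                              sensor_duration=100.0, n_channels=4)
        run = simulate_sensors(small_cohort.iloc[0], cfg)
        assert np.abs(run.data).max() < 1e-12

    def test_doubling_target_sd_doubles_measured_alpha_sd(self, small_cohort):
        """Planted SDs are exact: doubling the configured SD doubles the measurement."""
        p = small_cohort.iloc[0]
        cfg1 = GeneratorConfig(n_participants=8, seed=1, sensor_duration=100.0, n_channels=6)
        cfg2 = GeneratorConfig(n_participants=8, seed=1, sensor_duration=100.0, n_channels=6,
                               sensor_base_sd=2.0)
        np.testing.assert_allclose(
            band_sd(simulate_sensors(p, cfg2), (8, 13)),
            2 * band_sd(simulate_sensors(p, cfg1), (8, 13)),
            rtol=1e-6,
        )

    def test_aliasing_rejected(self, small_cohort):
        cfg = GeneratorConfig(n_participants=8, seed=1, sensor_duration=100.0)
        cfg.sensor_fs = 150.0
        with pytest.raises(InvalidConfigError):
            simulate_sensors(small_cohort.iloc[0], cfg)
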