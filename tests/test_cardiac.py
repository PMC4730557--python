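"""Cardiac pipeline: beats, iterated IBI cleaning, HR, HRV power, PCA index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from rsfa.cardiac import (
    HF_BAND,
    LF_BAND,
    IbiSeries,
    Waveform,
    detect_beats,
    hrv_band_power,
    ibi_tachogram,
    mean_hr,
    reject_outliers_iterative,
    vascular_pca,
)
from rsfa.exceptions import DetectionError, InsufficientDataError
from rsfa.simulate.physio import simulate_beat_times, waveform_from_beats


class TestDetectBeats:
    def test_one_hz_pulse_train_counted(self):
        w = waveform_from_beats(np.arange(0, 60, 1.0), 50.0, 60.0, 0.05)
        assert abs(len(detect_beats(w)) - 60) <= 1

    def test_flat_line_raises(self):
        with pytest.raises(DetectionError):
            detect_beats(Waveform(np.ones(3000), 50.0))

    def test_robust_to_ten_percent_noise(self):
        w = waveform_from_beats(np.arange(0, 60, 1.0), 50.0, 60.0, 0.05)
        clean_count = len(detect_beats(w))
        rng = np.random.default_rng(0)
        noisy = Waveform(w.values + 0.1 * rng.standard_normal(len(w.values)), 50.0)
        assert len(detect_beats(noisy)) == clean_count


class TestOutlierRejection:
    def test_single_extreme_removed_in_pass_one(self):
        """Manual execution of the iterated procedure on 50x800 + 2000 ms."""
        result = reject_outliers_iterative(np.array([800.0] * 50 + [2000.0]))
        assert result.removed_indices == {50: 1}
        assert len(result.ibis_ms) == 50

    def test_identical_values_untouched(self):
        result = reject_outliers_iterative(np.full(30, 900.0))
        assert result.removed_indices == {}

    def test_two_outliers_removed_within_two_passes(self):
        result = reject_outliers_iterative(np.array([700.0] * 20 + [1500.0, 1450.0]))
        assert set(result.removed_indices) == {20, 21}
        assert max(result.removed_indices.values()) <= 2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(min_value=300, max_value=2000), min_size=12, max_size=60),
        st.integers(0, 2**16),
    )
    def test_idempotent_and_no_inliers_removed(self, base, seed):
        """Re-cleaning the cleaned series removes nothing, and every survivor
        is within 3 SD of the final sample."""
        ibis = np.array(base)
        try:
            first = reject_outliers_iterative(ibis)
        except Exception:
            return  # degenerate random draw
        if len(first.ibis_ms) < 10:
            return
        second = reject_outliers_iterative(first.ibis_ms)
        assert second.removed_indices == {}
        mu, sd = first.ibis_ms.mean(), first.ibis_ms.std(ddof=1)
        assert np.all(np.abs(first.ibis_ms - mu) <= 3 * sd + 1e-9)


class TestMeanHr:
    @pytest.mark.parametrize("ibi_ms,expected", [(1000.0, 60.0), (500.0, 120.0)])
    def test_constant_ibi(self, ibi_ms, expected):
        beats = np.arange(0, 120_001, ibi_ms)
        series = IbiSeries.from_beat_times(beats)
        assert mean_hr(series) == pytest.approx(expected, rel=0.02)

    def test_alternating_ibis_match_hand_count(self):
        # 800/1200 ms alternating: 60 beats per full minute exactly
        ibis = np.tile([800.0, 1200.0], 70)
        beats = np.concatenate([[0.0], np.cumsum(ibis)])
        series = IbiSeries.from_beat_times(beats)
        # hand count: beats fall at 0, .8, 2, 2.8, 4 ... -> exactly 60/min
        assert mean_hr(series) == pytest.approx(60.0, rel=0.02)

    def test_short_record_rejected(self):
        series = IbiSeries.from_beat_times(np.arange(0, 30_000, 1000.0))
        with pytest.raises(InsufficientDataError):
            mean_hr(series)


class TestHrvPower:
    @staticmethod
    def modulated_series(depth: float, freq: float = 0.10, seed: int = 0) -> IbiSeries:
        beats = simulate_beat_times(
            np.random.default_rng(seed), 300, 1.0, depth, 0.0, freq, 0.25, 0.0, 0.4
        )
        return IbiSeries.from_beat_times(beats * 1000)

    def test_constant_ibi_near_zero_power(self):
        series = IbiSeries.from_beat_times(np.arange(0, 300_001, 1000.0))
        assert hrv_band_power(series, LF_BAND) < 1e-12
        assert hrv_band_power(series, HF_BAND) < 1e-12

    def test_lf_modulation_specific_to_lf_band(self):
        series = self.modulated_series(0.05)
        assert hrv_band_power(series, LF_BAND) >= 20 * hrv_band_power(series, HF_BAND)

    def test_power_quadruples_when_depth_doubles(self):
        p1 = hrv_band_power(self.modulated_series(0.05), LF_BAND)
        p2 = hrv_band_power(self.modulated_series(0.10), LF_BAND)
        assert p2 / p1 == pytest.approx(4.0, rel=0.10)

    def test_parseval_total_power_matches_variance(self):
        series = self.modulated_series(0.04)
        tach, fs = ibi_tachogram(series)
        nper = min(int(64 * fs), tach.size)
        freqs, psd = sps.welch(tach, fs=fs, nperseg=nper, noverlap=nper // 2)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(tach.var(), rel=0.10)


class TestVascularPca:
    def test_isotropic_columns_share_variance(self, rng):
        n = 4000
        feats = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["mean_hr", "lf_power", "hf_power"]
        )
        vi = vascular_pca(feats)
        np.testing.assert_allclose(vi.variance_fraction, [1 / 3] * 3, atol=0.05)
        np.testing.assert_allclose(vi.variance_fraction.sum(), 1.0)

    def test_rank_one_structure_matches_sign_pattern(self, rng):
        """HR anti-correlated with LF=HF: PC1 takes ~all variance with
        loadings signed (-, +, +)."""
        base = rng.standard_normal(500)
        feats = pd.DataFrame(
            {"mean_hr": -base, "lf_power": base, "hf_power": base}
        )
        vi = vascular_pca(feats)
        assert vi.variance_fraction[0] > 0.999
        assert vi.loadings[0, 0] < 0 < vi.loadings[1, 0]
        assert vi.loadings[2, 0] > 0

    def test_pc1_scores_standardized_up_to_scale(self, rng):
        feats = pd.DataFrame(
            rng.standard_normal((200, 3)), columns=["mean_hr", "lf_power", "hf_power"]
        )
        vi = vascular_pca(feats)
        assert vi.pc1.mean() == pytest.approx(0.0, abs=1e-10)
        # unit-norm loadings: score variance equals the PC eigenvalue
        eigval = vi.variance_fraction[0] * 3
        assert vi.pc1.var(ddof=1) == pytest.approx(eigval, rel=1e-6)
        np.testing.assert_allclose(np.linalg.norm(vi.loadings, axis=0), 1.0)
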