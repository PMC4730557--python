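"""Cardiac indices from physiological waveforms.

From a pulse-oximetry (50 Hz) or ECG (1 kHz) trace: detect beats, take the
interbeat intervals (IBIs, ms), clean ectopic/artifactual intervals with an
iterated 3-SD criterion, then summarize the record as mean heart rate and
low/high-frequency heart-rate-variability power.  A PCA across the three
summaries yields a single "vascular health" score per participant (higher
score = lower heart rate and larger HRV, the young-adult pattern).

The outlier pass is deliberately literal about its first iteration: the
initial mean/SD cut-off is computed with the single most extreme interval
temporarily excluded (so one wild ectopic cannot inflate its own cut-off);
subsequent passes use the full remaining sample, and iteration stops when
a pass removes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .exceptions import (
    BandError,
    DegenerateSeriesError,
    DetectionError,
    InsufficientDataError,
    InvalidConfigError,
)

LF_BAND = (0.05, 0.15)
HF_BAND = (0.15, 0.40)

#: Resampling rate of the IBI tachogram before spectral estimation (Hz).
TACHOGRAM_FS = 4.0

VASCULAR_FEATURES = ["mean_hr", "lf_power", "hf_power"]


@dataclass
class Waveform:
    """A physiological trace: amplitude samples at a fixed rate."""

    values: np.ndarray
    fs: float
    modality: str = "pulseox"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.modality not in ("pulseox", "ecg"):
            raise InvalidConfigError(f"unknown modality '{self.modality}'")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


@dataclass
class IbiSeries:
    """Beat times (ms) and interbeat intervals (ms) with cleaning provenance.

    ``removed_indices`` maps original-IBI index -> removal pass number.
    """

    beat_times_ms: np.ndarray
    ibis_ms: np.ndarray
    removed_indices: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_times_ms = np.asarray(self.beat_times_ms, dtype=float)
        self.ibis_ms = np.asarray(self.ibis_ms, dtype=float)
        if np.any(np.diff(self.beat_times_ms) <= 0):
            raise InvalidConfigError("beat times must be strictly increasing")
        if np.any(self.ibis_ms <= 0):
            raise InvalidConfigError("interbeat intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times_ms: np.ndarray) -> "IbiSeries":
        bt = np.asarray(beat_times_ms, dtype=float)
        return cls(beat_times_ms=bt, ibis_ms=np.diff(bt))

    @property
    def duration_s(self) -> float:
        return (self.beat_times_ms[-1] - self.beat_times_ms[0]) / 1000.0


@dataclass
class VascularIndex:
    """PCA summary of (mean HR, LF-HRV, HF-HRV) across participants."""

    scores: np.ndarray          # participants x components
    loadings: np.ndarray        # 3 x components, unit-norm columns
    variance_fraction: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]


def detect_beats(w: Waveform, refractory_s: float = 0.3) -> np.ndarray:
    """Beat times (ms) via adaptive height/prominence peak picking.

    The threshold adapts to the trace: peaks must rise half-way from the
    median amplitude towards the 99th percentile (which tracks the pulse
    tops even when pulses are sparse), with a prominence requirement at
    0.3 of the same spread.  Peaks closer together than the refractory
    period are suppressed (largest wins).
    """
    v = w.values
    spread = np.percentile(v, 99) - np.median(v)
    if spread <= 0 or np.ptp(v) == 0:
        raise DetectionError("waveform is flat; no beats to detect")
    height = np.median(v) + 0.5 * spread
    distance = max(int(round(refractory_s * w.fs)), 1)
    peaks, _ = signal.find_peaks(
        v, height=height, prominence=0.3 * spread, distance=distance
    )
    if len(peaks) < 10:
        raise DetectionError(f"only {len(peaks)} beats detected; need at least 10")
    return peaks / w.fs * 1000.0


def reject_outliers_iterative(
    ibis: np.ndarray | IbiSeries, k: float = 3.0, beat_times_ms: np.ndarray | None = None
) -> IbiSeries:
    """Iterated mean +/- k*SD outlier removal on an IBI sample.

    Pass 1 computes the cut-off after temporarily excluding the single most
    extreme interval; every later pass uses the full remaining sample.
    Iteration stops when a pass removes nothing.  Removal provenance (which
    original interval fell in which pass) is recorded on the result.
    """
    if isinstance(ibis, IbiSeries):
        beat_times_ms = ibis.beat_times_ms
        values = ibis.ibis_ms.copy()
    else:
        values = np.asarray(ibis, dtype=float).copy()
    if values.size < 10:
        raise InsufficientDataError("need at least 10 intervals to estimate a cut-off")

    original_idx = np.arange(values.size)
    removed: dict[int, int] = {}
    pass_no = 0
    while True:
        pass_no += 1
        if values.size < 3:
            raise DegenerateSeriesError("outlier rejection removed nearly the whole series")
        if pass_no == 1:
            extreme = np.argmax(np.abs(values - np.mean(values)))
            sample = np.delete(values, extreme)
        else:
            sample = values
        mu, sd = np.mean(sample), np.std(sample, ddof=1)
        # with sd == 0 this still removes any value off the mean, and keeps
        # an all-identical sample intact (0 > 0 is false)
        bad = np.abs(values - mu) > k * sd
        if not bad.any():
            break
        for j in original_idx[bad]:
            removed[int(j)] = pass_no
        values = values[~bad]
        original_idx = original_idx[~bad]
    if values.size == 0:
        raise DegenerateSeriesError("all intervals removed")

    if beat_times_ms is not None:
        # keep the beat time that ends each surviving interval, plus the first
        kept_bt = np.concatenate([beat_times_ms[:1], beat_times_ms[1:][np.isin(
            np.arange(len(beat_times_ms) - 1), original_idx)]])
    else:
        kept_bt = np.concatenate([[0.0], np.cumsum(values)])
    return IbiSeries(beat_times_ms=kept_bt, ibis_ms=values, removed_indices=removed)


def mean_hr(ibi: IbiSeries, window_s: float = 60.0) -> float:
    """Mean heart rate (bpm): beats counted per window, averaged over windows.

    Windows tile the record from the first beat; a trailing partial window
    shorter than half a window is discarded, a longer one contributes at its
    rate scaled to beats/min.
    """
    bt = (ibi.beat_times_ms - ibi.beat_times_ms[0]) / 1000.0
    total = bt[-1]
    if total < window_s:
        raise InsufficientDataError(
            f"record ({total:.0f} s) shorter than one {window_s:.0f}-s window"
        )
    rates = []
    start = 0.0
    while start + window_s <= total:
        count = np.count_nonzero((bt >= start) & (bt < start + window_s))
        rates.append(count * 60.0 / window_s)
        start += window_s
    tail = total - start
    if tail >= window_s / 2:
        count = np.count_nonzero((bt >= start) & (bt < total))
        rates.append(count * 60.0 / tail)
    return float(np.mean(rates))


def ibi_tachogram(
    ibi: IbiSeries, fs: float = TACHOGRAM_FS
) -> tuple[np.ndarray, float]:
    """Cubic-spline resampling of the IBI series to a uniform rate, detrended."""
    t = ibi.beat_times_ms[1:] / 1000.0  # each interval timestamped at its end beat
    y = ibi.ibis_ms
    if t.size < 4:
        raise InsufficientDataError("too few intervals for a tachogram")
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    spline = interpolate.CubicSpline(t, y)
    resampled = signal.detrend(spline(grid), type="linear")
    return resampled, fs


def hrv_band_power(ibi: IbiSeries, band: tuple[float, float]) -> float:
    """HRV spectral power (ms^2) in a band, via Welch on the 4-Hz tachogram.

    Welch uses 64-s segments with 50% overlap (shorter records fall back to
    the record length), and the band power is the integral of the PSD.
    """
    if ibi.duration_s < 120.0:
        raise InsufficientDataError("need at least 120 s of intervals for HRV power")
    lo, hi = band
    if not 0 <= lo < hi:
        raise BandError(f"bad band ({lo}, {hi})")
    if hi > TACHOGRAM_FS / 2:
        raise BandError(f"band edge {hi} Hz above the tachogram Nyquist {TACHOGRAM_FS / 2} Hz")
    x, fs = ibi_tachogram(ibi)
    nperseg = min(int(64 * fs), x.size)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 2:
        raise BandError("band too narrow for the spectral resolution")
    return float(np.trapezoid(psd[sel], freqs[sel]))


def cardiac_summary(
    w: Waveform, k: float = 3.0, window_s: float = 60.0
) -> dict[str, float]:
    """Beat detection -> cleaning -> {mean_hr, lf_power, hf_power} for one trace."""
    beats = detect_beats(w)
    ibi = reject_outliers_iterative(IbiSeries.from_beat_times(beats), k=k)
    return {
        "mean_hr": mean_hr(ibi, window_s=window_s),
        "lf_power": hrv_band_power(ibi, LF_BAND),
        "hf_power": hrv_band_power(ibi, HF_BAND),
    }


def vascular_pca(features: pd.DataFrame) -> VascularIndex:
    """Correlation-matrix PCA of the (mean HR, LF-HRV, HF-HRV) table.

    Columns are z-scored first.  PC1 is sign-oriented so its HF-HRV loading
    is positive: a higher score means lower heart rate and larger HRV, i.e.
    better vascular health.
    """
    missing = [c for c in VASCULAR_FEATURES if c not in features.columns]
    if missing:
        raise InvalidConfigError(f"feature table missing columns {missing}")
    x = features[VASCULAR_FEATURES].to_numpy(dtype=float)
    if x.shape[0] < 4:
        raise InsufficientDataError("need at least 4 participants for the PCA")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateSeriesError("constant feature column; PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    cov = z.T @ z / (z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.maximum(eigvals[order], 0.0), eigvecs[:, order]
    hf_row = VASCULAR_FEATURES.index("hf_power")
    flip = np.where(eigvecs[hf_row] < 0, -1.0, 1.0)
    eigvecs = eigvecs * flip
    scores = z @ eigvecs
    return VascularIndex(
        scores=scores,
        loadings=eigvecs,
        variance_fraction=eigvals / eigvals.sum(),
    )
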