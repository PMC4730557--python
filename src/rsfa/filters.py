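"""Zero-phase Butterworth band-pass filtering shared by every analysis path.

The same filter is used to band-limit resting BOLD before the fluctuation
amplitude is taken, to band-split sensor time series, and by the synthetic
generators (which filter white noise with the identical kernel so that
planted standard deviations survive the analysis path by construction).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .exceptions import BandError

DEFAULT_ORDER = 4


def bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int = DEFAULT_ORDER):
    """Second-order-sections Butterworth band-pass design.

    Parameters
    ----------
    low_hz, high_hz
        Pass-band edges in Hz; must satisfy ``0 < low < high < fs/2``.
    fs
        Sampling frequency in Hz.
    order
        Filter order (applied forward and backward, so the effective
        magnitude response is the square of a single pass).
    """
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz):
        raise BandError(f"band edges must satisfy 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise BandError(
            f"upper band edge {high_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filtfilt(
    x: np.ndarray,
    low_hz: float,
    high_hz: float,
    fs: float,
    order: int = DEFAULT_ORDER,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase band-pass: forward-backward application of :func:`bandpass_sos`."""
    sos = bandpass_sos(low_hz, high_hz, fs, order=order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    low_hz: float,
    high_hz: float,
    fs: float,
    target_sd: np.ndarray | float = 1.0,
    axis: int = -1,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """White noise band-passed and rescaled so each series has exactly ``target_sd``.

    ``target_sd`` broadcasts against the non-time axes; the SD is the
    sample SD with the n-1 denominator, matching how the fluctuation
    amplitude is measured downstream.
    """
    x = rng.standard_normal(shape)
    x = bandpass_filtfilt(x, low_hz, high_hz, fs, order=order, axis=axis)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    target = np.asarray(target_sd, dtype=float)
    if target.ndim and target.ndim < x.ndim:
        target = np.expand_dims(target, axis=axis)
    return x / sd * target
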