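"""Synthetic pulse waveforms with LF/HF interbeat modulation and ectopic beats.

The beat train integrates an instantaneous interbeat interval that is a
base interval (set by the participant's latent vascular gain through a
target heart rate) modulated by one sinusoid in the low-frequency HRV band
and one in the high-frequency band, both with amplitude proportional to V.
A configured fraction of beats is displaced by +/-40% of the local
interval to mimic ectopic beats, which the downstream iterated 3-SD
cleaning is expected to reject.  The waveform is a train of Gaussian
pulses sampled at the pulse-oximeter rate; ground-truth beat times are
returned alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cardiac import Waveform
from ..exceptions import InvalidConfigError
from .config import GeneratorConfig


def participant_heart_params(participant: pd.Series, config: GeneratorConfig) -> dict:
    """Base IBI and band modulation depths implied by a participant's V."""
    v = float(participant["V"])
    hr = config.base_hr_bpm + config.hr_per_v * (v - 1.25)
    hr = float(np.clip(hr, 40.0, 140.0))
    return {
        "base_ibi_s": 60.0 / hr,
        "lf_frac": config.lf_frac_per_v * v,
        "hf_frac": config.hf_frac_per_v * v,
    }


def simulate_beat_times(
    rng: np.random.Generator,
    duration_s: float,
    base_ibi_s: float,
    lf_frac: float,
    hf_frac: float,
    lf_hz: float,
    hf_hz: float,
    outlier_rate: float,
    outlier_frac: float,
) -> np.ndarray:
    """Integrate the modulated interbeat interval into beat times (seconds)."""
    if lf_frac + hf_frac >= 1.0:
        raise InvalidConfigError("IBI modulation depth must stay below the base interval")
    times = [0.0]
    while times[-1] < duration_s:
        t = times[-1]
        ibi = base_ibi_s * (
            1.0
            + lf_frac * np.sin(2 * np.pi * lf_hz * t)
            + hf_frac * np.sin(2 * np.pi * hf_hz * t)
        )
        times.append(t + ibi)
    beats = np.array(times[:-1])
    if outlier_rate > 0 and beats.size > 2:
        n_out = rng.binomial(beats.size - 2, outlier_rate)
        if n_out:
            picks = rng.choice(np.arange(1, beats.size - 1), size=n_out, replace=False)
            local = np.diff(beats).mean()
            shifts = rng.choice([-1.0, 1.0], size=n_out) * outlier_frac * local
            beats[picks] += shifts
            beats = np.sort(beats)
    return beats


def waveform_from_beats(
    beat_times_s: np.ndarray, fs: float, duration_s: float, pulse_width_s: float
) -> Waveform:
    """Render beats as a train of unit-amplitude Gaussian pulses."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    values = np.zeros(n)
    half = int(np.ceil(4 * pulse_width_s * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (kernel_t / pulse_width_s) ** 2)
    for bt in beat_times_s:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            values[lo:hi] += kernel[klo:khi]
    return Waveform(values=values, fs=fs, modality="pulseox")


def simulate_physio(
    participant: pd.Series, config: GeneratorConfig
) -> tuple[Waveform, np.ndarray]:
    """Pulse waveform plus ground-truth beat times (ms) for one participant."""
    config.validate()
    if config.physio_duration < 120.0:
        raise InvalidConfigError("physio duration must be at least 120 s")
    pid = int(str(participant.get("participant_id", "sub-0000")).rsplit("-", 1)[-1])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7919, pid)))
    params = participant_heart_params(participant, config)
    beats_s = simulate_beat_times(
        rng,
        config.physio_duration,
        params["base_ibi_s"],
        params["lf_frac"],
        params["hf_frac"],
        config.lf_hz,
        config.hf_hz,
        config.ibi_outlier_rate,
        config.ibi_outlier_frac,
    )
    wave = waveform_from_beats(
        beats_s, config.physio_fs, config.physio_duration, config.pulse_width_s
    )
    return wave, beats_s * 1000.0
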