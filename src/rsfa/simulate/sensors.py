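"""Synthetic multichannel sensor runs with planted band-SD structure.

Each channel is a sum over the six standard bands of band-limited noise
whose SD is set exactly (the generator filters white noise with the same
filter the analysis uses, then rescales).  Within each band the target
per-channel SD follows

``sd(c) = base_b(age) * (1 + l1 * p1(c) + l2 * p2(c))``

where ``p1, p2`` are two fixed, non-overlapping spatial patterns over
channels and ``l1, l2`` per-participant loadings (the first driven by the
latent neural amplitude N, the second independent).  Across a cohort the
participants x channels band-SD matrix is therefore an exact two-source
mixing model, which the ICA in :mod:`rsfa.decompose` should recover, and
the per-band base SD carries the band-specific age slope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..bands import SensorRun
from ..exceptions import InvalidConfigError
from ..filters import band_limited_noise
from .config import SENSOR_BANDS, GeneratorConfig


def sensor_patterns(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint focal bumps over the channel axis, peak height 1.

    The bumps are deliberately narrow (a couple of channels wide): focal,
    sharply peaked topographies are strongly super-Gaussian across
    channels, which is what makes them identifiable by ICA up to
    permutation and sign.
    """
    idx = np.arange(n_channels)
    width = max(0.035 * n_channels, 1.0)
    p1 = np.exp(-0.5 * ((idx - 0.25 * n_channels) / width) ** 2)
    p2 = np.exp(-0.5 * ((idx - 0.75 * n_channels) / width) ** 2)
    return p1, p2


def participant_pattern_loadings(
    participant: pd.Series, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Loadings of the two spatial patterns: one tied to N, one free.

    The N-driven loading is scaled to the latent's own spread so the
    planted spatial modulation (~30% of baseline SD at one loading SD)
    comfortably exceeds the finite-record SD estimation noise.
    """
    n_lat = float(participant["N"])
    z_n = (n_lat - config.n_intercept) / max(config.n_noise_sd, 1e-12)
    l1 = 0.3 * z_n + rng.normal(0.0, 0.05)
    l2 = rng.normal(0.0, 0.25)
    return l1, l2


def target_band_sd(
    participant: pd.Series,
    config: GeneratorConfig,
    loadings: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Planted per-channel SD for every band, for one participant."""
    if loadings is None:
        if rng is None:
            rng = np.random.default_rng(0)
        loadings = participant_pattern_loadings(participant, config, rng)
    l1, l2 = loadings
    p1, p2 = sensor_patterns(config.n_channels)
    age = float(participant["age"])
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    n_lat = float(participant["N"])
    out = {}
    for name in SENSOR_BANDS:
        slope = config.age_slope_n_by_band.get(name, 0.0)
        base = config.sensor_base_sd * n_lat * (1.0 + slope * (age - mid_age))
        base = max(base, 0.0)
        profile = 1.0 + config.pattern_gain * (l1 * p1 + l2 * p2)
        out[name] = np.maximum(base * profile, 0.0)
    return out


def simulate_sensors(
    participant: pd.Series,
    config: GeneratorConfig,
    return_truth: bool = False,
) -> SensorRun | tuple[SensorRun, dict]:
    """One participant's channels x samples run with exact planted band SDs."""
    config.validate()
    highest = max(hi for _, hi in SENSOR_BANDS.values())
    if config.sensor_fs <= 2 * highest:
        raise InvalidConfigError("sensor sampling rate too low for the gamma band (aliasing)")
    if config.sensor_duration < 100.0:
        raise InvalidConfigError("sensor records shorter than 100 s cannot carry 0.01 Hz content")
    pid = int(str(participant.get("participant_id", "sub-0000")).rsplit("-", 1)[-1])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 104729, pid)))
    loadings = participant_pattern_loadings(participant, config, rng)
    targets = target_band_sd(participant, config, loadings=loadings)

    n_samples = int(round(config.sensor_duration * config.sensor_fs))
    data = np.zeros((config.n_channels, n_samples))
    for name, (lo, hi) in SENSOR_BANDS.items():
        sd = targets[name]
        if np.all(sd == 0):
            continue
        data += band_limited_noise(
            rng,
            (config.n_channels, n_samples),
            lo,
            hi,
            config.sensor_fs,
            target_sd=sd,
            axis=-1,
        )
    run = SensorRun(data=data, fs=config.sensor_fs)
    if return_truth:
        return run, {"loadings": loadings, "target_sd": targets}
    return run
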