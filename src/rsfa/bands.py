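"""Band-limited variability of multichannel sensor (MEG-style) recordings.

For each named frequency band (infra-slow "subdelta" 0.01-0.08 Hz through
gamma 30-80 Hz) the per-channel statistic is the SD of the zero-phase
band-passed time series — the sensor-space analogue of RSFA, chosen over
Hilbert-envelope SD to keep the variability definition identical across
modalities (an envelope option is exposed).  A cohort's participants x
channels SD matrices feed the ICA in :mod:`rsfa.decompose`; the grand mean
over channels is the global summary used as a mediator.

Also here: a generic artifact-component flagger that marks ICA components
whose time courses correlate with reference (EOG/ECG-style) channels
beyond 3 SD of all such correlations, optionally additionally requiring a
spatial-template correlation beyond 2 SD for eye-movement references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import BandError, InsufficientDataError, InvalidConfigError, ShapeError
from .filters import bandpass_filtfilt

#: Named frequency bands (Hz). The gap between the infra-slow band and
#: delta is deliberate: variability is defined on this exact band list,
#: not on a partition of the spectrum.
SENSOR_BANDS: dict[str, tuple[float, float]] = {
    "subdelta": (0.01, 0.08),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


@dataclass
class SensorRun:
    """channels x samples array at a fixed sampling rate."""

    data: np.ndarray
    fs: float
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ShapeError("channel_ids length does not match data rows")
        if not np.isfinite(self.data).all():
            raise ShapeError("sensor data contains non-finite samples")


def band_sd(
    run: SensorRun, band: tuple[float, float], envelope: bool = False
) -> np.ndarray:
    """Per-channel SD of the band-passed time series (n-1 denominator).

    With ``envelope=True`` the SD is taken of the Hilbert envelope of the
    band-passed signal instead of the raw filtered samples.
    """
    lo, hi = band
    if hi >= run.fs / 2:
        raise BandError(f"band edge {hi} Hz at or above Nyquist {run.fs / 2} Hz")
    filtered = bandpass_filtfilt(run.data, lo, hi, run.fs, axis=1)
    if envelope:
        filtered = np.abs(hilbert(filtered, axis=1))
    return filtered.std(axis=1, ddof=1)


def all_band_sd(
    run: SensorRun, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, np.ndarray]:
    """Per-channel SD for every named band (default: the six standard bands)."""
    bands = SENSOR_BANDS if bands is None else bands
    return {name: band_sd(run, edges) for name, edges in bands.items()}


def grand_mean_variability(band_values: np.ndarray) -> np.ndarray:
    """Arithmetic mean over channels (the last axis) of a band-SD array.

    Accepts a (channels,) vector for one participant or a (participants,
    channels) matrix.
    """
    values = np.asarray(band_values, dtype=float)
    if values.shape[-1] < 1:
        raise InsufficientDataError("no channels to average")
    return values.mean(axis=-1)


def flag_artifact_components(
    component_timecourses: np.ndarray,
    reference_channels: np.ndarray,
    spatial_maps: np.ndarray | None = None,
    templates: np.ndarray | None = None,
    eog_references: list[int] | None = None,
    temporal_sd_factor: float = 3.0,
    spatial_sd_factor: float = 2.0,
) -> np.ndarray:
    """Flag components correlated with physiological reference channels.

    A component is temporally suspicious for reference channel ``r`` when
    ``|corr(component, r)|`` is at least ``temporal_sd_factor`` times the SD
    of all component correlations with that channel.  For references listed
    in ``eog_references`` the component must additionally have
    ``|corr(spatial_map, template)|`` at least ``spatial_sd_factor`` times
    the SD of all map-template correlations; other references (e.g. ECG)
    flag on the temporal criterion alone.  Returns a boolean flag per
    component.
    """
    tc = np.atleast_2d(np.asarray(component_timecourses, dtype=float))
    refs = np.atleast_2d(np.asarray(reference_channels, dtype=float))
    n_comp = tc.shape[0]
    if n_comp < 5:
        raise InsufficientDataError(
            "need at least 5 components to estimate the correlation SD threshold"
        )
    if tc.shape[1] != refs.shape[1]:
        raise ShapeError("component and reference time courses differ in length")
    eog_references = eog_references or []

    def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        az = (a - a.mean(axis=1, keepdims=True)) / (a.std(axis=1, keepdims=True) + 1e-300)
        bz = (b - b.mean(axis=1, keepdims=True)) / (b.std(axis=1, keepdims=True) + 1e-300)
        return az @ bz.T / a.shape[1]

    temporal = _corr_rows(tc, refs)  # components x references

    spatial_ok = np.ones((n_comp, refs.shape[0]), dtype=bool)
    if eog_references:
        if spatial_maps is None or templates is None:
            raise InvalidConfigError(
                "spatial_maps and templates are required when eog_references is set"
            )
        maps = np.atleast_2d(np.asarray(spatial_maps, dtype=float))
        tpl = np.atleast_2d(np.asarray(templates, dtype=float))
        if maps.shape[0] != n_comp:
            raise ShapeError("one spatial map per component is required")
        spatial = _corr_rows(maps, tpl)  # components x templates
        sp_thresh = spatial_sd_factor * spatial.std(ddof=1)
        sp_hit = (np.abs(spatial) >= sp_thresh).any(axis=1)
        for r in eog_references:
            spatial_ok[:, r] = sp_hit

    flags = np.zeros(n_comp, dtype=bool)
    for r in range(refs.shape[0]):
        thresh = temporal_sd_factor * temporal[:, r].std(ddof=1)
        flags |= (np.abs(temporal[:, r]) >= thresh) & spatial_ok[:, r]
    return flags
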