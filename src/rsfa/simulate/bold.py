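"""Synthetic resting and task BOLD runs on a labelled voxel grid.

The grid is split into five slabs along x: a vascular region (resting
fluctuation amplitude proportional to the latent vascular gain V and a
task response whose neural drive is age-flat), a neural region (resting
amplitude driven by V with a weaker neural contribution, task response
proportional to N*V), a null grey-matter region, and white-matter and CSF
slabs that carry a shared nuisance signal.  Runs come back as
:class:`~rsfa.fluctuation.BoldRun`, ready for the analysis pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import InvalidConfigError, ShapeError
from ..fluctuation import MOTION_COLUMNS, BoldRun, build_nuisance
from ..filters import band_limited_noise, bandpass_filtfilt
from ..task import task_regressor, validate_events
from .config import (
    BOLD_BAND,
    REGION_CSF,
    REGION_NEURAL,
    REGION_NULL,
    REGION_VASCULAR,
    REGION_WM,
    GeneratorConfig,
)

# x-extent fractions of the five slabs, in label order below
_SLAB_FRACTIONS = (
    (REGION_VASCULAR, 0.0, 0.3125),
    (REGION_NEURAL, 0.3125, 0.625),
    (REGION_NULL, 0.625, 0.8125),
    (REGION_WM, 0.8125, 0.9375),
    (REGION_CSF, 0.9375, 1.0),
)


def default_region_labels(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Partition a grid into vascular / neural / null GM, WM, and CSF slabs."""
    nx = grid_shape[0]
    if nx < 5:
        raise InvalidConfigError("grid needs at least 5 voxels along x for the region slabs")
    labels = np.full(grid_shape, REGION_NULL, dtype=int)
    for code, lo, hi in _SLAB_FRACTIONS:
        i0, i1 = int(round(lo * nx)), int(round(hi * nx))
        labels[i0:max(i1, i0 + 1)] = code
    return labels


def masks_from_labels(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Tissue masks from a region-label array."""
    gm = np.isin(labels, (REGION_VASCULAR, REGION_NEURAL, REGION_NULL))
    return {
        "gm_mask": gm,
        "wm_mask": labels == REGION_WM,
        "csf_mask": labels == REGION_CSF,
        "vascular": labels == REGION_VASCULAR,
        "neural": labels == REGION_NEURAL,
        "null": labels == REGION_NULL,
    }


def simulate_motion(rng: np.random.Generator, n_volumes: int) -> pd.DataFrame:
    """Slow random-walk motion traces (mm / rad), mild by construction."""
    steps = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    walk *= np.array([0.05] * 3 + [0.001] * 3)  # mm, rad
    return pd.DataFrame(walk, columns=MOTION_COLUMNS)


def _rest_amplitude_map(
    labels: np.ndarray, v: float, n_lat: float, config: GeneratorConfig
) -> np.ndarray:
    """Per-voxel target SD of the band-limited resting fluctuation."""
    amp = np.zeros(labels.shape)
    amp[labels == REGION_VASCULAR] = config.rest_fluct_sd * v
    # the neural region's resting amplitude is still vascular-dominated;
    # N contributes with a weaker multiplicative coupling
    amp[labels == REGION_NEURAL] = (
        config.rest_fluct_sd * v * (1.0 + config.neural_rest_coupling * (n_lat - 1.0))
    )
    amp[labels == REGION_NULL] = config.rest_fluct_sd
    return np.maximum(amp, 0.0)


def _common_parts(
    participant: pd.Series,
    config: GeneratorConfig,
    labels: np.ndarray | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.random.Generator]:
    config.validate()
    if labels is None:
        labels = default_region_labels(config.grid_shape)
    elif labels.shape != tuple(config.grid_shape):
        raise ShapeError(
            f"region labels shape {labels.shape} does not match grid {config.grid_shape}"
        )
    masks = masks_from_labels(labels)
    # per-participant stream: offset the study seed by the participant index
    pid = int(str(participant.get("participant_id", "sub-0000")).rsplit("-", 1)[-1])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, pid)))
    return labels, masks, rng


def _drift_and_noise(
    rng: np.random.Generator,
    n_vox: int,
    t: int,
    config: GeneratorConfig,
    motion: pd.DataFrame,
    wm_idx: np.ndarray,
    csf_idx: np.ndarray,
    fs: float,
    white_sd: float,
) -> np.ndarray:
    """Drift + motion-coupled + shared-nuisance + white-noise components, (vox, t)."""
    time = np.arange(t, dtype=float)
    linear = (time - time.mean()) / (time.std() or 1.0)
    quad = linear**2 - (linear**2).mean()
    c1 = rng.normal(0.0, config.drift_linear_sd, size=n_vox)
    c2 = rng.normal(0.0, config.drift_quad_sd, size=n_vox)
    out = c1[:, None] * linear + c2[:, None] * quad

    mot = motion[MOTION_COLUMNS].to_numpy(float)
    mot_z = (mot - mot.mean(axis=0)) / (mot.std(axis=0) + 1e-12)
    weights = rng.normal(0.0, config.motion_coupling_sd, size=(n_vox, 6))
    out += weights @ mot_z.T

    # distinct (independent) shared signals for WM and CSF so both nuisance
    # regressors carry information
    for tissue_idx in (wm_idx, csf_idx):
        if tissue_idx.size and config.nuisance_sd > 0:
            shared = band_limited_noise(
                rng, (t,), BOLD_BAND[0], BOLD_BAND[1], fs, target_sd=config.nuisance_sd
            )
            out[tissue_idx] += shared

    if white_sd > 0:
        out += rng.normal(0.0, white_sd, size=(n_vox, t))
    return out


def simulate_rest_bold(
    participant: pd.Series,
    config: GeneratorConfig,
    labels: np.ndarray | None = None,
) -> BoldRun:
    """A resting run whose band-limited fluctuation SD is planted per region.

    The fluctuation is white noise passed through the same 0.01-0.08 Hz
    filter the analysis uses, orthogonalized against the run's own nuisance
    design, and rescaled so that its SD *after* the analysis band-pass
    equals the target.  The measured RSFA therefore recovers the planted
    amplitude exactly up to the in-band part of the white measurement
    noise.
    """
    labels, masks, rng = _common_parts(participant, config, labels)
    t = config.n_volumes
    fs = 1.0 / config.tr
    n_vox = int(np.prod(config.grid_shape))
    flat_labels = labels.reshape(-1)

    # structured background first: drift, motion coupling, shared WM/CSF
    # nuisance, white noise.  The nuisance design is built from this base
    # run so the planted fluctuation can be made orthogonal to it.
    motion = simulate_motion(rng, t)
    wm_idx = np.flatnonzero(flat_labels == REGION_WM)
    csf_idx = np.flatnonzero(flat_labels == REGION_CSF)
    data = _drift_and_noise(
        rng, n_vox, t, config, motion, wm_idx, csf_idx, fs, config.white_noise_sd
    )

    amp = _rest_amplitude_map(
        labels, float(participant["V"]), float(participant["N"]), config
    ).reshape(-1)
    active = np.flatnonzero(amp > 0)
    if active.size:
        base_run = BoldRun(
            data=data.reshape(*config.grid_shape, t),
            tr=config.tr,
            gm_mask=masks["gm_mask"],
            wm_mask=masks["wm_mask"],
            csf_mask=masks["csf_mask"],
            motion=motion,
        )
        design = build_nuisance(base_run).matrix
        raw = bandpass_filtfilt(
            rng.standard_normal((active.size, t)), BOLD_BAND[0], BOLD_BAND[1], fs, axis=-1
        ).T  # (t, n_active)
        coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
        resid = raw - design @ coef
        refiltered = bandpass_filtfilt(resid, BOLD_BAND[0], BOLD_BAND[1], fs, axis=0)
        sd = refiltered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        data[active] += (resid * (amp[active] / sd)).T

    return BoldRun(
        data=data.reshape(*config.grid_shape, t),
        tr=config.tr,
        gm_mask=masks["gm_mask"],
        wm_mask=masks["wm_mask"],
        csf_mask=masks["csf_mask"],
        motion=motion,
    )


def make_event_table(config: GeneratorConfig, n_events: int | None = None) -> pd.DataFrame:
    """Regularly spaced brief stimulation events filling most of the run."""
    run_dur = config.n_volumes * config.tr
    first = 10.0
    if n_events is None:
        n_events = int((run_dur - first - 20.0) // config.task_soa)
    onsets = first + config.task_soa * np.arange(n_events)
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": np.full(n_events, config.event_duration),
            "condition": "stim",
        }
    )
    return validate_events(events, run_dur)


def simulate_task_bold(
    participant: pd.Series,
    events: pd.DataFrame,
    config: GeneratorConfig,
    labels: np.ndarray | None = None,
) -> BoldRun:
    """A task run whose true response amplitude is neural drive x vascular gain.

    In the vascular region the neural drive is constant (amplitude = V); in
    the neural region it is the latent N (amplitude = N*V).  The unscaled
    GLM beta therefore tracks the product while the RSFA-scaled beta tracks
    the neural drive alone.
    """
    labels, masks, rng = _common_parts(participant, config, labels)
    t = config.n_volumes
    validate_events(events, t * config.tr)
    reg = task_regressor(events, t, config.tr)

    v = float(participant["V"])
    n_lat = float(participant["N"])
    amp = np.zeros(labels.shape)
    amp[labels == REGION_VASCULAR] = config.task_amplitude * v
    amp[labels == REGION_NEURAL] = config.task_amplitude * n_lat * v
    amp = amp.reshape(-1)

    n_vox = int(np.prod(config.grid_shape))
    data = amp[:, None] * reg[None, :]

    motion = simulate_motion(rng, t)
    flat_labels = labels.reshape(-1)
    wm_idx = np.flatnonzero(flat_labels == REGION_WM)
    csf_idx = np.flatnonzero(flat_labels == REGION_CSF)
    data += _drift_and_noise(
        rng, n_vox, t, config, motion, wm_idx, csf_idx, 1.0 / config.tr, config.task_noise_sd
    )

    return BoldRun(
        data=data.reshape(*config.grid_shape, t),
        tr=config.tr,
        gm_mask=masks["gm_mask"],
        wm_mask=masks["wm_mask"],
        csf_mask=masks["csf_mask"],
        motion=motion,
    )
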