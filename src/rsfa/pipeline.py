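"""Cohort-level convenience pipelines chaining the per-participant stages.

These loops exist so a whole synthetic study — cohort, per-participant
resting/task BOLD, physiology and sensor runs, summary extraction, group
decomposition and the mediation battery — runs with a few calls.  Each
returns plain tables/arrays; nothing here adds statistics of its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bands, cardiac, decompose, fluctuation, mediation, task
from .simulate import (
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


def cohort_cardiac_table(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Waveform -> beats -> cleaned IBIs -> {mean HR, LF, HF} per participant."""
    rows = []
    for _, participant in cohort.iterrows():
        wave, _ = simulate_physio(participant, config)
        summary = cardiac.cardiac_summary(wave)
        summary["participant_id"] = participant["participant_id"]
        rows.append(summary)
    return pd.DataFrame(rows)[["participant_id", *cardiac.VASCULAR_FEATURES]]


def cohort_rsfa_matrix(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Participants x GM-voxels RSFA matrix (and the GM flat index)."""
    if labels is None:
        labels = default_region_labels(config.grid_shape)
    masks = masks_from_labels(labels)
    gm_idx = np.flatnonzero(masks["gm_mask"].reshape(-1))
    rows = []
    for _, participant in cohort.iterrows():
        run = simulate_rest_bold(participant, config, labels=labels)
        rsfa_map = fluctuation.compute_rsfa(run)
        rows.append(rsfa_map.values.reshape(-1)[gm_idx])
    return np.vstack(rows), gm_idx


def cohort_band_matrices(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> dict[str, np.ndarray]:
    """Per-band participants x channels SD matrices."""
    out: dict[str, list[np.ndarray]] = {name: [] for name in bands.SENSOR_BANDS}
    for _, participant in cohort.iterrows():
        run = simulate_sensors(participant, config)
        sds = bands.all_band_sd(run)
        for name, values in sds.items():
            out[name].append(values)
    return {name: np.vstack(rows) for name, rows in out.items()}


def scaling_experiment(
    config: GeneratorConfig | None = None,
    n: int = 100,
    seed: int = 0,
) -> dict:
    """The vascular-vs-neural task-scaling experiment on a synthetic cohort.

    The generator plants a vascular-only age decline in the vascular region
    (neural drive age-flat, V falls with age) and a genuine neural age
    increase in the neural region (N rises with age).  Unscaled group age
    maps should show spurious "activation decline" in the vascular region;
    dividing betas by RSFA should abolish it there while the neural
    region's effect survives.

    Returns the group stat maps plus the voxel fractions summarizing the
    pattern.
    """
    if config is None:
        config = GeneratorConfig(
            n_participants=n,
            seed=seed,
            # a decisive neural age increase for the planted region-B effect
            age_slope_n=0.01,
            n_noise_sd=0.08,
            n_intercept=0.5,
        )
    cohort = generate_cohort(config)
    labels = default_region_labels(config.grid_shape)
    masks = masks_from_labels(labels)
    events = make_event_table(config)

    unscaled, scaled = [], []
    for _, participant in cohort.iterrows():
        rest = simulate_rest_bold(participant, config, labels=labels)
        rsfa_map = fluctuation.compute_rsfa(rest)
        trun = simulate_task_bold(participant, events, config, labels=labels)
        beta = task.fit_task_glm(trun, events)
        # restrict to grey matter: the scaling question is about GM voxels
        beta.mask &= masks["gm_mask"]
        unscaled.append(beta)
        scaled.append(task.scale_betas(beta, rsfa_map))

    stats_unscaled = task.group_age_regression(unscaled, cohort)
    stats_scaled = task.group_age_regression(scaled, cohort)

    vasc, neur = masks["vascular"], masks["neural"]
    scaled_mask = scaled[0].mask
    for m in scaled[1:]:
        scaled_mask = scaled_mask & m.mask
    vasc_s = vasc & scaled_mask
    neur_s = neur & scaled_mask
    return {
        "cohort": cohort,
        "stats_unscaled": stats_unscaled,
        "stats_scaled": stats_scaled,
        "frac_vascular_unscaled_negative": float(
            np.mean(stats_unscaled.t[vasc] < -2)
        ),
        "frac_vascular_scaled_null": float(np.mean(np.abs(stats_scaled.t[vasc_s]) < 2)),
        "frac_neural_scaled_significant": float(np.mean(stats_scaled.t[neur_s] > 2)),
        "masks": masks,
    }


def mediation_battery(
    cohort: pd.DataFrame,
    vascular_score: np.ndarray,
    rsfa_loading: np.ndarray,
    neural_variability: np.ndarray,
    B: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
    covariates: tuple[str, ...] = ("gender", "handedness"),
) -> dict[str, mediation.MediationResult]:
    """The three standard mediation models on cohort summary measures.

    * Model 1: age -> vascular score -> RSFA loading;
    * Model 2: age -> neural (sensor) variability -> RSFA loading;
    * Model 3: age -> vascular score -> neural variability.
    """
    table = cohort.copy()
    table["vascular_score"] = np.asarray(vascular_score, dtype=float)
    table["rsfa_loading"] = np.asarray(rsfa_loading, dtype=float)
    table["neural_variability"] = np.asarray(neural_variability, dtype=float)
    covs = list(covariates)
    return {
        "model1_vascular_to_rsfa": mediation.mediate(
            table, "age", "vascular_score", "rsfa_loading", covs, B=B, alpha=alpha, seed=seed
        ),
        "model2_neural_to_rsfa": mediation.mediate(
            table, "age", "neural_variability", "rsfa_loading", covs, B=B, alpha=alpha,
            seed=seed + 1,
        ),
        "model3_vascular_to_neural": mediation.mediate(
            table, "age", "vascular_score", "neural_variability", covs, B=B, alpha=alpha,
            seed=seed + 2,
        ),
    }
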