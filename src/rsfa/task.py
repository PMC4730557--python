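"""Task activation estimation and haemodynamic (RSFA) scaling.

The BOLD response to a task confounds neural drive with vascular gain: the
same neural input produces a larger signal change in a person with more
reactive vasculature.  Scaling each participant's task beta by their RSFA
at the same voxel discounts the vascular gain, so group age effects that
survive scaling are more plausibly neural in origin.

This module fits a canonical-HRF GLM per voxel, divides betas by RSFA with
a stability floor, and runs mass-univariate group regressions of the
(scaled, unscaled, or scaled-minus-unscaled) maps on age with covariates,
with Bonferroni or permutation max-t family-wise error control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import compute_regressor
from scipy import stats

from .exceptions import DesignError, InsufficientDataError, InvalidConfigError, ShapeError
from .fluctuation import MOTION_COLUMNS, BoldRun, RsfaMap

EVENT_COLUMNS = ["onset_s", "duration_s", "condition"]


@dataclass
class BetaMap:
    """A 3D map of GLM parameter estimates for one condition."""

    values: np.ndarray
    condition: str
    scaled: bool = False
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ShapeError("beta mask shape does not match values")
        if not np.isfinite(self.values[self.mask]).all():
            raise ShapeError("non-finite beta values inside the mask")


@dataclass
class GroupStatMap:
    """Voxelwise group regression output for the age effect."""

    slope: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    correction: str = "none"
    threshold_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.threshold_mask is None:
            self.threshold_mask = np.zeros(self.slope.shape, dtype=bool)


def validate_events(events: pd.DataFrame, run_duration_s: float) -> pd.DataFrame:
    """Check an event table (columns onset_s, duration_s, condition) against a run."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InvalidConfigError(f"event table missing columns {missing}")
    if (events["onset_s"] < 0).any() or (events["duration_s"] < 0).any():
        raise InvalidConfigError("onsets and durations must be non-negative")
    if (events["onset_s"] >= run_duration_s).any():
        raise InvalidConfigError("event onset beyond the end of the run")
    return events


def task_regressor(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    condition: str | None = None,
) -> np.ndarray:
    """Canonical double-gamma HRF regressor sampled at the volume times.

    Uses the standard canonical shape (response peak near 6 s, undershoot
    near 16 s) convolved with the event stick/boxcar function.
    """
    frame_times = np.arange(n_volumes) * tr
    validate_events(events, n_volumes * tr)
    if condition is not None:
        events = events[events["condition"] == condition]
    if len(events) == 0:
        raise InvalidConfigError("no events for the requested condition")
    exp_condition = (
        events["onset_s"].to_numpy(float),
        events["duration_s"].to_numpy(float),
        np.ones(len(events)),
    )
    reg, _ = compute_regressor(exp_condition, "spm", frame_times)
    return reg[:, 0]


def fit_task_glm(
    run: BoldRun,
    events: pd.DataFrame,
    condition: str | None = None,
    include_motion: bool = True,
    drift_order: int = 2,
) -> BetaMap:
    """Per-voxel OLS beta for the task regressor.

    Design: intercept, polynomial drift terms up to ``drift_order`` (the
    low-order trend stands in for the usual slow-drift high-pass set at
    this scale), the 6 motion parameters as regressors of no interest
    (``include_motion``), and the canonical-HRF task regressor.  Restricted
    to the union of the tissue masks.
    """
    if len(events) < 3:
        raise InvalidConfigError("need at least 3 events to fit a task GLM")
    t = run.n_volumes
    reg = task_regressor(events, t, run.tr, condition)
    time = np.arange(t, dtype=float)
    linear = (time - time.mean()) / time.std()
    cols = [np.ones(t)]
    drift = linear.copy()
    for _ in range(max(drift_order, 0)):
        cols.append(drift.copy())
        drift = drift * linear
        drift -= drift.mean()
    if include_motion:
        mot = run.motion[MOTION_COLUMNS].to_numpy(float)
        mot = (mot - mot.mean(axis=0)) / (mot.std(axis=0) + 1e-12)
        cols.append(mot)
    cols.append(reg)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("task design is rank deficient")
    mask = run.gm_mask | run.wm_mask | run.csf_mask
    flat = run.data.reshape(-1, t)
    idx = np.flatnonzero(mask.reshape(-1))
    beta, *_ = np.linalg.lstsq(x, flat[idx].T, rcond=None)
    values = np.zeros(flat.shape[0])
    values[idx] = beta[-1]
    name = condition if condition is not None else str(events["condition"].iloc[0])
    return BetaMap(values.reshape(run.grid_shape), condition=name, scaled=False, mask=mask)


def scale_betas(beta: BetaMap, rsfa: RsfaMap, floor_quantile: float = 0.01) -> BetaMap:
    """Divide betas voxelwise by RSFA, excluding unstably small denominators.

    The floor is the ``floor_quantile`` quantile of in-mask RSFA (default
    the 1st percentile); voxels at or below the floor, or with zero RSFA,
    are dropped from the output mask rather than divided.
    """
    if beta.values.shape != rsfa.values.shape:
        raise ShapeError("beta and RSFA grids differ")
    mask = beta.mask & rsfa.mask
    in_mask = rsfa.values[mask]
    if in_mask.size == 0:
        raise ShapeError("empty joint mask")
    floor = np.quantile(in_mask[in_mask > 0], floor_quantile) if (in_mask > 0).any() else 0.0
    ok = mask & (rsfa.values > 0) & (rsfa.values >= floor)
    values = np.zeros_like(beta.values)
    values[ok] = beta.values[ok] / rsfa.values[ok]
    return BetaMap(values, condition=beta.condition, scaled=True, mask=ok)


def _stack_maps(maps: list[BetaMap]) -> tuple[np.ndarray, np.ndarray]:
    """Participants x voxels matrix over the intersection mask."""
    if len(maps) == 0:
        raise InvalidConfigError("no maps supplied")
    mask = maps[0].mask.copy()
    for m in maps[1:]:
        if m.values.shape != maps[0].values.shape:
            raise ShapeError("maps on different grids")
        mask &= m.mask
    data = np.stack([m.values[mask] for m in maps], axis=0)
    return data, mask


def _age_design(cohort: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise InvalidConfigError(f"cohort table missing covariates {missing}")
    cols = [np.ones(len(cohort)), cohort["age"].to_numpy(float)]
    cols += [cohort[c].to_numpy(float) for c in covariates]
    return np.column_stack(cols)


def _mass_ols_age_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized per-voxel OLS; returns (slope, t) for column 1 of x and df."""
    n, k = x.shape
    df = n - k
    if df < 2:
        raise InsufficientDataError("too few participants for the group design")
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1], beta[1] / se, df


def group_age_regression(
    maps: list[BetaMap],
    cohort: pd.DataFrame,
    covariates: list[str] = (),
) -> GroupStatMap:
    """Mass-univariate OLS of participant maps on age (plus covariates)."""
    data, mask = _stack_maps(maps)
    if len(cohort) != data.shape[0]:
        raise ShapeError("cohort rows do not match number of maps")
    x = _age_design(cohort, list(covariates))
    slope_v, t_v, df = _mass_ols_age_t(x, data)
    p_v = 2 * stats.t.sf(np.abs(t_v), df)
    shape = maps[0].values.shape
    slope = np.zeros(shape)
    tmap = np.zeros(shape)
    pmap = np.ones(shape)
    slope[mask], tmap[mask], pmap[mask] = slope_v, t_v, p_v
    return GroupStatMap(slope=slope, t=tmap, p=pmap, df=df)


def contrast_scaled_unscaled(
    scaled: list[BetaMap],
    unscaled: list[BetaMap],
    cohort: pd.DataFrame,
    covariates: list[str] = (),
    correction: str = "max_t_permutation",
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GroupStatMap:
    """Age regression on per-participant (scaled - unscaled) difference maps.

    Scaled and unscaled maps live on different units (a ratio vs a raw
    beta), so each set is z-scored across participants per voxel before
    differencing.  ``correction`` is ``bonferroni`` or ``max_t_permutation``
    (age labels permuted, null distribution of the maximum |t|).
    """
    if len(scaled) != len(unscaled):
        raise ShapeError("scaled and unscaled lists must pair up per participant")
    s_data, s_mask = _stack_maps(scaled)
    u_data, u_mask = _stack_maps(unscaled)
    if s_data.shape[1:] and scaled[0].values.shape != unscaled[0].values.shape:
        raise ShapeError("scaled and unscaled grids differ")
    mask = s_mask & u_mask
    shape = scaled[0].values.shape
    s_data = np.stack([m.values[mask] for m in scaled], axis=0)
    u_data = np.stack([m.values[mask] for m in unscaled], axis=0)

    def _zscore(d: np.ndarray) -> np.ndarray:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (d - d.mean(axis=0)) / sd

    diff = _zscore(s_data) - _zscore(u_data)
    x = _age_design(cohort, list(covariates))
    slope_v, t_v, df = _mass_ols_age_t(x, diff)
    p_v = 2 * stats.t.sf(np.abs(t_v), df)

    if correction == "bonferroni":
        sig = p_v < alpha / max(diff.shape[1], 1)
    elif correction == "max_t_permutation":
        rng = np.random.default_rng(seed)
        max_t = np.empty(n_permutations)
        xp = x.copy()
        for i in range(n_permutations):
            xp[:, 1] = rng.permutation(x[:, 1])
            _, t_perm, _ = _mass_ols_age_t(xp, diff)
            max_t[i] = np.abs(t_perm).max()
        thresh = np.quantile(max_t, 1 - alpha)
        sig = np.abs(t_v) >= thresh
    else:
        raise InvalidConfigError(f"unknown correction '{correction}'")

    slope = np.zeros(shape)
    tmap = np.zeros(shape)
    pmap = np.ones(shape)
    sigmask = np.zeros(shape, dtype=bool)
    slope[mask], tmap[mask], pmap[mask], sigmask[mask] = slope_v, t_v, p_v, sig
    return GroupStatMap(
        slope=slope, t=tmap, p=pmap, df=df, correction=correction, threshold_mask=sigmask
    )
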