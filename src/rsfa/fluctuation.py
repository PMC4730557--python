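"""Resting-state fluctuation amplitude (RSFA) from 4D BOLD runs.

RSFA is the voxelwise standard deviation of the resting BOLD time series
after nuisance cleaning and band-pass filtering to 0.01-0.08 Hz.  It is a
practical proxy for cerebrovascular reactivity: the amplitude of slow BOLD
fluctuations is dominated by vascular gain rather than neural activity, so
dividing task responses by RSFA discounts vascular differences between
people (see :mod:`rsfa.task`).

Pipeline per voxel:

1. regress out a 17-column nuisance design (intercept, linear and quadratic
   trends, mean white-matter and CSF signals, 6 motion parameters and their
   first differences);
2. zero-phase 4th-order Butterworth band-pass of the residual;
3. SD over time (n-1 denominator).

The nuisance regression runs before the filter; the order is configurable
through :func:`clean_and_filter` because the literature debates it, but the
default matches the order the steps are listed above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, InsufficientDataError, ShapeError
from .filters import bandpass_filtfilt

DEFAULT_BAND = (0.01, 0.08)
MIN_VOLUMES = 50

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class BoldRun:
    """A 4D BOLD acquisition with tissue masks and a motion table.

    ``data`` is (x, y, z, t) in arbitrary signal units; ``motion`` is a
    t-row table of 3 translations (mm) and 3 rotations (rad).
    """

    data: np.ndarray
    tr: float
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    motion: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ShapeError(f"BOLD data must be 4D, got {self.data.ndim}D")
        grid = self.data.shape[:3]
        for name in ("gm_mask", "wm_mask", "csf_mask"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != grid:
                raise ShapeError(f"{name} shape {mask.shape} does not match grid {grid}")
            setattr(self, name, mask)
        if (self.gm_mask & self.wm_mask).any() or (self.gm_mask & self.csf_mask).any() or (
            self.wm_mask & self.csf_mask
        ).any():
            raise ShapeError("tissue masks must be disjoint")
        if len(self.motion) != self.n_volumes:
            raise ShapeError(
                f"motion table has {len(self.motion)} rows for {self.n_volumes} volumes"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class NuisanceDesign:
    """A t x k nuisance regressor matrix with per-column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ShapeError("design matrix and labels disagree")


@dataclass
class RsfaMap:
    """Voxelwise fluctuation amplitude (SD units of the input signal)."""

    values: np.ndarray
    band: tuple[float, float]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ShapeError("RSFA mask shape does not match values")


def build_nuisance(run: BoldRun) -> NuisanceDesign:
    """Assemble the 17-column nuisance design for a run.

    Columns: intercept, linear trend, quadratic trend, mean WM signal, mean
    CSF signal, the 6 motion parameters, and their first differences
    (zero-padded at the first sample).  Zero-variance and near-collinear
    columns (pairwise |r| > 0.999) are pruned with a warning; the intercept
    is always kept.
    """
    t = run.n_volumes
    if not run.wm_mask.any():
        raise DesignError("white-matter mask is empty")
    if not run.csf_mask.any():
        raise DesignError("CSF mask is empty")

    time = np.arange(t, dtype=float)
    linear = (time - time.mean()) / (time.std() or 1.0)
    quadratic = linear**2 - (linear**2).mean()

    flat = run.data.reshape(-1, t)
    wm_mean = flat[run.wm_mask.reshape(-1)].mean(axis=0)
    csf_mean = flat[run.csf_mask.reshape(-1)].mean(axis=0)

    motion = run.motion[MOTION_COLUMNS].to_numpy(dtype=float)
    dmotion = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])

    columns = [np.ones(t), linear, quadratic, wm_mean, csf_mean]
    labels = ["intercept", "trend_linear", "trend_quadratic", "wm_mean", "csf_mean"]
    for i, name in enumerate(MOTION_COLUMNS):
        columns.append(motion[:, i])
        labels.append(name)
    for i, name in enumerate(MOTION_COLUMNS):
        columns.append(dmotion[:, i])
        labels.append(f"d_{name}")

    matrix = np.column_stack(columns)
    return _prune_design(NuisanceDesign(matrix, labels))


def _prune_design(design: NuisanceDesign, r_thresh: float = 0.999) -> NuisanceDesign:
    """Drop zero-variance (non-intercept) and near-collinear columns."""
    x = design.matrix
    keep = np.ones(x.shape[1], dtype=bool)
    sd = x.std(axis=0)
    for j in range(x.shape[1]):
        if design.labels[j] != "intercept" and sd[j] == 0:
            keep[j] = False
    kept_idx = [j for j in range(x.shape[1]) if keep[j]]
    # pairwise correlation pruning: keep the earlier column
    for pos, j in enumerate(kept_idx):
        if not keep[j] or sd[j] == 0:
            continue
        for k in kept_idx[pos + 1 :]:
            if not keep[k] or sd[k] == 0:
                continue
            r = np.corrcoef(x[:, j], x[:, k])[0, 1]
            if abs(r) > r_thresh:
                keep[k] = False
    if not keep.all():
        dropped = [design.labels[j] for j in range(x.shape[1]) if not keep[j]]
        warnings.warn(
            f"pruned degenerate nuisance columns: {dropped}", RuntimeWarning, stacklevel=3
        )
    return NuisanceDesign(x[:, keep], [lab for lab, k in zip(design.labels, keep) if k])


def clean_and_filter(
    series: np.ndarray,
    design: NuisanceDesign,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
    filter_first: bool = False,
) -> np.ndarray:
    """Nuisance-clean then band-pass one or many time series.

    ``series`` is (t,) or (t, n_series).  The OLS residual on ``design`` is
    taken first (guaranteeing orthogonality to every design column), then a
    zero-phase Butterworth band-pass; ``filter_first=True`` swaps the order.
    Output has the same shape and length as the input.
    """
    x = design.matrix
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if y.shape[0] != x.shape[0]:
        raise ShapeError(f"series length {y.shape[0]} does not match design {x.shape[0]}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("nuisance design is rank deficient after pruning")
    fs = 1.0 / tr

    def _residual(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(x, v, rcond=None)
        return v - x @ beta

    if filter_first:
        out = _residual(bandpass_filtfilt(y, band[0], band[1], fs, axis=0))
    else:
        out = bandpass_filtfilt(_residual(y), band[0], band[1], fs, axis=0)
    return out[:, 0] if squeeze else out


def compute_rsfa(
    run: BoldRun,
    band: tuple[float, float] = DEFAULT_BAND,
    design: NuisanceDesign | None = None,
) -> RsfaMap:
    """Voxelwise RSFA map for a run.

    Voxels outside the union of the tissue masks are marked invalid and set
    to zero.  A custom ``design`` overrides :func:`build_nuisance`.
    """
    if run.n_volumes < MIN_VOLUMES:
        raise InsufficientDataError(
            f"need at least {MIN_VOLUMES} volumes for a stable RSFA, got {run.n_volumes}"
        )
    if design is None:
        design = build_nuisance(run)
    mask = run.gm_mask | run.wm_mask | run.csf_mask
    flat = run.data.reshape(-1, run.n_volumes)
    idx = np.flatnonzero(mask.reshape(-1))
    cleaned = clean_and_filter(flat[idx].T, design, run.tr, band)
    values = np.zeros(flat.shape[0])
    values[idx] = cleaned.std(axis=0, ddof=1)
    return RsfaMap(values.reshape(run.grid_shape), band=tuple(band), mask=mask)
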