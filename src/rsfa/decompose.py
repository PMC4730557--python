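"""Group decomposition of participants x features variability matrices.

A cohort's RSFA maps (participants x voxels) or band-SD matrices
(participants x channels) are factorized as ``X ~ mixing @ sources``:
``sources`` are spatial component maps and ``mixing`` holds per-participant
loadings, which downstream analyses relate to age and feed into mediation
models.  The model order is chosen by a minimum-description-length (MDL)
criterion on the eigenvalue spectrum, then FastICA (tanh contrast,
symmetric decorrelation) unmixes the top-K PCA subspace.

The observed vectors are the columns of X (one per feature), so the MDL
sample count is the number of features and the signal dimension is the
number of participants — the convention of group spatial ICA, where voxels
play the role of samples.

Determinism: components are ordered by explained variance, each source map
is sign-oriented to positive skewness, and mixing columns are z-scored, so
repeated runs with one seed are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .exceptions import ConvergenceError, InsufficientDataError, ShapeError


@dataclass
class ComponentModel:
    """Mixing (participants x K, z-scored columns) and sources (K x features)."""

    mixing: np.ndarray
    sources: np.ndarray
    order: int
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mixing.shape[1] != self.order or self.sources.shape[0] != self.order:
            raise ShapeError("mixing/sources shapes disagree with the model order")


def _eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the participant-space covariance.

    Rows (participants) are centred across features; the covariance is that
    of the feature-indexed observation vectors.
    """
    x = np.asarray(matrix, dtype=float)
    n, m = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / m
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    return np.maximum(eigvals, 0.0)


def mdl_order(matrix: np.ndarray, k_max: int | None = None) -> int:
    """Model order minimizing the MDL cost over candidate orders.

    For each candidate k the description length is the negative
    log-likelihood of the model "k structured components + isotropic
    Gaussian residual" plus half the free-parameter count times log of the
    sample count.  The cost depends only on eigenvalue ratios and the two
    covariance orientations share their non-zero spectrum, so the smaller
    matrix side serves as the model dimension and the larger as the sample
    count.  Degenerate spectra raise.
    """
    x = np.asarray(matrix, dtype=float)
    n, m = x.shape
    if n < 6:
        raise InsufficientDataError("need at least 6 participants for order selection")
    eigvals = _eigenvalues(x)
    # the MDL cost is scale-invariant and the two covariance orientations
    # share their non-zero spectrum, so use the smaller side as the model
    # dimension and the larger as the sample count (centering costs one
    # rank along the feature axis)
    p = min(n, m - 1)
    n_samples = max(n, m)
    eigvals = eigvals[:p]
    if eigvals[0] <= 0:
        raise InsufficientDataError("degenerate covariance: no positive eigenvalues")
    k_cap = p - 1 if k_max is None else min(k_max, p - 1)

    floor = eigvals[0] * 1e-12
    lam = np.maximum(eigvals, floor)
    costs = np.empty(k_cap + 1)
    for k in range(k_cap + 1):
        tail = lam[k:]
        geo = np.exp(np.mean(np.log(tail)))
        arith = np.mean(tail)
        loglik = -n_samples * (p - k) * np.log(geo / arith)
        n_free = k * (2 * p - k) + 1
        costs[k] = loglik + 0.5 * n_free * np.log(n_samples)
    return max(int(np.argmin(costs)), 1)


def ica_decompose(
    matrix: np.ndarray,
    order: int | None = None,
    seed: int = 0,
    max_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ComponentModel:
    """FastICA of a participants x features matrix in the top-K PCA subspace.

    ``order=None`` chooses K by :func:`mdl_order`.  Non-convergence triggers
    reseeded restarts; persistent failure raises with diagnostics.
    """
    x = np.asarray(matrix, dtype=float)
    if order is None:
        order = mdl_order(x)
    if order > min(x.shape) - 1:
        raise ShapeError(
            f"order {order} exceeds min(participants, features) - 1 = {min(x.shape) - 1}"
        )
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        ica = FastICA(
            n_components=order,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            tol=tol,
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                # samples = features, dimensions = participants
                sources_t = ica.fit_transform(x.T)  # features x K
            except ConvergenceWarning as err:  # noqa: PERF203
                last_err = err
                continue
        mixing = ica.mixing_  # participants x K
        sources = sources_t.T  # K x features
        return _canonicalize(mixing, sources, order, seed)
    raise ConvergenceError(
        f"FastICA did not converge in {max_restarts} restarts "
        f"(order={order}, tol={tol}, max_iter={max_iter}): {last_err}"
    )


def pca_decompose(matrix: np.ndarray, order: int, seed: int = 0) -> ComponentModel:
    """PCA factorization with the same canonical form as the ICA path."""
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    mixing = u[:, :order] * s[:order]
    sources = vt[:order]
    return _canonicalize(mixing, sources, order, seed, method="pca")


def _canonicalize(
    mixing: np.ndarray, sources: np.ndarray, order: int, seed: int, method: str = "ica"
) -> ComponentModel:
    """Explained-variance ordering, positive source skewness, z-scored mixing."""
    explained = (mixing**2).sum(axis=0) * (sources**2).sum(axis=1)
    idx = np.argsort(explained)[::-1]
    mixing, sources = mixing[:, idx], sources[idx]
    flip = np.where(stats.skew(sources, axis=1) < 0, -1.0, 1.0)
    mixing = mixing * flip
    sources = sources * flip[:, None]
    mu = mixing.mean(axis=0)
    sd = mixing.std(axis=0)
    sd[sd == 0] = 1.0
    mixing = (mixing - mu) / sd
    return ComponentModel(mixing=mixing, sources=sources, order=order, method=method, seed=seed)


def loading_age_stats(model: ComponentModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each component's loadings with age.

    Returns a table with one row per component: ``component, r, p``.
    """
    if len(cohort) != model.mixing.shape[0]:
        raise ShapeError("cohort rows do not match mixing rows")
    age = cohort["age"].to_numpy(float)
    rows = []
    for k in range(model.order):
        r, p = stats.pearsonr(model.mixing[:, k], age)
        rows.append({"component": k, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
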