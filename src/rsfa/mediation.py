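"""Three-variable mediation path analysis with bias-corrected bootstrap CIs.

The question: does a mediator M (e.g. a cardiac vascular-health score)
account for the association between an independent variable IV (age) and a
dependent variable DV (an RSFA component loading)?  Three OLS regressions,
all including the same covariates (by default gender and handedness):

* ``M  = i1 + a*IV  (+ covariates)``           -> path a
* ``DV = i2 + c*IV  (+ covariates)``           -> total effect c
* ``DV = i3 + b*M + c'*IV (+ covariates)``     -> paths b and c' (direct)

The indirect effect is ``ab = a*b``; with identical covariates across the
three fits the OLS identity ``ab = c - c'`` holds to machine precision.
All variables are z-scored first so every coefficient is a standardized
beta.

Inference on every path uses the bias-corrected (BC) percentile bootstrap:
participants are resampled with replacement B times (default 10,000), the
paths refit per draw, and the CI endpoints are the bootstrap quantiles at
``Phi(2*z0 +/- z_{1-alpha/2})`` where ``z0 = Phi^{-1}(fraction of bootstrap
estimates below the point estimate)`` corrects median bias.  Significance
means the CI (default 99%) excludes zero.  An effect is classified as
mediation when the indirect path is significant, |c'| < |c| and ab shares
c's sign; as suppression when |c'| > |c| (controlling the mediator
*strengthens* the direct effect).  The effect size reported is the
proportion mediated, ``100*|ab/c|`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import (
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidConfigError,
    ShapeError,
)

PATH_NAMES = ("a", "b", "c", "c_prime", "ab")

#: Alpha grid used to report a CI-based p-value per path.
ALPHA_GRID = (0.05, 0.01, 0.001)


@dataclass
class MediationInput:
    """Aligned per-participant IV, mediator, DV and covariate columns."""

    iv: np.ndarray
    mediator: np.ndarray
    dv: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.iv = np.asarray(self.iv, dtype=float)
        self.mediator = np.asarray(self.mediator, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        n = len(self.iv)
        if len(self.mediator) != n or len(self.dv) != n:
            raise ShapeError("iv, mediator, dv must have equal lengths")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ShapeError("covariate rows must match participants")
        for name in ("iv", "mediator", "dv"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise InvalidConfigError(f"{name} contains missing or non-finite values")
            if np.ptp(arr) == 0:
                raise DegenerateSeriesError(f"{name} is constant")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        iv: str,
        mediator: str,
        dv: str,
        covariates: list[str] = (),
    ) -> "MediationInput":
        cov = table[list(covariates)].to_numpy(float) if covariates else None
        return cls(
            iv=table[iv].to_numpy(float),
            mediator=table[mediator].to_numpy(float),
            dv=table[dv].to_numpy(float),
            covariates=cov,
        )

    @property
    def n(self) -> int:
        return len(self.iv)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


@dataclass
class PathEstimate:
    beta: float
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan

    def excludes_zero(self) -> bool:
        return bool(self.ci_lo > 0 or self.ci_hi < 0)


@dataclass
class MediationResult:
    """Point estimates, bootstrap CIs and classification for one model."""

    paths: dict[str, PathEstimate]
    n: int
    B: int = 0
    alpha: float = 0.01
    seed: int | None = None
    classification: str = "none"
    proportion_mediated_pct: float = np.nan
    n_discarded_draws: int = 0
    extra: dict = field(default_factory=dict)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def _standardized_data(inp: MediationInput) -> np.ndarray:
    """Columns: iv, mediator, dv, then z-scored covariates."""
    cols = [_zscore(inp.iv), _zscore(inp.mediator), _zscore(inp.dv)]
    if inp.covariates is not None:
        for j in range(inp.covariates.shape[1]):
            col = inp.covariates[:, j]
            if np.ptp(col) == 0:
                raise DegenerateSeriesError(f"covariate column {j} is constant")
            cols.append(_zscore(col))
    return np.column_stack(cols)


def _paths_from_data(z: np.ndarray) -> dict[str, float]:
    """The three OLS fits on a standardized data matrix (see module docstring)."""
    n = z.shape[0]
    iv, m, dv, cov = z[:, 0], z[:, 1], z[:, 2], z[:, 3:]
    ones = np.ones(n)
    xa = np.column_stack([ones, iv, cov])
    xb = np.column_stack([ones, m, iv, cov])
    beta_m, *_ = np.linalg.lstsq(xa, m, rcond=None)
    beta_c, *_ = np.linalg.lstsq(xa, dv, rcond=None)
    beta_b, *_ = np.linalg.lstsq(xb, dv, rcond=None)
    a, c = beta_m[1], beta_c[1]
    b, c_prime = beta_b[1], beta_b[2]
    return {"a": a, "b": b, "c": c, "c_prime": c_prime, "ab": a * b}


def fit_paths(inp: MediationInput) -> dict[str, float]:
    """Standardized point estimates of paths a, b, c, c' and ab = a*b."""
    if inp.n < inp.n_covariates + 4:
        raise InsufficientDataError("too few participants for the path model")
    r = np.corrcoef(inp.iv, inp.mediator)[0, 1]
    if abs(r) > 0.999:
        raise DegenerateSeriesError("mediator is collinear with the IV")
    return _paths_from_data(_standardized_data(inp))


def _batched_paths(z: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Path estimates for each bootstrap index row.

    Returns (paths array of shape (B, 5) ordered as PATH_NAMES, valid mask).
    Draws in which iv, mediator or dv is constant are marked invalid.
    """
    B, n = idx.shape
    data = z[idx]  # (B, n, p)
    iv, m, dv = data[:, :, 0], data[:, :, 1], data[:, :, 2]
    cov = data[:, :, 3:]
    valid = (
        (np.ptp(iv, axis=1) > 0) & (np.ptp(m, axis=1) > 0) & (np.ptp(dv, axis=1) > 0)
    )
    ones = np.ones((B, n, 1))
    xa = np.concatenate([ones, iv[:, :, None], cov], axis=2)
    xb = np.concatenate([ones, m[:, :, None], iv[:, :, None], cov], axis=2)

    def _solve(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        g = np.einsum("bnk,bnl->bkl", x, x)
        h = np.einsum("bnk,bn->bk", x, y)
        # tiny jitter keeps singular (invalid-marked) draws from raising
        g = g + 1e-12 * np.eye(x.shape[2])
        return np.linalg.solve(g, h[..., None])[..., 0]

    beta_m = _solve(xa, m)
    beta_c = _solve(xa, dv)
    beta_b = _solve(xb, dv)
    a, c = beta_m[:, 1], beta_c[:, 1]
    b, c_prime = beta_b[:, 1], beta_b[:, 2]
    out = np.column_stack([a, b, c, c_prime, a * b])
    return out, valid


def _bc_interval(boot: np.ndarray, point: float, alpha: float) -> tuple[float, float]:
    """Bias-corrected percentile interval endpoints."""
    B = boot.size
    frac = np.count_nonzero(boot < point) / B
    frac = np.clip(frac, 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(frac)
    zc = norm.ppf(1 - alpha / 2)
    lo_q = norm.cdf(2 * z0 - zc)
    hi_q = norm.cdf(2 * z0 + zc)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


def bc_bootstrap_ci(
    inp: MediationInput,
    B: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    chunk: int = 2000,
) -> MediationResult:
    """Bias-corrected bootstrap mediation analysis.

    Whole participant rows (iv, mediator, dv, covariates) are resampled
    with replacement.  The per-path p is the smallest alpha on a fixed grid
    (0.05, 0.01, 0.001) at which the BC interval excludes zero (1.0 when
    none does) — inference here is CI-based, not Wald.
    """
    if inp.n < 20:
        raise InsufficientDataError("bootstrap mediation needs at least 20 participants")
    if not 0 < alpha < 1:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    point = fit_paths(inp)
    z = _standardized_data(inp)
    rng = np.random.default_rng(seed)

    boots = np.empty((B, len(PATH_NAMES)))
    valid = np.empty(B, dtype=bool)
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        idx = rng.integers(0, inp.n, size=(stop - start, inp.n))
        boots[start:stop], valid[start:stop] = _batched_paths(z, idx)
    n_bad = int(B - valid.sum())
    if n_bad > 0.01 * B:
        raise DegenerateSeriesError(
            f"{n_bad}/{B} bootstrap draws had a constant variable"
        )
    boots = boots[valid]

    paths: dict[str, PathEstimate] = {}
    for j, name in enumerate(PATH_NAMES):
        col = boots[:, j]
        se = float(col.std(ddof=1))
        ci_lo, ci_hi = _bc_interval(col, point[name], alpha)
        p_val = 1.0
        for a_grid in sorted(ALPHA_GRID, reverse=True):
            lo, hi = _bc_interval(col, point[name], a_grid)
            if lo > 0 or hi < 0:
                p_val = a_grid
        paths[name] = PathEstimate(
            beta=float(point[name]),
            se=se,
            z=float(point[name] / se) if se > 0 else np.nan,
            p=p_val,
            ci_lo=ci_lo,
            ci_hi=ci_hi,
        )

    result = MediationResult(
        paths=paths,
        n=inp.n,
        B=B,
        alpha=alpha,
        seed=seed,
        n_discarded_draws=n_bad,
    )
    result.classification = classify_effect(result)
    if point["c"] != 0:
        result.proportion_mediated_pct = proportion_mediated(point["ab"], point["c"])
    return result


def proportion_mediated(ab: float, c: float) -> float:
    """Effect size of the indirect path: ``100 * |ab / c|`` percent.

    Display convention is the nearest integer percent; the exact value is
    returned.
    """
    if c == 0:
        raise InvalidConfigError("proportion mediated is undefined when c = 0")
    return 100.0 * abs(ab / c)


def classify_effect(result: MediationResult) -> str:
    """Mediation vs suppression vs no indirect effect.

    ``mediation``: the ab CI excludes zero, the direct effect shrank
    (|c'| < |c|) and ab shares the sign of c.  ``suppression``: the ab CI
    excludes zero but the direct effect grew (|c'| > |c|) — the mediator
    was masking part of the IV-DV association.
    """
    ab = result.paths["ab"]
    c = result.paths["c"].beta
    c_prime = result.paths["c_prime"].beta
    if not ab.excludes_zero():
        return "none"
    if abs(c_prime) < abs(c) and np.sign(ab.beta) == np.sign(c):
        return "mediation"
    if abs(c_prime) > abs(c):
        return "suppression"
    return "none"


def mediate(
    table: pd.DataFrame,
    iv: str,
    mediator: str,
    dv: str,
    covariates: list[str] = (),
    B: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> MediationResult:
    """Convenience wrapper: column names in, :class:`MediationResult` out."""
    inp = MediationInput.from_table(table, iv, mediator, dv, covariates)
    return bc_bootstrap_ci(inp, B=B, alpha=alpha, seed=seed)
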