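"""Cohort-level generation: ages, covariates, and latent vascular/neural factors.

A cohort is a plain :class:`pandas.DataFrame` with one row per participant
and columns

``participant_id, age, gender, handedness, V, N``

where ``V`` is the latent vascular gain (drives BOLD fluctuation amplitude
and heart-rate variability) and ``N`` the latent neural amplitude (drives
band-limited sensor variability and the neural part of task responses).
Both are linear in age plus Gaussian noise, truncated strictly positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import InvalidConfigError
from .config import GeneratorConfig

COHORT_COLUMNS = ["participant_id", "age", "gender", "handedness", "V", "N"]


def _truncated_linear(
    rng: np.random.Generator,
    age: np.ndarray,
    intercept: float,
    slope: float,
    noise_sd: float,
    floor: float,
) -> np.ndarray:
    values = intercept + slope * age + rng.normal(0.0, noise_sd, size=age.shape)
    return np.maximum(values, floor)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table from ``config``.

    Ages are uniform over ``config.age_range`` (the emulated lifespan sample
    is close to uniform across age deciles); gender is a balanced binary
    indicator; handedness is a laterality score in [-100, 100] drawn from a
    right-dominant mixture.  Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    age = rng.uniform(*config.age_range, size=n)
    gender = rng.integers(0, 2, size=n)

    # ~85% right-handers clustered near +75, the rest left-leaning
    right = rng.random(n) < 0.85
    handedness = np.where(
        right,
        rng.normal(75.0, 15.0, size=n),
        rng.normal(-40.0, 30.0, size=n),
    )
    handedness = np.clip(handedness, -100.0, 100.0)

    v = _truncated_linear(
        rng, age, config.v_intercept, config.age_slope_v, config.v_noise_sd, config.latent_floor
    )
    n_lat = _truncated_linear(
        rng, age, config.n_intercept, config.age_slope_n, config.n_noise_sd, config.latent_floor
    )

    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age,
            "gender": gender.astype(int),
            "handedness": handedness,
            "V": v,
            "N": n_lat,
        }
    )


def simulate_mediation_dataset(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    seed: int | np.random.Generator = 0,
    with_covariates: bool = True,
) -> pd.DataFrame:
    """Generate a three-variable chain with known standardized path coefficients.

    ``iv ~ N(0,1)``; ``m = a*iv + e1`` with ``Var(e1) = 1 - a**2``;
    ``dv = b*m + c_prime*iv + e2`` with the residual variance chosen so that
    ``dv`` has unit variance.  The population standardized paths are then
    exactly ``a``, ``b``, ``c' = c_prime`` and the indirect effect ``a*b``.
    Independent binary gender and continuous handedness covariates are
    appended (they carry no signal) so the fitting surface matches the
    cohort-analysis one.
    """
    if abs(a) >= 1:
        raise InvalidConfigError("|a| must be < 1 for a standardized chain")
    dv_signal_var = b**2 + c_prime**2 + 2 * a * b * c_prime
    if dv_signal_var >= 1:
        raise InvalidConfigError("(b, c') imply dv variance above 1; shrink the paths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iv = rng.standard_normal(n)
    m = a * iv + np.sqrt(1 - a**2) * rng.standard_normal(n)
    dv = b * m + c_prime * iv + np.sqrt(1 - dv_signal_var) * rng.standard_normal(n)
    out = pd.DataFrame({"iv": iv, "m": m, "dv": dv})
    if with_covariates:
        out["gender"] = rng.integers(0, 2, size=n)
        out["handedness"] = rng.uniform(-100, 100, size=n)
    return out
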