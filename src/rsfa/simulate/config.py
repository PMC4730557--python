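"""Configuration for the synthetic study generator.

The generator emulates a cross-sectional adult-lifespan cohort in which a
latent vascular gain ``V`` declines with age and drives both resting BOLD
fluctuation amplitude and cardiac variability, while an independent latent
neural amplitude ``N`` drives band-limited sensor variability and the
neural part of task responses.  Every tunable lives here so that a whole
study (cohort table, resting/task BOLD runs, physiological waveforms,
multichannel sensor runs) is reproducible from one config and one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..bands import SENSOR_BANDS
from ..exceptions import InvalidConfigError

#: BOLD fluctuation band (Hz) used both for generation and analysis.
BOLD_BAND: tuple[float, float] = (0.01, 0.08)

#: Region label codes for the synthetic voxel grid.
REGION_NULL = 0
REGION_VASCULAR = 1
REGION_NEURAL = 2
REGION_WM = 3
REGION_CSF = 4


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    Latent model
    ------------
    ``V = v_intercept + age_slope_v * age + eps`` (truncated at
    ``latent_floor``), and likewise ``N`` with ``age_slope_n``.  The
    defaults put the age-V correlation near -0.5 and the age-N correlation
    near +0.45, moderate cross-sectional effects for a lifespan sample.
    Band-specific neural age slopes modulate the sensor variability of each
    band around the shared ``N``.
    """

    n_participants: int = 335
    seed: int = 0
    age_range: tuple[float, float] = (18.0, 88.0)

    # latent vascular gain V
    v_intercept: float = 1.5
    age_slope_v: float = -0.005
    v_noise_sd: float = 0.175

    # latent neural amplitude N
    n_intercept: float = 0.85
    age_slope_n: float = 0.003
    n_noise_sd: float = 0.12

    # per-band multiplicative age modulation of sensor variability,
    # applied on top of N (per year, centred on the mid-range age)
    age_slope_n_by_band: dict[str, float] = field(
        default_factory=lambda: {
            "subdelta": 0.004,
            "delta": 0.0,
            "theta": 0.0,
            "alpha": 0.004,
            "beta": 0.004,
            "gamma": 0.0,
        }
    )

    latent_floor: float = 0.05

    # BOLD grid
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_volumes: int = 250
    tr: float = 1.97

    # resting BOLD signal composition (signal units)
    rest_fluct_sd: float = 1.0          # band-limited SD per unit V
    neural_rest_coupling: float = 0.3   # weight of (N-1) in neural-region rest SD
    drift_linear_sd: float = 1.0        # SD of random linear drift coefficient
    drift_quad_sd: float = 0.5
    motion_coupling_sd: float = 0.2
    white_noise_sd: float = 0.2
    nuisance_sd: float = 1.0            # shared WM/CSF signal SD

    # task
    task_amplitude: float = 3.0         # percent-signal-like units per unit N*V
    task_noise_sd: float = 0.2
    task_soa: float = 1.97 * 2          # stimulus onset asynchrony, s
    event_duration: float = 1.0

    # physiology
    physio_fs: float = 50.0
    physio_duration: float = 300.0
    base_hr_bpm: float = 75.0
    hr_per_v: float = -15.0             # bpm change per unit V above 1.25
    lf_frac_per_v: float = 0.04         # fractional LF IBI modulation per unit V
    hf_frac_per_v: float = 0.03
    lf_hz: float = 0.10
    hf_hz: float = 0.25
    ibi_outlier_rate: float = 0.02
    ibi_outlier_frac: float = 0.4       # ectopic displacement, fraction of local IBI
    pulse_width_s: float = 0.05

    # sensors
    n_channels: int = 32
    sensor_fs: float = 200.0
    sensor_duration: float = 120.0
    sensor_base_sd: float = 1.0
    pattern_gain: float = 0.6           # strength of the two planted spatial patterns

    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 4:
            raise InvalidConfigError("n_participants must be at least 4")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidConfigError("age_range must be increasing")
        for name in ("tr", "physio_fs", "sensor_fs", "physio_duration", "sensor_duration"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.physio_duration < 120.0:
            raise InvalidConfigError("physio_duration must be at least 120 s for HRV work")
        if self.ibi_outlier_rate < 0 or self.ibi_outlier_rate >= 1:
            raise InvalidConfigError("ibi_outlier_rate must lie in [0, 1)")
        highest_edge = max(hi for _, hi in SENSOR_BANDS.values())
        if self.sensor_fs <= 2 * highest_edge:
            raise InvalidConfigError(
                f"sensor_fs must exceed twice the highest band edge ({highest_edge} Hz)"
            )
        return self
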