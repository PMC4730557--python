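"""Band-limited sensor variability and artifact-component flagging.

Per-channel SD of the band-passed signal is the sensor-space analogue of
RSFA, computed for six standard bands (infra-slow through gamma).  The
artifact flagger marks ICA components whose time courses correlate with
reference (EOG/ECG-style) channels beyond 3 SD of all such correlations.
"""

import numpy as np

from rsfa.bands import SENSOR_BANDS, all_band_sd, flag_artifact_components, grand_mean_variability
from rsfa.simulate import GeneratorConfig, generate_cohort, simulate_sensors

config = GeneratorConfig(n_participants=4, seed=3, n_channels=24, sensor_duration=100.0)
cohort = generate_cohort(config)
run = simulate_sensors(cohort.iloc[0], config)
print(f"sensor run: {run.data.shape[0]} channels x {run.data.shape[1]} samples "
      f"@ {run.fs:.0f} Hz")

sds = all_band_sd(run)
print("\nband           grand-mean SD over channels")
for name in SENSOR_BANDS:
    print(f"  {name:9s}  {grand_mean_variability(sds[name]):.3f}")

# artifact flagging demo: one of 30 components is a noisy copy of the
# reference (the SD-based threshold needs a realistic component count)
rng = np.random.default_rng(0)
components = rng.standard_normal((30, 5000))
eog_like = components[2] + 0.2 * rng.standard_normal(5000)
flags = flag_artifact_components(components, eog_like[None, :])
print(f"\nflagged components (planted artifact is #2): {np.flatnonzero(flags)}")
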