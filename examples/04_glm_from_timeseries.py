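"""First-level GLM: simulated raw runs -> per-concept beta patterns.

Generates event-related time series (HRF-convolved concept responses +
low-frequency drift + white noise), fits the run-wise GLM (concept
regressors, temporal derivatives, 128 s DCT high-pass, intercept), and
shows that the fitted betas recover the generative patterns.
"""

import dataclasses

import numpy as np

import semdecode as sd
from semdecode import glm

geom = sd.VolumeGeometry.isotropic((8, 8, 8), 3.0)
region = sd.cuboid_region(geom, (1, 1, 1), (7, 7, 7), "shared_semantic", amplitude=1.0)
cfg = sd.SimulationConfig(
    n_subjects=1, tasks=("reading",), n_runs=2, n_concepts=4,
    presentations_per_run=4, effect_regions=(region,), noise_sd=0.0,
    timeseries_noise_sd=0.3, drift_sd=1.0, n_scans_per_run=100, seed=13,
)
ts = sd.generate_timeseries(cfg, geom, subjects=[0])
fitted = glm.fit_dataset(ts)
truth = sd.generate_beta_dataset(dataclasses.replace(cfg, noise_sd=0.0), geom)

events = ts.events[(0, "reading", "L1", 0)]
print(f"trials per run:       {len(events)}")
print(f"scans per run:        {cfg.n_scans_per_run}")
r = np.corrcoef(fitted.betas.ravel(), truth.betas.ravel())[0, 1]
print(f"beta recovery r:      {r:.3f}")
rmse = np.sqrt(np.mean((fitted.betas - truth.betas) ** 2))
print(f"beta recovery RMSE:   {rmse:.3f}")
# With modest scanner noise the fitted betas correlate ~0.9+ with the
# generative amplitudes; with timeseries_noise_sd=0 recovery is exact.
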