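"""Simulate a bilingual dataset and run the cross-language searchlight.

Builds a small two-subject dataset with a shared-semantic region (the
same concept patterns in both languages) and a language-specific control
region, then decodes concepts across languages with a radius-3 searchlight.
High accuracy inside the shared region and chance (~10%) elsewhere shows
that only language-independent structure transfers.
"""

import numpy as np

import semdecode as sd

geom = sd.VolumeGeometry.isotropic((20, 20, 20), voxel_size_mm=3.0)
shared = sd.cuboid_region(geom, (3, 3, 3), (8, 8, 8), "shared_semantic",
                          amplitude=1.5, name="shared")
control = sd.cuboid_region(geom, (13, 13, 13), (18, 18, 18), "language_specific",
                           amplitude=1.5, name="control")
cfg = sd.SimulationConfig(
    n_subjects=2, tasks=("reading",), n_runs=5, n_concepts=10,
    effect_regions=(shared, control), noise_sd=1.0, seed=7,
)
dataset = sd.generate_beta_dataset(cfg, geom)

scheme = sd.make_cross_language_scheme("reading")
amap = sd.run_searchlight(dataset, subject=0, scheme=scheme)

print(f"chance level:              {1 / cfg.n_concepts:.2f}")
print(f"shared-region accuracy:    {np.nanmean(amap.data[shared.mask]):.2f}")
print(f"control-region accuracy:   {np.nanmean(amap.data[control.mask]):.2f}")
print(f"background accuracy:       "
      f"{np.nanmean(amap.data[~shared.mask & ~control.mask]):.2f}")
# The shared-semantic region decodes far above the 0.10 chance level;
# the language-specific region does not transfer across languages.
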