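"""ROI decoding with the permutation + bootstrap group null and FDR.

Decodes one ROI covering an implanted shared-semantic region and one
empty control ROI, builds each ROI's group-level chance distribution
(label permutations within runs, then bootstrap resampling of subject
chance accuracies), and FDR-corrects the two p-values.
"""

import semdecode as sd

geom = sd.VolumeGeometry.isotropic((14, 14, 14), 3.0)
region = sd.cuboid_region(geom, (2, 2, 2), (7, 7, 7), "shared_semantic",
                          amplitude=1.5, name="implant")
cfg = sd.SimulationConfig(
    n_subjects=6, tasks=("reading",), effect_regions=(region,), noise_sd=1.0, seed=33,
)
dataset = sd.generate_beta_dataset(cfg, geom)
scheme = sd.make_cross_language_scheme("reading")

# world-mm centres: one inside the implanted region, one far from it
inside = geom.voxel_to_world([4, 4, 4])[0]
outside = geom.voxel_to_world([11, 11, 11])[0]
rois = [
    sd.ROISpec(name="implanted", center_mm=tuple(inside), radius_mm=8.0),
    sd.ROISpec(name="empty", center_mm=tuple(outside), radius_mm=8.0),
]

results = [
    sd.permutation_bootstrap_p(dataset, roi, scheme, P=50, B=2000, seed=4)
    for roi in rois
]
table = sd.roi_table(rois, {"cross_language:reading": results})
print(table[["region", "observed_accuracy", "p", "significant_fdr"]].to_string(index=False))
print(f"null mean (chance): {results[0].null.group_means.mean():.3f}")
# The implanted ROI decodes near ceiling with a minimal p-value; the
# empty ROI sits at the ~0.10 chance level and is not significant.
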