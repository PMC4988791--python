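"""Render a synthetic multimodal phantom cohort with known ground truth.

Builds the default near-spherical "nucleus" phantom (0.5 mm grid, a relative
T2*-like modality and an absolute susceptibility-like modality), simulates a
small two-group cohort with a planted -10% volume effect in the elderly
group, and prints the true per-group volumes from the manifest.
"""

import meshseg as ms

spec = ms.default_spec(seed=0)
subjects, manifest = ms.generate_cohort(
    spec, {"young": 10, "elderly": 10},
    volume_effect={"elderly": -0.10}, seed=42)

print(manifest[["subject_id", "group", "nucleus_true_volume_mm3"]])
group_means = manifest.groupby("group")["nucleus_true_volume_mm3"].mean()
print("\ngroup mean true volumes (mm^3):")
print(group_means)
print("\nThe elderly mean sits below the young mean by roughly the planted "
      "10% (per-subject jitter adds ~9% volume noise, so small cohorts "
      "scatter around that); every parameter above is recorded in the "
      "manifest, and re-rendering with the same seeds reproduces the "
      "volumes bit-for-bit.")
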