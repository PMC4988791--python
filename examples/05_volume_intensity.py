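"""Volume-versus-intensity regression across a simulated cohort.

Iron accumulation brightens susceptibility maps and darkens T2*-weighted
images; if segmentation volume tracks image contrast rather than anatomy,
volume and intensity correlate. This example plants such a coupling in the
generator and recovers it with the per-group OLS regression.
"""

import numpy as np

import meshseg as ms

rng = np.random.default_rng(5)
records = []
i = 0
for group, intensity_shift in [("young", 0.00), ("middle-aged", 0.02),
                               ("elderly", 0.04)]:
    for _ in range(12):
        qsm_inside = 0.12 + intensity_shift + rng.normal(0, 0.01)
        # planted coupling: +0.01 susceptibility ~ +8 mm^3 volume
        volume = 320.0 + 800.0 * (qsm_inside - 0.12) + rng.normal(0, 4.0)
        records.append(ms.SubjectRecord(
            subject_id=f"sub-{i:03d}", group=group,
            volumes={"nucleus": volume},
            intensities={("nucleus", "qsm"): qsm_inside}))
        i += 1

table = ms.group_intensity_regression(records, "nucleus", "qsm")
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nThe pooled slope should recover ~800 mm^3 per susceptibility unit "
      "(flagged significant); per-group slopes are noisier because each "
      "group spans a narrower intensity range.")
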