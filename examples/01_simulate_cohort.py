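"""Generate a small synthetic two-class cohort and inspect its structure.

Each patient has four co-registered MRI sequences, a reference tumor mask,
and 2 readers x 2 sessions of repeated segmentations with boundary jitter.
"""

from itertools import combinations

import numpy as np

from wavemics import CohortConfig, generate_cohort

cfg = CohortConfig(
    n_patients=8,
    volume_shape=(12, 16, 16),
    tumor_radius_range_per_class={1: (3.5, 5.5), 0: (2.5, 4.5)},
    reader_jitter=0.15,
    seed=7,
)
cases = generate_cohort(cfg)

print(f"{len(cases)} patients, labels:", [c.label for c in cases])
for case in cases[:3]:
    dices = [
        2 * np.logical_and(a.voxels, b.voxels).sum() / (a.voxels.sum() + b.voxels.sum())
        for a, b in combinations(case.masks.values(), 2)
    ]
    print(
        f"{case.patient_id}: class {case.label}, "
        f"{case.reference_mask.n_voxels} tumor voxels, "
        f"pairwise segmentation Dice {min(dices):.3f}-{max(dices):.3f}"
    )

# Dice stays >= 0.8 by construction: the repeated masks emulate realistic
# reader variability without destroying the lesion.
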