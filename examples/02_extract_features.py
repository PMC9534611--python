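"""Extract the 107 features per sequence (428 per patient) from one case.

Volumes are resampled to 1 mm isotropic, in-mask intensities discretized
with bin width 64, then shape / first-order / GLCM / GLRLM / GLSZM / GLDM /
NGTDM statistics are computed.
"""

from wavemics import CohortConfig, extract_all, generate_cohort

cases = generate_cohort(
    CohortConfig(n_patients=4, volume_shape=(12, 16, 16),
                 tumor_radius_range_per_class={1: (3.5, 5.5), 0: (2.5, 4.5)},
                 seed=3)
)
row = extract_all(cases[0])

print(f"feature row length: {len(row)} (4 sequences x 107)")
for name in (
    "T1W_shape_Sphericity",
    "T1W_firstorder_Mean",
    "T1W_glcm_Contrast",
    "T2W_glrlm_RunPercentage",
    "T1C_glszm_ZonePercentage",
    "FLAIR_ngtdm_Coarseness",
):
    print(f"  {name:32s} {row[name]:10.4f}")

# Sphericity near 1 reflects the ellipsoidal synthetic lesion; the texture
# statistics quantify the gray-level heterogeneity planted inside the ROI.
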