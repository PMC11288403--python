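"""Run one BraTS-shaped phantom volume through the preprocessing chain.

mask -> fixed crop around the tumor centroid -> block-mean downscale by 2
-> pad the last axis to square slices -> per-volume min-max to [0, 1].
"""

import spottune3d as st

spec = st.CohortSpec.small(n_total=1, shape=(155, 240, 240), seed=0)
cohort = st.generate_cohort(spec)
pid = cohort.records[0].patient_id

vol = st.MRVolume(cohort.volume(pid, "T1"), (1, 1, 1), "T1", pid)
mask = st.SegmentationMask(cohort.mask(pid))

masked = st.apply_mask(vol, mask)
cropped = st.crop_to_tumor(masked, mask, (140, 172, 164))
down = st.downscale(cropped, 2)
padded = st.pad_square_slices(down, 86)
final = st.minmax_normalize(padded)

print(f"input:      {vol.shape} at {vol.spacing_mm} mm")
print(f"cropped:    {cropped.shape}")
print(f"downscaled: {down.shape} at {down.spacing_mm} mm")
print(f"padded:     {padded.shape}")
print(f"normalized: range [{final.voxels.min():.1f}, {final.voxels.max():.1f}]")
print()
print("The printed geometry (155×240×240 → 140×172×164 → 70×86×82 → "
      "70×86×86) is the fixed pipeline every modality goes through.")
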