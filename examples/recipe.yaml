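# Cohort recipe for `lggspat simulate --recipe recipe.yaml`.
# Every key is optional; omitted keys fall back to the defaults shown here
# (lggspat.synthetic.DEFAULT_RECIPE), which emulate a typical low-grade
# glioma malignant-transformation cohort.

shape: [96, 96, 96]          # voxel grid
spacing: [2.0, 2.0, 2.0]     # mm per voxel

# preoperative tumor: volume log-uniform (ml), mild random anisotropy
preop_volume_ml_range: [6.0, 150.0]
growth_factor: 1.15          # radial scale preop -> pre-transformation
center_jitter_mm: 4.0        # random offset of the tumor from grid center

# transformation foci: sphere volume log-uniform (ml)
focus_volume_ml_range: [0.3, 6.0]

# clinical mixture
category_probs: {local: 0.91, distant: 0.07, combined: 0.02}
p_second_focus_local: 0.264  # second focus for a local case (multifocal)
local_mode_probs: {inside: 0.70, rim: 0.15, near: 0.15}
near_distance_mm_range: [4.0, 16.0]   # local but non-overlapping foci
far_distance_mm_range: [24.0, 34.0]   # distant foci
local_threshold_mm: 20.0     # the 2-cm rule; near/far ranges must clear
                             # a +/- 2 mm band around it

# metadata frequencies
histology_probs:
  oligodendroglioma: 0.279
  astro_idh_mut: 0.372
  astro_idh_wt: 0.302
  lgg_nos: 0.047
p_resection: 0.488
p_chemo: 0.326
p_rt: 0.535
p_missing_preop: 0.163       # cases without digitized preoperative MRI
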