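"""Simulate a small synthetic DCE-MRI cohort and inspect its ground truth.

Benign foci enhance slowly and persistently; malignant foci show fast
wash-in followed by wash-out.  Each case is five aligned 3D volumes
(T0 unenhanced, T1-T4 enhanced, 60 s apart) plus a binary lesion mask.
"""

import numpy as np

import focusradiomics as fr

cfg = fr.CohortConfig(n_benign=3, n_malignant=3, seed=7)
cohort = fr.generate_cohort(cfg)

print(f"{len(cohort)} cases, volume {cfg.volume_shape}, "
      f"spacing {cfg.voxel_spacing} mm\n")
for case in cohort:
    curve = np.asarray(case.truth["enhancement_curve"])
    mean_t = [case.series.data[t][case.mask.data].mean() for t in range(5)]
    print(f"{case.case_id} ({case.label:9s}): "
          f"mask {int(case.mask.data.sum()):3d} voxels, "
          f"enhancement e(t) = {np.round(curve, 2)}, "
          f"masked mean = {np.round(mean_t, 1)}")

print("\nMalignant curves peak early then decay (wash-out); benign curves "
      "keep rising.\nThe masked mean follows baseline*(1+e(t)) plus noise — "
      "this kinetic contrast is what the\ndownstream classifier must find.")
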