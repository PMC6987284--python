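"""Inject per-slice affine motion into a case and recover it by registration.

Each slice of T1-T4 is moved by a random 2D affine (translation up to 2 px
plus a small rotation/shear); the registration module then re-aligns every
slice to T0 by minimising the mean-square intensity difference.
"""

import numpy as np

import focusradiomics as fr
from focusradiomics.affine import center_displacement

cfg = fr.CohortConfig(n_benign=1, n_malignant=1, volume_shape=(8, 48, 48),
                      seed=3)
case = fr.generate_case(fr.MALIGNANT, cfg, np.random.default_rng(3))
moved = fr.inject_motion(case, amplitude=2.0, rng=np.random.default_rng(4))

registered, transforms = fr.register_series(moved.series)

errors = [center_displacement(moved.truth["motion"][ti][z].inverse(),
                              transforms[ti][z], (48, 48))
          for ti in range(4) for z in range(8)]
residual = np.abs(registered.data[1:] - case.series.data[1:]).mean()
before = np.abs(moved.series.data[1:] - case.series.data[1:]).mean()

print(f"32 slices registered (4 time-points x 8 slices)")
print(f"median translation-recovery error: {np.median(errors):.3f} px "
      f"(max {np.max(errors):.3f} px)")
print(f"mean |difference| to the unmoved series: {before:.2f} before, "
      f"{residual:.2f} after registration")
print("\nThe error is the distance, at the slice centre, between the true "
      "inverse motion and\nthe recovered transform — sub-0.3 px means the "
      "texture matrices downstream see\nessentially motion-free data.")
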