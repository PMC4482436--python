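"""Generate a synthetic cardiac phantom case with a known deformation.

Builds a 64^3 six-structure phantom (AO, LV, LVM, LA, RV, RA), draws a
random 8 mm B-spline warp, and prints the per-structure voxel counts and
the ground-truth landmark displacement statistics.  The landmark pairs
satisfy p_m = T_true(p_f) exactly, so they later serve as the gold
standard for registration accuracy.
"""
import numpy as np

import shapereg as sr

spec = sr.PhantomSpec(seed=0)
case = sr.make_case(spec, warp_magnitude=8.0, warp_grid_spacing=24.0, seed=0)

print("structure  voxels  mean intensity")
for name, code in sr.CARDIAC_LABELS.items():
    m = case.fixed_labels.mask(code)
    print(f"{name:>9}  {int(m.sum()):6d}  {case.fixed.data[m].mean():8.1f}")

disp = np.linalg.norm(case.true_pairs.p_m - case.true_pairs.p_f, axis=1)
print(f"\n{len(case.true_pairs)} landmark pairs from five surfaces (LV excluded)")
print(f"ground-truth displacement: mean {disp.mean():.2f} mm, max {disp.max():.2f} mm")
print("penalty at the true transform:",
      sr.penalty(case.true_pairs, case.true_transform).value, "(exact zero)")
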