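# shapereg

Shape-regularized multifeature nonrigid registration and mean-intensity
atlas construction for 3-D cardiac CT.

Cardiac atlases — a mean image of a population with a reference
segmentation — need every subject registered accurately into one space,
but chamber boundaries in CT are often ambiguous: neighbouring blood
pools share the same intensity, so purely intensity-driven registration
underdetermines the deformation exactly where anatomy matters most.
`shapereg` addresses this for researchers building volumetric cardiac
atlases (and anyone registering multi-structure volumes with
segmentations available) by combining two ingredients in one cost:

- a **multifeature similarity**: alpha-mutual information estimated from
  k-nearest-neighbour graphs over per-voxel feature vectors
  z = (L, g'g, g'Hg, g'HHg, tr H, tr HH, tr HHH, theta, phi) built from
  Gaussian derivatives at scales sigma = 1, 2 (d = 17 channels,
  z-scored), where theta = arccos(v3/r) and phi are the gradient
  orientation angles;
- a **shape-consistency penalty**: sparse surface landmarks
  {(p_f_i, p_m_i)} extracted from the fixed segmentation by marching
  cubes + 96% mesh decimation and propagated through a kappa-statistic
  registration of the binary masks, penalizing
  C_P = (1/N) sum_i ||p_m_i − T_mu(p_f_i)||.

The registration minimizes C = −C_alphaMI + omega·C_P (omega = 0.05 by
default) over the coefficients mu of a cubic B-spline free-form
deformation T(x) = T_global(x) + T_local(x) (affine initialization by
intensity MI, then FFD refinement), using decaying-gain stochastic
gradient descent a/(A+k+1)^tau over a smoothing-only multiresolution
pyramid. Both cost terms have analytic gradients. Everything is testable
without patient data through a synthetic multi-chamber phantom with known
ground-truth deformations. See `docs/methods.md` for the full model.

## Worked example

`examples/03_register_phantom.py` hides an 8 mm random B-spline warp in a
64^3 six-chamber phantom and recovers it with a reduced 2-level schedule
(about a minute on one CPU):

```
$ python examples/03_register_phantom.py
  affine MI init: translation [ 1.394  0.44  -0.164]
  level 0: sigma=2.0, grid=32.0mm, d=17, nodes=(8, 8, 8)
  level 0: auto gain a=33.24
  level 1: sigma=1.0, grid=16.0mm, d=17, nodes=(15, 15, 15)
  level 1: auto gain a=112.6
  total time 74.1s

mean landmark residual: 2.57 mm -> 0.37 mm (ratio 0.143; < 0.4 counts as a good recovery)

Dice per structure (before -> after registration):
structure  label  dice_before  dice_after
       AO      1     0.565014    0.962433
       LV      2     0.776369    0.961719
      LVM      3     0.578382    0.922846
       LA      4     0.820927    0.957156
       RV      5     0.688509    0.959396
       RA      6     0.707782    0.968026
```

The residual ratio says the registration removed ~86% of the hidden
deformation at the ground-truth landmarks; the Dice rows show every
structure's overlap improving once the moving segmentation is warped by
the estimated transform. The other examples demonstrate the phantom
generator, the alpha-MI metric on its own, the shape-correspondence
pipeline, and atlas construction with Wilcoxon comparison of methods.

A thin CLI wraps the same pipelines:

```bash
shapereg phantom --size 64 --seed 0 --out case/
shapereg register --fixed case/fixed.mha --moving case/moving.mha \
    --fixed-seg case/fixed_labels.mha --moving-seg case/moving_labels.mha \
    --config cfg.txt --out out/
shapereg evaluate --fixed-seg case/fixed_labels.mha \
    --moving-seg case/moving_labels.mha --transform out/transform.txt \
    --out dice.csv
```

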