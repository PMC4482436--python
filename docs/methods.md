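# Methods

## Problem and model

`shapereg` registers a moving 3-D cardiac CT volume M to a fixed volume F
by estimating a spatial mapping T from fixed-image to moving-image world
coordinates (mm), then uses that machinery to build a mean-intensity
atlas of a population. The transform is a combination

    T(x) = A(x) + u(A(x))

of an affine map `A(x) = matrix (x - center) + center + translation` and
a free-form deformation (FFD) `u`, a displacement field parameterized by
a regular lattice of control-point vectors interpolated with
tensor-product cubic B-splines. The affine part is fitted once by a
dense histogram mutual information of intensities (32 bins) and then
frozen; the FFD coefficients mu are the free parameters of the nonrigid
optimization. Because the notation "T_global + T_local" leaves open
whether the local term is evaluated at x or at A(x), both conventions are
implemented (`compose_at_affine`); the default evaluates the FFD at the
affine-mapped point, matching a sequential affine-then-nonrigid pipeline.
The control lattice always extends at least one node beyond every face of
the fixed-image domain so the cubic support is complete everywhere, and
the zero lattice is exactly the identity displacement.

## Similarity: multifeature alpha-mutual information

Instead of an intensity histogram MI, alignment is scored by a
mutual-information generalization estimated from k-nearest-neighbour
graphs over feature vectors. Each voxel carries d features: the raw
intensity L; at each Gaussian scale sigma in {1, 2} (voxel units) the six
rotation-invariant Cartesian combinations of the gradient g and Hessian H
(g'g, g'Hg, g'HHg, tr H, tr HH, tr HHH); and the gradient-orientation
angles theta = arccos(v3/r), phi = atan2(v1, v2). The default
configuration gives d = 17. Orientation captures boundary direction even
where gradient magnitude differs between subjects. The literal
arctan(v1/v2) is replaced by the full-quadrant arctangent to remove the
v2 = 0 singularity; when the in-plane gradient (or the whole gradient)
vanishes the angles are set to a sentinel 0 and the voxel is flagged
degenerate. All channels are z-scored (population statistics) over a
random sample of fixed-domain points, and the identical affine
normalization is applied to the moving stack so both images live in one
feature space. Channels that are constant over the sample are dropped
with a warning.

For N sample points with fixed features z^f_i, moving features
z^m_i = z^m(T(x_i)) and joint vectors z^fm_i = [z^f_i, z^m_i], each of the
three graphs contributes per-sample total neighbour distances
Gamma_i = sum over the k nearest neighbours of ||z_i - z_ip||, and

    alpha-MI = 1/(alpha-1) log [ 1/N^alpha sum_i
               (Gamma^fm_i / (Gamma^f_i Gamma^m_i))^(2 gamma) ],
    gamma = d (1 - alpha),  0 < alpha < 1.

Defaults k = 5, alpha = 0.99. The product denominator is implemented
literally; a related published estimator divides by sqrt(Gamma^f Gamma^m)
instead, and that variant is available via `denominator="sqrt_product"`
(default stays with the product form; at alpha close to 1 the exponent
2 gamma is small and the two differ little in practice). Distances and
graph sums are floored at epsilon = 1e-10 so coincident feature vectors
cannot produce division by zero or log of zero; the metric is finite for
all inputs. Neighbour search uses a kd-tree with leaf bucket size 50 and
an approximate-search error bound of 10 (interpreted as the epsilon slack
of the tree query); tests and oracles use the exact setting (bound 0),
where the tree search reproduces exhaustive search to 1e-12.

### Gradient

The analytic gradient with respect to mu freezes the kNN graph topology
(neighbour indices treated as locally constant — the standard treatment
for graph-based metric derivatives, since index changes occur on a
measure-zero set) and chains through three factors: the derivative of
each Euclidean edge length (unit difference vector), the spatial gradient
of the moving feature channels at the transformed points, and the sparse
B-spline Jacobian dT/dmu (64 support nodes per point, partition of
unity). Moving channels are interpolated with cubic B-splines
(prefiltered coefficients, mirror boundary) so the sampled values and
their analytic spatial gradients are mutually consistent; this is what
lets frozen-topology finite differences of the metric agree with the
analytic gradient to better than 1e-3 (observed ~1e-5). Samples whose
transformed point leaves the moving domain or the FFD support are dropped
from all three graphs for that evaluation. Fixed-stack features at
off-grid sample points use linear interpolation (they are data, not
functions of mu).

## Shape-consistency penalty

Sparse corresponding shape points {(p_f_i, p_m_i)} regularize the
registration through

    C_P = 1/N sum_i || p_m_i - T(p_f_i) ||,

with analytic derivative -1/N sum_i (unit residual) dT/dmu(p_f_i). At a
zero residual the norm has a cone point; pairs with residual below 1e-9 mm
contribute zero gradient (a subgradient choice). Affine parameters are
frozen, so no affine derivatives are needed.

Shape points come from the fixed segmentation: marching cubes triangulates
each structure's 0.5 iso-surface (the indicator is lightly smoothed,
sigma = 1 voxel, to suppress staircase artifacts that otherwise inflate
surface area by ~10%; tiny structures fall back to the raw indicator),
and the mesh is decimated by 96% with an error-driven half-edge collapse
under quadric error metrics. Collapses move a vertex onto a neighbour,
so every surviving landmark is an original surface node. The decimator is
implemented in-package (no VTK dependency) and hits the target node count
within a few percent. Landmarks are pooled from five surfaces — AO, LVM,
LA, RV, RA; the LV endocardium is excluded, matching the five-surface
convention — without per-structure weighting. They are propagated to the
moving image by a volumetric registration of the two binary foreground
masks driven by a kappa overlap statistic 2|A∩B|/(|A|+|B|): translation
initialized from mask centroids, then an FFD maximizes a differentiable
soft kappa over Gaussian-smoothed indicators on a coarse 3-level pyramid
(sigmas 4/2/1 voxels, grids 32/16/8 mm, 60 iterations, 3000 samples per
iteration by default). The best-seen parameters by hard kappa are kept,
so the returned transform never scores below its initialization.

## Cost and optimization

The registration minimizes

    C(mu) = -alpha-MI(mu) + omega C_P(mu),

with omega in [0.01, 0.1] when the shape term is enabled (omega = 0
disables it); the default omega = 0.05. Optimization is stochastic
gradient descent with the decaying gain a/(A + k + 1)^tau, A = 50,
tau = 0.6, run over a smoothing-only multiresolution pyramid: at each
level both volumes are Gaussian-smoothed (no downsampling, so moving-image
interpolation stays at full resolution), the feature stacks are rebuilt
from the smoothed images, and the control grid is refined. The full-scale
schedule is five levels with smoothing sigmas 16/8/4/2/1 voxels and grid
spacings 80/40/20/10/5 mm, 1000 iterations per level and N = 5000 fresh
uniform coordinate samples per iteration. When the grid spacing halves
between levels the coefficients are carried over by exact dyadic B-spline
knot insertion (the represented deformation is preserved to machine
precision); non-dyadic schedules fall back to sampling the previous
displacement at the new node sites, with a warning.

The gain numerator defaults to `a = "auto"`: at the start of each level,
a is calibrated so the first step's largest control-point update equals
`step0_mm` (default 0.5 mm), in the spirit of adaptive step-size
estimation for stochastic descent. A fixed constant (e.g. a = 2000, the
full-scale protocol value) can be set instead; at desk scale the
gradient magnitudes differ enough from the full-scale problem that a
fixed constant tuned for one size is wrong for the other, which is why
calibration is the default. Non-finite gradients skip the step with a
warning. With a fixed RNG seed the entire pipeline — affine
initialization (dense, deterministic), binary registration, sampling and
descent — is bit-reproducible.

## Atlas construction and evaluation

A designated reference subject defines the atlas space (reference
selection is an explicit input, not a heuristic). Every other image is
registered to it and resampled into the reference grid; the atlas
intensity image is the voxel-wise arithmetic mean including the reference
itself (so a population of one is well defined), and the atlas label
image is the reference segmentation. Failed registrations exclude that
subject with a warning. Registration quality is measured by the Dice
similarity coefficient per structure after warping the moving
segmentation into fixed space with nearest-neighbour interpolation, and
two methods are compared with a paired two-sided Wilcoxon signed-rank
test on corresponding Dice values (zero differences dropped; exact null
distribution for n <= 25; all-zero differences degenerate to p = 1 with a
warning), significance at p < 0.05.

## Synthetic phantom

The phantom emulates a contrast-enhanced cardiac CT at desk scale
(default 64^3 voxels at 1 mm): six disjoint structures in the AO, LV,
LVM, LA, RV, RA roles built from ellipsoids, with the LV/LA and RV/RA
chambers sharing flat interface planes and a myocardium-like shell
around the LV. Structures carry distinct mean intensities (blood pools
180-210, myocardium 120, background 40, arbitrary HU-like units), plus
smooth Gaussian-correlated texture (sigma 2 voxels, amplitude 10) so
gradient features are informative inside homogeneous regions, plus
additive white noise (sd 5). The texture belongs to the anatomy and is
warped with it; the white noise is applied after warping with independent
realizations in the fixed and moving images.

`make_case` draws FFD control-point displacements uniformly in
+-warp_magnitude (default 8 mm) on a 24 mm lattice — the same transform
family the registration estimates, on a coarser grid than the finest
registration level, so recovery is well-posed but not trivial. Draws
whose deformation folds (det(I + du/dx) <= 0 anywhere on a strided voxel
grid) are rejected, up to 10 attempts; the magnitude is required to stay
below half the warp grid spacing as a folding guard. The warped volume
plays the fixed image and the unwarped base the moving image, so the
drawn transform is exactly the fixed-to-moving mapping the registration
should recover: M(T_true(x)) = F(x), and surface landmarks satisfy
p_m = T_true(p_f) identically (making `penalty` exactly zero at the truth).
A `low_contrast_spec` variant sets the atria to their ventricles'
intensities and nearly removes the blood-pool texture, producing
interfaces invisible to any intensity-driven metric while the label maps
still separate them — the regime in which the shape term is expected to
help.

What the phantom does not emulate: real anatomical shape variability
(ellipsoid chambers, not hearts), CT physics (beam hardening, partial
volume, streak artifacts), intensity inhomogeneity between subjects, and
population-scale diversity. Passing the phantom experiments therefore
demonstrates correctness of the estimator, gradients and optimization
machinery and the qualitative benefit of shape regularization under
controlled ambiguity — not clinical-grade accuracy on patient data.

## Problem sizes and numerical choices

Experiments run on 64^3 phantoms with a reduced schedule (2 levels,
smoothing sigmas 2/1, grids 32/16 mm, 200 iterations, 2000 samples); the
shape-benefit experiment uses a single 16 mm level with 120 iterations
over 5 seeds. These sizes were chosen so the whole experiment suite runs
on one CPU in minutes while leaving the recovery problem genuinely
nonrigid (the 24 mm ground-truth warp cannot be represented by the
initial affine). Other fixed choices: interpolation is linear for
intensities and nearest-neighbour for labels, with out-of-domain fill 0
and an optional out-of-domain mask; sample points avoid a 2-voxel margin
at the fixed-image border; Gaussian derivative kernels use truncate = 6
so the discrete derivative kernels are near zero-sum (a constant image
yields derivatives ~1e-6 of its level rather than ~1e-4); distance and
graph floors at 1e-10; zero-residual penalty cutoff at 1e-9 mm.

## Known limitations

- No diffeomorphic guarantee or inverse-transform computation; the
  phantom generator rejects folded ground truths, but the estimated
  transform is unconstrained.
- The alpha-MI gradient ignores kNN topology changes between iterations
  (exact only piecewise); stochastic sampling makes this harmless in
  practice but the cost trace is noisy by construction.
- Landmark propagation quality is bounded by the binary-mask
  registration; no filtering of poorly propagated pairs is applied.
- The decimator targets node count and surface fidelity, not mesh
  quality; it may produce non-manifold patches on pathological inputs
  (irrelevant for landmark use).
- 4-D (time-resolved) data and DICOM series reading are out of scope;
  inputs are single-phase MetaImage/NIfTI volumes with axis-aligned
  direction cosines.
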