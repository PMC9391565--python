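# Methods

`prcrecon` models the positron-range (PR) blur of high-energy β⁺ emitters —
¹²⁴I throughout — inside the system matrix of iterative PET reconstruction,
and evaluates full versus simplified implementations of that correction with
the standard contrast-recovery / background-noise phantom protocol.  This
note records the model, its assumptions, the tunable parameters and their
defaults, the numerical choices, and what the synthetic experiments do and
do not establish.

## Reconstruction model

The system matrix is factorized as `A = W·X·H`:

* `X` — geometric projector.  A stacked-2D parallel-beam multi-slice
  geometry: `n_angles` views over [0, π), `n_radial` bins of `radial_spacing`
  mm per view, one sinogram plane per image slice.  Line integrals use exact
  per-voxel intersection lengths from a vectorized grid-crossing (Siddon-type)
  traversal; the per-plane system matrix is held sparse, and the
  back-projector is its literal transpose, so adjoint tests hold to float
  round-off.  A clinical scanner's 3D cylindrical TOF geometry is *not*
  modelled: the update equations are geometry-agnostic, and the parallel-beam
  choice keeps the projector analytic and the adjoint exact at desk scale.
  Time-of-flight weighting, scatter and randoms are out of scope (the update
  equations here, as in the protocol they implement, exclude them).
* `W` — per-LOR weights: attenuation survival factors `exp(−∫μ dl)`
  computed with the same ray tracer, times per-LOR efficiencies (1 by
  default: normalization is perfect in simulation).
* `H` — image-space resolution blur: the spatially variant PR kernel
  (below), optionally composed with a stationary isotropic Gaussian detector
  PSF (default FWHM 4.4 mm, a parametric stand-in for a measured detector
  response).  When both are active the forward order is PR first (the
  physics happens in tissue) then detector blur; the adjoint is applied in
  reverse.  The two operators nearly commute for smooth kernels; the order
  is configurable in code.

Six ordered-subsets EM variants run over this model: OSEM, PSF (detector
blur in `H`), and each with PRC in *simplified* form (PR blur applied to the
image estimate before forward projection only; back-projector and
sensitivity image unchanged) or *full* form (PR blur and its exact adjoint
in the forward step, back step and sensitivity image).  The simplified
scheme deliberately mismatches the forward and backward projectors; the
evaluation protocol measures the resulting noise amplification.

Defaults follow the protocol's working settings: 12 subsets, 10 iterations
(20 for PSF+PRC, which converges slowest), uniform positive initialization
inside the FOV cylinder, no post-reconstruction filtering.  The division
guard adds `ε = 1e−12·mean(m)` to projected denominators; at that size it
prevents 0/0 in cold regions without shifting converged values at the 1e−6
level probed by the fixed-point tests.  Voxels whose subset sensitivity is
below 1e−10 of its maximum are frozen at zero.

## Positron-range kernels

Uniform per-material kernels are Monte-Carlo'd with a deliberately simple
transport model (full condensed-history transport à la GEANT4 is out of
scope, and the sampler is pluggable):

1. a β⁺ branch is drawn from the isotope's tabulated branches — for ¹²⁴I,
   endpoints 1.535 MeV (11.7 %) and 2.138 MeV (10.6 %), daughter ¹²⁴Te;
2. the initial kinetic energy is drawn from the allowed β-spectrum shape
   `p·W·(Q−T)²` times the non-relativistic Coulomb (Fermi) factor for
   positrons, `2πη/(e^{2πη}−1)` with `η = Zα/β`.  The Coulomb factor is
   essential, not cosmetic: positron spectra are exponentially suppressed at
   low energy, and without that suppression the annihilation density
   acquires a scale-free ~r⁻² cusp at the emission point that makes the
   voxel-scale kernel width nearly material-independent;
3. energy converts to a path length via the Katz–Penfold extrapolated-range
   relation `R = 0.412·E^{1.265−0.0954 ln E}` g/cm², scaled by 1/ρ (mass
   density; electron-density differences between lung, water and bone are
   ignored — first-order physics that reproduces the density-driven
   lung ≫ water > bone ordering);
4. the net emission-to-annihilation displacement is a fixed tortuosity
   factor (0.8) of that path length, in an isotropic direction.  The factor
   absorbs path curvature and range straggling in one number; with it, the
   water kernel has a mean 3D displacement of ≈2.7 mm and a maximum of
   ≈8 mm, in the range reported for ¹²⁴I in water.

Displacements are binned into an 11×11×11 kernel at 2×2×2 mm voxels
(kernel extent matched to the maximum range in water; larger supports are
known to introduce artifacts).  Events outside the support are discarded and
the kernel renormalized; the discarded fraction is recorded (≈29 % for
lung, whose range distribution extends far beyond ±11 mm).  Because the
density enters only as a 1/ρ scale on an otherwise identical random stream,
matched seeds at two densities give displacement fields related by exactly
the density ratio — a property the tests assert.

**Spatially variant composition.**  The attenuation map is segmented into
lung / soft tissue / bone by HU intervals (boundaries −150 and +150 HU by
default, chosen to separate −800, 0 and +500/+1000 HU cleanly; air is
folded into lung).  The kernel at voxel `j` takes, at each offset `h`, the
uniform-kernel value of the material at the *destination* voxel `j+h`, then
renormalizes to unit sum; out-of-volume destinations clamp to the nearest
in-volume voxel.  This destination-lookup rule is an implementation
assumption (the literature's composition rule is not fully specified); it
is linear, reduces exactly to the uniform kernel in homogeneous regions,
and has a decisive computational property: the whole-volume blur factorizes
into one shift-invariant FFT convolution per material, gated by that
material's mask —

    (B f)[d] = Σ_m mask_m[d] · (K_m ∗ (f / norm))[d],
    norm[j]  = Σ_h K_{mat(j+h)}(h),

which the tests verify against a brute-force per-voxel composition.  The
blur spreads from the source voxel (emitted counts are conserved for
interior-supported images); at the volume edge the spread truncates and the
truncated mass is lost, mirroring out-of-field annihilations.  The exact
adjoint transposes each factor.

## HU → μ conversion

A bilinear map anchored at μ = 0 for air (−1000 HU) and
μ_water(511 keV) = 0.0096 mm⁻¹ at 0 HU, with slope 4.8×10⁻⁶ mm⁻¹ per HU
above water (the standard shallower bone segment of CT-based attenuation
conversion).  Monotone by construction.

## Digital phantoms

The body shell is a cylinder instead of the torso-shaped shell —
VOI analysis is unaffected and the geometry stays analytic.  The
image-quality phantom uses a 280 mm body: with the six co-planar spheres on
the standard 57.2 mm ring, twelve 37 mm background VOIs cannot sit in the
sphere plane of a 230 mm circle at ≥15 mm from both spheres and edge; the
real torso shell is 300 mm wide laterally, so the wider cylinder is the
faithful compromise.  The bone–lung phantom keeps a 230 mm body and places
its six 37 mm background VOIs on two rings at the angles midway between the
three 50 mm cylinders.

Spheres and cylinders are voxelized by fractional sub-voxel sampling
(3³ subsamples per voxel) so sub-voxel spheres (3.7 mm) carry
partial-volume-correct activity; `subsamples=1` degenerates to the binary
center-of-voxel rule, used when a ground-truth image must match the
voxel-center VOI membership rule exactly.  Sphere positions, ring radii and
background-VOI placement are deterministic and configurable (the reference
hardware's exact insert coordinates are not published, so nothing is
hard-coded beyond the ring layout).

Bone–lung specifics: cylinders are cold in activity (solid housing); the
two hot spheres per cylinder (8.5/19.4 mm, 30 kBq/ml) are water-filled
(HU 0) and sit on the cylinder axis at ±12 mm from the central plane.

## Evaluation protocol

Contrast recovery per sphere is `(mean_sphere / mean_background) /
activity_ratio`, with the background mean over the voxels of *all*
background VOIs pooled; background noise is `100·SD/mean` of that same
pooled set, using the population (÷n) standard deviation — the n vs n−1
choice is not pinned by the protocol and is irrelevant at thousands of
voxels, so it is fixed for determinism.  A per-VOI-then-average background
convention is available behind a flag-equivalent (pool the VOIs yourself).
VOI membership is voxel-center-inside-sphere.  Variants are compared at the
iteration whose noise is nearest the target (10 % for the 5:1 phantoms,
33 % for the small-tumor phantom), ties toward the lower iteration; a
variant is flagged unreachable when its noise stays more than 5 points
below the target.

Gibbs (edge) overshoot is the clipped percent excess of a line profile
through a sphere center over the true fill, within two radii of the center.
On a noisy image at the 10 % working point this max-based statistic is
dominated by voxel noise for *every* variant, so the experiment-level
overshoot comparison reconstructs the noiseless realization of the same
acquisition to each variant's matched iteration and profiles that —
isolating the systematic artifact the statistic is meant to capture.  (The
raw noisy-iterate variant remains available.)

## Scaled-down study conditions

Desk-scale sizes, fixed once:

| setting | IQ / small-tumor | bone–lung |
|---|---|---|
| grid | 160×160×24 @ 2 mm | 128×128×24 @ 2 mm |
| views × radial bins | 120 × 160 | 120 × 128 |
| subsets | 12 | 12 |
| total counts | 1.2×10⁸ / 1.2×10⁷ | 1.0×10⁸ |
| detector FWHM | 4.4 mm | 4.4 mm |
| kernel events | 2×10⁵ per material | 2×10⁵ |

Counts are calibrated so background noise lands near the protocol's working
points at the expected iteration numbers — OSEM reaches ~10 % at iteration
2, full PRC/PSF variants near iterations 7–17 (and ~33 % at iteration 2 for
the small-tumor fill).  With the calibrated counts the matched iterations
(2/2/7/10/9/17 across the six variants at seed 1) closely mirror the
working points of the measured protocol.

## What the synthetic experiments show — and what they do not

The acquisition simulator uses the same projector, attenuation and blur
operators as the reconstruction (an "inverse crime"), with Poisson noise as
the only corruption.  That is deliberate: the studies isolate the
*algorithmic* differences between PRC implementations — convergence speed,
the forward/backward mismatch noise signature, matched-noise contrast
orderings, material dependence, Gibbs overshoot — under a model where the
correct answer is known.  They do not establish absolute contrast-recovery
values for any real scanner: real acquisitions add TOF weighting, scatter,
randoms, detector normalization, a measured spatially variant PSF and
inter-crystal effects, none of which are modelled.  One visible consequence:
without TOF, full-PRC deconvolution of a two-voxel sphere inside the wide
lung kernel converges too slowly to show a gain at the matched 10 % noise
point in the OSEM pairing, while the PSF-coupled pairing reproduces the
expected lung ≫ bone pattern for both sphere sizes.

## Known limitations

* The transport sampler ignores positron energy loss across density
  interfaces during flight: each displacement is drawn for the *emission*
  voxel's material only, and heterogeneity enters solely through the
  per-offset destination-material composition.
* No magnetic-field deformation of the positron cloud (PET/MRI).
* The parallel-beam projector has no depth-of-interaction or crystal-pitch
  structure; the detector PSF is stationary and isotropic.
* Kernel support is capped at 11³ voxels; in lung ≈29 % of annihilations
  fall outside and are redistributed by renormalization.
* The composition rule's destination-material lookup is one of several
  defensible choices; alternatives (e.g. path-weighted mixing) would change
  interface behavior at the 1-voxel scale.
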