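# Methods

This note documents the models implemented in `y90pet`, the parameters that
matter, and what the synthetic experiments do and do not establish.

## Voxel grid and geometry conventions

All analysis runs on a single regular grid per case, by default the PET
reconstruction grid of 4.07 × 4.07 × 3 mm voxels. Voxel index `(i, j, k)`
maps to the physical *center* `origin + (i·dx, j·dy, k·dz)` in mm, and all
distances (ray lengths, surface distances) are between voxel centers.
Masks are rasterized by voxel-center inclusion; no fractional/partial-volume
masks are used, so a rasterized shape's volume differs from the analytic
volume by at most a boundary-shell worth of voxels (this bias is measured in
the tests, not hidden). Surface extraction uses 6-connectivity with the
grid border counting as outside. Images are stored as NIfTI-1 (NRRD is
accepted on read); masks as uint8 {0, 1}.

## Synthetic ⁹⁰Y-PET generator

The generator emulates *reconstructed* ⁹⁰Y PET images; it does not simulate
projections, randoms, scatter or TOF reconstruction, on the grounds that
the whole analysis operates on reconstructed images.

**Ground truth.** Piecewise-constant activity concentration: background
`c_b` inside a 1200 cm³ ellipsoidal liver, `c_b·TBR` inside each lesion's
perfused region, zero elsewhere. `c_b` is solved so that the total liver
activity equals the administered activity (3.0 GBq for the bench phantoms),
which fixes the absolute dose scale. Partial perfusion removes a random
half-space cut of the lesion from the uptake region; a necrotic core zeroes
a concentric ellipsoid of the given fractional radius. The morphologic
truth mask is always the full shape — anatomy does not see perfusion.

**Degradation.** A 5-mm FWHM isotropic Gaussian blur stands in for the
reconstruction point-spread function (total activity conserved to < 0.1%),
followed by zero-mean Gaussian noise with standard deviation proportional
to `sqrt(signal + floor)`, spatially correlated with a 1-voxel Gaussian
kernel, scaled so the realized coefficient of variation (CoV) in the warm
liver background hits a target, and clipped at zero. ⁹⁰Y PET noise level is
scanner- and count-dependent and is the one free knob of the generator: the
default background CoV of 0.25 was chosen once as representative of the
very noisy character of ⁹⁰Y PET relative to FDG. For the cold-background
phantom (no warm liver) the noise is calibrated to the level the lesion
would imply at TBR 5, matching the count level of the warm experiments.

**Phantom suite.** Three bench configurations on the PET grid: (a) a 60 cm³
hot sphere in a cold background, (b) the same sphere in the warm liver at
TBR 5:1, and (c) 8/16/29 cm³ lesions (two spheres and an ovoid) at TBRs
5.1/6.2/5.5. Lesions sit at deterministic positions on the liver's long
axis; only volumes, TBRs, blur and grid are physically constrained.

**Patient-like cohort.** Per patient: 1–9 lesions, volumes log-uniform on
2–818 cm³; large lesions become liver-proportional ellipsoids (a sphere of
that volume cannot fit in the liver); placement is rejection-sampled with a
one-voxel gap and unplaceable lesions are dropped. Each lesion is randomly
fully perfused (p = 0.5), partially perfused (p = 0.3, perfused fraction
0.3–1) or rim-only (p = 0.2, core fraction 0.3–0.7). Administered activity
is uniform on 0.6–5.8 GBq and lesion TBR uniform on 1.5–8, chosen so lesion
mean doses span roughly 15–800 Gy, exercising the BED nonlinearity.
Morphologic masks are re-rasterized after a per-lesion rigid translation
with per-axis Gaussian σ = 2 mm (default), emulating residual registration
error between the diagnostic scan and PET. The cohort does **not** model
respiratory motion, liver deformation, intra-lesion microsphere clustering
heterogeneity, or anatomy changes between scans — the main drivers of the
much lower patient-study concordance — so passing phantom bounds here shows
algorithmic fidelity, not clinical equivalence.

## Gradient-based segmentation

The commercial gradient tool this emulates is proprietary; the realization
here is defined by the package itself:

1. Smooth the image with a Gaussian of `smooth_sigma` voxels (default 0.5).
2. Cast `n_directions` (default 642, an icosahedron subdivided three times)
   near-uniform rays from the seed, sampled every `step` = 1 mm out to an
   octant-ellipsoid bound built from the six signed initialization rays
   times `margin` = 1.3.
3. Stop each ray at the most negative *outward directional derivative* —
   intensity falling away from the seed — rather than the gradient-magnitude
   maximum, which would lock onto interior heterogeneity. The minimum is
   refined to sub-step accuracy by a parabolic fit. Radii below `r_min`
   (default one voxel diagonal) are excluded; rays whose bound is shorter
   than `r_min` (thin lesions, seeds near the surface) shrink the exclusion
   proportionally, and rays with no falling edge retry over the full range
   before counting as failed. If ≥ 20% of rays fail the image is declared
   flat (degenerate input).
4. Regularize the radii with `regularization_iters` = 2 passes of
   neighbor-median smoothing on the icosphere mesh.
5. Re-initialize from the result — new seed at the star-convex surface's
   own centroid, new rays its axis extents — and repeat up to
   `refine_iters` = 3 times, stopping when seed and radii move < 0.05 mm.
6. Voxelize once by a center-inside test against the surface, with the
   radius interpolated from the three nearest directions; keep the
   component containing the seed and fill holes.

Two design points deserve emphasis. First, smoothing: the default of 0.5
voxel (≈ 2 mm in-plane) matches the σ of the 5-mm-FWHM reconstruction blur.
Heavier smoothing (1 voxel) measurably biases small lesions: tangential
averaging over a curved surface pulls the gradient maximum inward, costing
the 8 cm³ sphere ~25% of its volume. Second, the continuous-space
self-consistency loop (step 5): a single pass inherits the operator's seed
and ray choices, and with a 2-mm jittered initialization two realizations
agreed only at DSC ≈ 0.85–0.96; iterating to the fixed point makes the
contour essentially initialization-free (repeat DSC ≥ 0.997 on the phantom
suite) while leaving the detected edge — a property of the image — in
charge. The output is restricted to star-convex shapes about the final
seed; the lesion geometries studied here (including rims, which are
segmented as one filled VOI) satisfy this.

Edge location depends only on where intensity falls, so the segmentation is
exactly invariant to positive rescaling of the image — as is the
percent-of-max threshold comparator, whose optimal percent nonetheless
shifts with TBR (the classical failure mode the gradient method avoids).
For the threshold method the bounding region is a sphere of the mask's
equivalent radius plus 10 mm, and `optimal_threshold` scans 1–99% in 0.5%
steps, breaking ties toward the lower percent. Because rasterized volume is
piecewise-constant in the threshold, a plateau of percents can be equally
optimal; the tie-break makes the reported optimum the plateau's lower edge,
which is why the absolute optimal percents are lower than the analytic
half-rise values while their TBR *ordering* (warm > cold) is robust.

## Dosimetry

Local deposition: `D = C/ρ · Δ/λ`, with Δ = 0.9267 MeV per decay,
λ = ln 2 / 64.1 h and ρ = 1 g/mL (water phantom; 1.06 g/mL soft-tissue
option). Time integration is physical decay only — microspheres are
permanently trapped. Monte Carlo transport is out of scope; local
deposition is the standard desk approximation at PET resolution (≥ 5 mm),
which exceeds the ⁹⁰Y β range (mean ≈ 2.5 mm in tissue). The optional
radial-kernel convolution (`dose_kernel_convolve`) exists to bound the
effect of cross-voxel transport: the kernel table is resampled onto the
grid as `f(r)/(4πr²)` per voxel, the sub-grid remainder is assigned to the
center voxel, and the discrete kernel is renormalized so total energy is
conserved. In a uniform medium interior both methods agree by construction.

## DVH, BED and concordance metrics

Dq (q = 70, 90) is the empirical quantile of the voxel-dose sample at
probability 1 − q/100, with linear interpolation at plotting positions
(i−1)/(n−1); differences against nearest-bin conventions are sub-voxel.
BED applies the linear-quadratic model for permanent implants per voxel,
`BED = D + D²/(α/β)·λ/(λ+μ)` (α/β = 10 Gy, λ = 0.0108/h, μ = 0.462/h);
the mean BED is the mean of the per-voxel transform, while BED70/BED90 are
computed as `BED(Dq)` — the transform is monotone, so quantile equivariance
holds exactly instead of only up to interpolation. EUD (and EUBED on the
transformed sample) uses `−(1/α)·ln(mean exp(−α·D))` with α = 0.004/Gy; at
these dose levels and α the exponential is nearly linear, so EUD tracks the
mean closely (r > 0.98 on the default cohort).

DSC = 2|A∩B|/(|A|+|B|); two empty masks are defined as DSC 1 with a warning
so batch runs stay total. MDA is the *symmetric* mean surface distance
between boundary-voxel centers under anisotropic spacing (the directional
convention is not standardized; symmetry is this package's choice), and is
verified exactly against an O(n²) brute force on small masks.

## Cohort statistics

Lesions cluster within patients, so CIs come from a patient-level
bootstrap: clusters are resampled with replacement, the statistic is
recomputed on the pooled lesions, and the percentile 95% interval is
reported (n_boot = 2000 by default). The mean PS−MS difference with this CI
replaces a random-intercept mixed model; it protects against the same
within-patient correlation without a REML fit. Lin's ccc uses population
(divide-by-n) moments. "PS" in all correlation/agreement analyses is the
per-metric average of the two realizations. Known limitation: the
percentile cluster bootstrap under-covers with few clusters (≈ 87% empirical
coverage at 20 clusters in our checks); the calibration test therefore runs
in its asymptotic regime (100 clusters, 200 replicates, coverage ≈ 0.94).
Cohorts of ~15 patients should read the CIs as mildly anti-conservative.

## Problem sizes and determinism

The phantom suite runs on a 57 × 45 × 42 grid (≈ 108k voxels, ~1 s for the
full five-lesion pipeline); the default synthetic cohort uses 10 patients
(~20–30 lesions, ~20 s including bootstrap). One master seed drives
simulation, segmentation jitter and bootstrap; every run is bit-reproducible
given the seed, and `run`/`run-phantom-acceptance` write a manifest
(config hash, seed, version) next to their outputs.

## Exclusion rules

Lesions with morphologic volume < 2 cm³ (below PET resolution, and highly
sensitive to mis-registration) or morphologic mean AD < 5 Gy (no uptake)
are excluded before cohort statistics. Both rules evaluate on the
morphologic mask only, so exclusion is identical for both methods; an
excluded lesion is a valid, labeled result, not an error.
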