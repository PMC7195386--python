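# Methods

`emish3d` analyses 3D chromatin structures imaged by serial block-face
scanning electron microscopy after in-situ hybridization with silver-enhanced
detection.  The input is a registered z-stack of 2D sections with anisotropic
voxels (in-plane pixel 5–7 nm, section thickness 30–50 nm).  The output is,
per structure: a cleaned isotropic mask, a decomposition into morphological
sub-domains, morphometric measurements (volume, surface area, form factor,
principal-axis extents), and group-level statistics across sub-domain
classes.

## Segmentation front end

**Maximum-entropy threshold.**  The intensity cut maximizes the summed
Shannon entropies of the normalized sub-histograms below and above the cut
(Kapur–Sahoo–Wong), over a 256-bin histogram spanning [min, max].  Bins of
zero probability contribute nothing; ties between cuts resolve to the lowest
threshold.  Foreground is strictly above the cut.  A constant image has no
threshold and raises an error.

**Non-specific signal removal.**  Hybridization reactions produce punctate
background staining.  The specific signal, bound to the target chromatin, is
continuous across consecutive sections, whereas punctate noise is confined to
single sections.  Each 26-connected foreground component is therefore
classified by its z-extent (number of distinct sections touched): components
spanning at least `min_layers` sections are specific, the rest are
non-specific.  `min_layers` defaults to 2, the weakest reading of
"several consecutive sections"; it is exposed on the CLI.  The specific
(SP), non-specific (NS) and remaining background (BN) masks give the
specific-to-non-specific volume ratio vol(SP)/vol(NS) and the background
occupancy vol(NS)/(vol(NS)+vol(BN)); voxel volume cancels in both.

**Largest component.**  The target structure is the largest 26-connected
component among the specific components (never among removed noise).

**Isotropic resampling.**  Output voxel centres are laid on an exact
`target_nm` grid (default 5 nm) spanning the input's physical sample
positions; values are linearly interpolated at those physical positions, so
original plane values are reproduced exactly and axes already at target
spacing are untouched.  This handles non-integer pitch ratios (50/5, 50/7 …)
by physical-space interpolation rather than index arithmetic.  Only
upsampling is supported.

**Isotropic structure mask.**  The intensity threshold is re-applied on the
interpolated grid, restricted to the interpolation support of the raw
structure mask.  (Thresholding a linearly resampled *binary* mask at 0.5
occupancy can sever thin parts of the structure whose occupancy falls below
one half between coarse z-planes, while the interpolated intensity stays well
above threshold.)  The final component is selected with 6-connectivity,
because the diffusion stage transports mass across voxel faces: a
corner-attached island would never fill.

**Pixel-noise smoothing.**  A per-section 2D Gaussian of σ = 5 nm
(1 pixel at target spacing), reflective boundary.  The acquisition notes
describe this smoothing step in two places; it is implemented once, after
resampling.

## Sub-domain decomposition

**Smoothing.**  A grayscale maximum filter with a cubic structuring element
of edge `round(135 nm / voxel)` (forced odd; 27 voxels at 5 nm) is applied to
the intensity masked to the structure.  135 nm is the scale that removes
fine-grain density variation without erasing lobe-scale morphology; a radius
interpretation of the cutoff is available via a flag.

**Seeding.**  Local density centres are the regional maxima (26-connected
plateaus not exceeded by any neighbour) of the smoothed density inside the
mask.  Each plateau contributes its centroid, snapped into the mask.  Maxima
closer than `min_separation_nm` (default: half the smoothing cutoff) merge
into the denser one — a safety net against plateau fragmentation by noise.
Seeds are ordered by descending density, ties by lexicographic coordinate,
making the decomposition fully deterministic.

**Seeded diffusion.**  One diffusion equation per seed,
∂u_i/∂t = ∇·(D(r) ∇u_i), is integrated with the image density as a
position-dependent diffusion coefficient.  D is the intensity divided by its
in-mask maximum, so D ∈ (0, 1] strictly inside the structure (a min–max
normalization would zero the least dense voxel and could stall transport
through it).  D is taken state-independent: the operational description of
the method uses the local image density as the coefficient.  Each u_i starts
as a unit-mass Gaussian (σ = 10 nm, two voxels: approximating "all signal
concentrated at the seed" without a delta-function grid artifact) truncated
to the mask and renormalized.

The integrator is an explicit conservative finite-volume scheme assembled as
a sparse matrix over mask voxels: face diffusivity is the arithmetic mean of
the adjacent voxel densities, faces across the mask border carry no flux
(zero-flux boundary, so mass cannot leak), and dt = 0.9 h²/(6 max D)
satisfies the 3D explicit stability bound, making the update monotone
(u ≥ 0 preserved) and mass-conserving to round-off.  Diffusion runs on the
*original* intensities; the max-filtered density is a seeding device only
(a flag switches D to the smoothed field).  Integration stops once every
mask voxel's total field mass exceeds `eps` (default 1e-12 of the unit seed
mass) plus one settling sweep; a step cap (default 10⁶) guards against
non-convergence and reports the number of unfilled voxels.

**Labeling and classification.**  Every mask voxel joins the sub-domain whose
field is largest there (ties to the lowest seed index).  The morphological
class is min(n_domains, 4): five-domain structures are rare and pooled with
the four-domain group for statistics, while the raw count is retained.

## Morphometry

**Volume** is voxel count × voxel volume (reported in µm³).  **Surface** is,
by default, the area of a marching-cubes iso-surface at level 0.5 of the
lightly anti-aliased mask (Gaussian σ = 1.5 voxels).  Meshing the raw binary
volume overestimates a ball's area by 7–9 % (stair-casing); with
anti-aliasing the digitized-ball form factor converges monotonically to 1
(deviations −5.4 %, −1.3 %, −0.3 %, −0.04 % at radii 10/20/40/80 voxels).
A `voxel_faces` estimator (exposed foreground faces × voxel area) is kept for
comparability with voxel-counting plugins; it cannot reach the spherical
anchor.  **Form factor** ff = (36π)^(−1/3) S V^(−2/3) is dimensionless and
unit-invariant: 1 for a sphere, larger for less compact shapes.

**Principal-axis alignment** orthogonalizes the second central moment
(inertia) tensor of the voxel distribution, intensity-weighted by default
(binary moments via flag).  The largest-variance eigenvector maps to x, the
middle to y, the smallest to z.  Signs follow the third central moment
(skewness) along each axis (ties: first nonzero component positive); if the
three sign-fixed axes are left-handed, the axis with the smallest absolute
skewness is flipped, so the rotation always has determinant +1.  The aligned
volume is trilinearly resampled into the rotated bounding box padded by two
voxels.  A structure with all mass in one voxel gets the identity rotation
and a degeneracy flag.

## Group statistics

Per measure (volume, surface, form factor), classes are compared with a
tie-corrected Kruskal–Wallis test (χ², k−1 df) and pairwise two-sided
Mann–Whitney tests with Bonferroni correction (multiplier = number of pairs
actually tested).  When both sides of a pair have ≤ 8 observations the
permutation distribution of U is enumerated exactly (ties handled exactly);
larger pairs use the normal approximation with tie and continuity
correction.  The two-sided exact p-value is the permutation probability of a
U at least as far from its null mean nm/2 as observed.  Classes with fewer
than two observations are excluded from pairwise testing (with a warning)
but kept in the class histogram.  All-identical inputs report H = 0, p = 1
(Kruskal–Wallis) or p = 1 (degenerate pair).  Significance marks: ns, *, **,
*** at 0.05 / 0.01 / 0.001.

## Synthetic phantoms

The generator emulates the signal classes of the real data so the whole
chain is testable without microscope data:

* **Structure**: 1–4 Gaussian density lobes (σ = 30 nm, peak 200 detector
  units) placed 240 nm apart along a smoothly drifting 3D path, joined by
  bridges of the same cross-section scale at half the lobe peak.  Lobe cores
  saturate the detector (rendered as peak × min(1, 2·exp(−d²/2σ²))):
  silver-enhanced staining is locally complete, and the resulting high
  intensity mode is what makes histogram-based thresholding well-posed.
  With purely Gaussian (valley-free) histograms the maximum-entropy optimum
  is unstable under noise — no automatic threshold behaves reproducibly
  there, and the real data evidently did not look like that.
* **Non-specific signal**: bright discs (35 nm diameter, intensity above the
  lobe peak) confined to single random sections, placed disjoint from the
  structure and from each other (bounded retries).
* **Background**: uniform nuclear counterstain (level 20) plus additive
  Gaussian detector noise (σ = 2), rounded and clipped to 8-bit.

Geometry choices are constrained by resolvability and by the decomposition
scales: lobe spacing (240 nm) exceeds the max-filter support (135 nm) plus
the saturated core extent (~70 nm), so adjacent lobes produce distinct
regional maxima; the above-threshold bridge radius (~38 nm) exceeds half the
coarsest section pitch (25 nm), so slicing cannot sever the structure's
connectivity — a structure thinner than the section pitch would be
unrecoverable by any method, and the imaged structures were not.

**Ground truth** is defined on the noiseless signal, thresholded at the
generated image's own maximum-entropy operating point (minus background).
A Gaussian lobe has no canonical boundary; defining truth at the operating
point makes the end-to-end precision/recall metrics measure what they should
— the quality of noise filtering and connectivity classification — rather
than the arbitrary choice of where a Gaussian tail "ends".  (A fixed
half-peak truth contour sits far from where any histogram threshold lands on
such data, and would mis-score a correct segmentation.)  Domain truth labels
assign each structure voxel to the nearest lobe centre in physical distance.
One PCG64 stream (`numpy.random.default_rng(seed)`) drives path, jitter,
speck placement and noise in documented order, so phantoms are
bit-reproducible given the seed.

The fixed test battery covers domain counts 1–4 × both acquisition
geometries (5×5×30 nm and 7×7×50 nm) × with/without specks (16 members,
~1100 nm fields of view).  On it, the full pipeline recovers the true domain
count in 16/16 members (verified across five independent battery seeds,
80/80), with voxel precision and recall of the specific mask ≥ 0.97 and no
speck voxel ever leaking into the specific mask.

What the phantoms do *not* emulate: electron-optics contrast formation and
point-spread, section-thickness variation and registration error, textured
nuclear background, partial-volume effects at lobe boundaries, and chromatin
shapes beyond smooth lobes-on-a-path.  Passing the battery therefore shows
the algorithmic chain is correct and robust to the modelled nuisances, not
that it would segment arbitrary real stacks.

## Numerical and edge-case conventions

* Axis order (z, y, x), 0-based voxel indices, half-open ROI boxes.
* Voxel sizes are caller-supplied, never read from TIFF tags (written on
  output as a courtesy, with an authoritative plain-text sidecar).
* 26-connectivity for object analysis; 6-connectivity only for the final
  diffusion-facing mask (see above).
* Largest-component ties resolve to the first component in raster order.
* Empty NS mask: signal ratio reported as +inf with a flag, fraction 0.
* Problem sizes in the tests (16 phantoms of ≤ 5·10⁶ isotropic voxels,
  digitized balls to radius 80 voxels, 2000 null simulations at n = 5+5)
  were chosen so the battery demonstrates every claim at desk scale.

## Known limitations

* Absolute surface areas (hence form factors) are estimator-dependent at the
  voxel scale; the mesh estimator is calibrated on balls, not on thin sheets.
* The diffusion partition depends mildly on the seed-field width σ_init and
  on termination time; both defaults are documented and the partition is
  deterministic given them.
* Unit-mass seed fields slightly favour volume-balanced partitions on
  near-uniform density; with real density lobes the coefficient D dominates.
* Only integer-shift residual registration is provided; stacks are assumed
  pre-registered.
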