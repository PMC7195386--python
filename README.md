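# emish3d

Analysis of 3D chromatin-folding structures imaged by serial block-face
scanning electron microscopy (SBF-SEM) after DNA in-situ hybridization with
silver-enhanced detection ("3D-EMISH"-style data).

Such experiments produce anisotropic z-stacks (in-plane pixels of 5–7 nm,
sections of 30–50 nm) in which the hybridized target chromatin appears as a
bright, connected, multi-lobed object, contaminated by punctate non-specific
staining and a weak nuclear background.  `emish3d` takes a registered ROI
stack and produces, per structure:

1. **Segmentation** — maximum-entropy (Kapur) thresholding; removal of
   non-specific signal by *multilayer connectivity* (specific signal is
   continuous across consecutive sections, punctate noise is not); largest
   connected component; isotropic resampling (linear interpolation at
   physical positions, default 5 nm); per-section Gaussian smoothing.
2. **Sub-domain decomposition** — maximum-filter smoothing (135 nm support),
   local density centres as seeds, then one diffusion equation per seed,

       ∂u_i/∂t = ∇·( D(r) ∇u_i ),   i = 1..N,

   with the image density D as a position-dependent diffusion coefficient,
   zero-flux boundaries at the mask border, and unit-mass Gaussian initial
   fields at the seeds.  Once every voxel carries material, each voxel joins
   the sub-domain with the largest diffused field.
3. **Morphometry** — volume V, mesh surface area S, the compactness
   *form factor*

       ff = (36 π)^(−1/3) · S · V^(−2/3)

   (1 for a sphere, larger for less compact shapes), and principal-axis
   extents after inertia-tensor alignment.
4. **Group statistics** — sub-domain class histogram, Kruskal–Wallis, and
   pairwise two-sided Mann–Whitney tests (exact enumeration for small
   groups) with Bonferroni correction.

A synthetic phantom generator with known ground truth (lobes, bridges,
single-section specks, background, detector noise, anisotropic sampling)
makes the entire chain testable without microscope data.  See
`docs/methods.md` for the full model description and numerical conventions.

## Worked example

```python
import emish3d as e

# a 3-lobe phantom with 30 non-specific specks, 5x5x30 nm voxels
p = e.generate_phantom(e.PhantomSpec(n_domains=3, speckle_count=30, seed=11))
r = e.analyze_stack(p.grid, structure_id="sID11")

seg = r.segmentation
print(f"threshold          : {seg.threshold:.2f}")
print(f"SP/NS volume ratio : {seg.ratio_specific_to_nonspecific:.3f}")
print(f"NS background frac : {100*seg.nonspecific_background_fraction:.3f} %")
print(f"sub-domains        : {r.labeling.n_domains}  (class {r.record.morph_class})")
print(f"volume             : {r.record.volume_um3:.5f} um^3")
print(f"surface            : {r.record.surface_um2:.5f} um^2")
print(f"form factor        : {r.record.form_factor:.3f}")
print(f"extents (nm)       : {tuple(round(x) for x in r.record.extents_nm)}")
```

prints

```
threshold          : 48.88
SP/NS volume ratio : 1.272
NS background frac : 0.807 %
sub-domains        : 3  (class 3)
volume             : 0.00603 um^3
surface            : 0.23161 um^2
form factor        : 1.445
extents (nm)       : (619, 192, 152)
```

The threshold is the entropy-optimal intensity cut; the SP/NS ratio compares
specific to non-specific signal volume in the ROI and the background fraction
is the share of non-signal volume occupied by punctate noise; the pipeline
recovered all three density lobes as sub-domains; the form factor 1.445 > 1
quantifies how far the elongated three-lobe structure departs from a ball,
and the extents are the structure's size along its principal axes.

The same chain is available from the shell:

```sh
emish3d simulate --n-domains 3 --seed 11 --out sim/
emish3d segment  --in sim/grid.tif --voxel-size 30,5,5 --out seg/
emish3d domains  --in seg/iso.tif --mask seg/mask.tif --out dom/
emish3d measure  --in seg/iso.tif --mask seg/mask.tif --labels dom/labels.tif --out morph.tsv
emish3d stats    --in morph.tsv --measure volume --out stats.tsv
```

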