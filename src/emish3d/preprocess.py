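"""Raw-stack preprocessing: thresholding, connectivity filtering, resampling.

The processing chain turns a registered, anisotropic ROI stack into a clean
isotropic segmented structure:

1. maximum-entropy (Kapur) intensity threshold;
2. removal of non-specific signal: connected components that do not span
   enough consecutive z-slices are punctate staining noise, not chromatin
   (the specific hybridization signal is continuous across slices);
3. largest connected component = the target structure;
4. isotropic resampling (linear interpolation at physical voxel positions)
   to the in-plane pixel size, typically 5 nm;
5. per-slice Gaussian smoothing to suppress residual pixel noise.

All masks and volumes use 26-connectivity in 3D unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imagestack import VoxelGrid

__all__ = [
    "StructureMask",
    "max_entropy_threshold",
    "largest_component",
    "filter_nonspecific",
    "signal_ratio",
    "resample_isotropic",
    "smooth_xy",
    "align_integer_shift",
    "segment_stack",
]

#: 26-neighbourhood structuring element for 3D connected components.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StructureMask:
    """Binary mask of one segmented structure, with segmentation provenance."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    threshold_value: float
    min_layers_kept: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")


def max_entropy_threshold(grid: VoxelGrid | np.ndarray, nbins: int = 256) -> float:
    """Kapur–Sahoo–Wong maximum-entropy threshold.

    Builds an ``nbins``-bin histogram over [min, max] and returns the cut
    value t maximizing the summed Shannon entropies of the normalized
    sub-histograms below (<= t) and above (> t) the cut.  Foreground is
    ``intensity > t``.  Zero-probability bins contribute nothing to either
    entropy.  Ties between cut points resolve to the lowest threshold.

    Raises
    ------
    ValueError
        If the image is constant (no threshold separates two classes).
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    lo = float(data.min())
    hi = float(data.max())
    if lo == hi:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(data.reshape(-1), bins=nbins, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()

    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P = np.cumsum(p)            # P[t]  = mass of bins 0..t
    S = np.cumsum(plogp)        # S[t]  = sum p log p over bins 0..t
    Ptot, Stot = P[-1], S[-1]

    # candidate cuts after bin t, for t = 0 .. nbins-2
    w0 = P[:-1]
    w1 = Ptot - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(w0) - S[:-1] / w0
        h1 = np.log(w1) - (Stot - S[:-1]) / w1
    obj = np.where(valid, h0 + h1, -np.inf)
    t_idx = int(np.argmax(obj))  # argmax returns the first (lowest) maximizer
    # threshold = upper edge of bin t_idx: foreground is strictly above it
    return float(edges[t_idx + 1])


def largest_component(mask: np.ndarray, connectivity: np.ndarray = CONN26) -> np.ndarray:
    """Keep only the connected component with the most voxels.

    Ties are broken toward the component whose minimum (z, y, x) coordinate
    is lexicographically smallest, which for raster-order labeling is the
    component with the smallest label.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no component to select")
    labels, n = ndimage.label(mask, structure=connectivity)
    if n == 1:
        return mask.copy()
    counts = np.bincount(labels.reshape(-1))[1:]
    # np.argmax keeps the first (lowest label = first in raster order) on ties
    best = int(np.argmax(counts)) + 1
    return labels == best


def _component_z_extents(labels: np.ndarray, n: int) -> np.ndarray:
    """Number of distinct z-slices each labeled component touches (1-based labels)."""
    extents = np.zeros(n + 1, dtype=int)
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is not None:
            sub = labels[sl] == i
            extents[i] = int(sub.any(axis=(1, 2)).sum())
    return extents


def filter_nonspecific(mask: np.ndarray, min_layers: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask into specific (kept) and non-specific (removed) signal.

    A 26-connected component is specific only if it touches at least
    ``min_layers`` distinct z-slices: hybridization signal bound to the
    target chromatin persists across consecutive sections, whereas punctate
    non-specific staining is confined to single sections.

    Returns ``(kept, removed)``; the two masks partition the input exactly.
    """
    if min_layers < 1:
        raise ValueError("min_layers must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_layers == 1 or not mask.any():
        return mask.copy(), np.zeros_like(mask)
    labels, n = ndimage.label(mask, structure=CONN26)
    extents = _component_z_extents(labels, n)
    keep = extents >= min_layers
    keep[0] = False
    kept = keep[labels]
    return kept, mask & ~kept


def signal_ratio(kept: np.ndarray, removed: np.ndarray) -> tuple[float, float, bool]:
    """Specific/non-specific bookkeeping over an ROI.

    With SP = kept (specific), NS = removed (non-specific) and BN the
    remaining no-signal background, returns

    - ``ratio`` = vol(SP) / vol(NS),
    - ``fraction`` = vol(NS) / (vol(NS) + vol(BN)), the share of the
      background volume occupied by non-specific signal,
    - ``ns_empty`` flag: True when NS is empty, in which case the ratio is
      reported as ``inf`` and the fraction as 0.

    Voxel volume cancels in both quantities, so plain voxel counts are used.
    """
    kept = np.asarray(kept, dtype=bool)
    removed = np.asarray(removed, dtype=bool)
    if kept.shape != removed.shape:
        raise ValueError("kept and removed must have the same shape")
    if (kept & removed).any():
        raise ValueError("kept and removed must be disjoint")
    sp = int(kept.sum())
    ns = int(removed.sum())
    bn = kept.size - sp - ns
    if ns == 0:
        return float("inf"), 0.0, True
    return sp / ns, ns / (ns + bn), False


def resample_isotropic(grid: VoxelGrid, target_nm: float) -> VoxelGrid:
    """Resample to isotropic voxels of edge ``target_nm`` by linear interpolation.

    Output voxel centres are laid on an exact ``target_nm`` grid spanning the
    input's physical sample positions (plane k of axis a sits at
    ``k * voxel_size[a]``); values are linearly interpolated between adjacent
    input samples at those physical positions, so values at original plane
    positions are reproduced exactly.  Axes already at the target spacing are
    left untouched.  Only upsampling is supported: the slice spacing is the
    coarse axis being refined.
    """
    if target_nm <= 0:
        raise ValueError("target_nm must be positive")
    if any(target_nm > v for v in grid.voxel_size):
        raise ValueError(
            f"downsampling unsupported: target {target_nm} nm exceeds a voxel "
            f"dimension of {grid.voxel_size}"
        )
    coords = []
    new_shape = []
    for n, v in zip(grid.shape, grid.voxel_size):
        if v == target_nm:
            c = np.arange(n, dtype=np.float64)
        else:
            extent = (n - 1) * v
            m = int(np.floor(extent / target_nm + 1e-9)) + 1
            c = np.arange(m, dtype=np.float64) * (target_nm / v)
        coords.append(c)
        new_shape.append(len(c))
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        grid.data.astype(np.float32), np.stack([zz, yy, xx]), order=1, mode="nearest"
    )
    return VoxelGrid(out, (target_nm, target_nm, target_nm), grid.origin_index)


def smooth_xy(grid: VoxelGrid, sigma_nm: float) -> VoxelGrid:
    """Per-slice 2D Gaussian smoothing (reflective boundary).

    ``sigma_nm`` is converted to pixels with the in-plane voxel size; each
    z-section is filtered independently, which removes detector pixel noise
    without mixing information across sections.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be positive")
    _, vy, vx = grid.voxel_size
    out = ndimage.gaussian_filter(
        grid.data.astype(np.float64), sigma=(0.0, sigma_nm / vy, sigma_nm / vx),
        mode="reflect",
    )
    return VoxelGrid(out, grid.voxel_size, grid.origin_index)


def align_integer_shift(reference: np.ndarray, moving: np.ndarray,
                        max_shift: int = 10) -> tuple[int, int]:
    """Optional utility: integer (y, x) shift maximizing cross-correlation.

    Stacks are assumed pre-registered; this helper corrects residual whole-
    pixel drift between two slices when needed.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    best, arg = -np.inf, (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(mov, dy, axis=0), dx, axis=1)
            c = float((ref * shifted).sum())
            if c > best:
                best, arg = c, (dy, dx)
    return arg


@dataclass
class SegmentationResult:
    """Products of the raw-stack segmentation front end."""

    kept: np.ndarray            # specific-signal mask (raw grid resolution)
    removed: np.ndarray         # non-specific mask
    structure_raw: np.ndarray   # largest specific component, raw resolution
    threshold: float
    ratio_specific_to_nonspecific: float
    nonspecific_background_fraction: float
    iso: VoxelGrid              # isotropic, smoothed intensity grid
    mask: StructureMask         # structure mask on the isotropic grid
    n_components_kept: int


def segment_stack(grid: VoxelGrid, min_layers: int = 2, target_nm: float = 5.0,
                  sigma_nm: float = 5.0) -> SegmentationResult:
    """Full front end: threshold -> layer filter -> largest component ->
    isotropic resample -> per-slice Gaussian smoothing.

    The largest-component search is restricted to components that pass the
    consecutive-layer filter, so an aggregation of non-specific specks can
    never be selected as the target structure.  The isotropic structure mask
    re-applies the intensity threshold on the interpolated grid, restricted
    to the interpolation support of the raw structure mask: thresholding the
    resampled *binary* mask instead can sever thin parts of the structure
    whose interpolated occupancy falls below one half between coarse
    z-planes, while the interpolated intensity stays well above threshold.
    """
    t = max_entropy_threshold(grid)
    raw_mask = grid.data > t
    kept, removed = filter_nonspecific(raw_mask, min_layers)
    ratio, fraction, _ = signal_ratio(kept, removed)
    if not kept.any():
        raise ValueError("no specific signal remains after the layer filter")
    structure_raw = largest_component(kept)
    n_comp = int(ndimage.label(kept, structure=CONN26)[1])

    iso = resample_isotropic(grid, target_nm)
    iso = smooth_xy(iso, sigma_nm)
    mgrid = VoxelGrid(structure_raw.astype(np.float32), grid.voxel_size, grid.origin_index)
    support = resample_isotropic(mgrid, target_nm).data > 0.05
    miso = support & (iso.data > t)
    if not miso.any():
        raise ValueError("structure mask vanished during resampling")
    # 6-connectivity here: the diffusion stage transports mass across voxel
    # faces, so the final mask must be face-connected or corner-attached
    # islands would never fill
    miso = largest_component(miso, connectivity=ndimage.generate_binary_structure(3, 1))
    mask = StructureMask(mask=miso, voxel_size=(target_nm,) * 3,
                         threshold_value=t, min_layers_kept=min_layers)
    return SegmentationResult(
        kept=kept, removed=removed, structure_raw=structure_raw, threshold=t,
        ratio_specific_to_nonspecific=ratio,
        nonspecific_background_fraction=fraction,
        iso=iso, mask=mask, n_components_kept=n_comp,
    )
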