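"""Synthetic 3D-EMISH phantoms with known ground truth.

A phantom emulates the signal classes of a serial block-face EM stack after
in-situ hybridization with silver-enhanced detection:

* a bright, connected, multi-lobed chromatin structure spanning many
  consecutive z-slices.  Lobes are Gaussian density kernels whose cores
  saturate the detector (silver deposition is locally complete, so real
  signal cores sit at the top of the intensity range); consecutive lobes are
  joined by thinner bridges whose density dips mid-way, giving the dumbbell
  morphology of multi-domain structures;
* sparse punctate non-specific staining: bright discs confined to a single
  z-slice each;
* a weak, uniformly stained nuclear background plus additive detector noise;
* anisotropic sampling: the z (slicing) voxel pitch is several times the
  in-plane pixel size.

Ground-truth masks are defined on the *noiseless* signal, thresholded at the
image's own maximum-entropy operating point, so that segmentation metrics
computed against them measure filtering quality rather than the arbitrary
choice of where a Gaussian tail "ends".  Domain labels assign every
structure voxel to the nearest lobe centre in physical distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imagestack import VoxelGrid
from .preprocess import max_entropy_threshold

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "phantom_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic stack.

    Intensities are 8-bit detector units.  Defaults emulate the replicate-2
    acquisition geometry (5 x 5 nm pixels, 30 nm sections).
    """

    shape: tuple[int, int, int] = (16, 220, 220)
    voxel_size: tuple[float, float, float] = (30.0, 5.0, 5.0)
    n_domains: int = 2
    blob_centers: tuple[tuple[float, float, float], ...] | None = None
    blob_sigma_nm: float = 30.0
    blob_peak: float = 200.0
    core_saturation: float = 2.0
    link_intensity: float = 100.0
    link_sigma_nm: float = 30.0
    link_dip: float = 1.0
    lobe_spacing_nm: float = 240.0
    speckle_count: int = 30
    speckle_diameter_nm: float = 35.0
    speckle_peak: float = 220.0
    background_level: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        for name in ("blob_sigma_nm", "blob_peak", "link_intensity",
                     "speckle_peak", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.speckle_count < 0:
            raise ValueError("speckle_count must be >= 0")


@dataclass
class PhantomTruth:
    """A generated stack together with its ground truth."""

    grid: VoxelGrid
    structure_mask: np.ndarray   # bool; the connected target structure
    domain_labels: np.ndarray    # int16; 0 background, 1..n_domains
    noise_mask: np.ndarray       # bool; union of single-slice specks
    truth_threshold: float       # intensity cut (detector units) defining the masks
    spec: PhantomSpec
    lobe_centers_nm: tuple[tuple[float, float, float], ...] = ()


def _axis_grids(shape, voxel_size):
    z, y, x = (np.arange(n, dtype=np.float64) * v
               for n, v in zip(shape, voxel_size))
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _sample_path(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Lobe centres along a gently curving 3D path, centred in the volume."""
    n = spec.n_domains
    Lz, Ly, Lx = ((s - 1) * v for s, v in zip(spec.shape, spec.voxel_size))
    center = np.array([Lz / 2, Ly / 2, Lx / 2])
    if n == 1:
        return (center + rng.normal(0.0, 12.0, 3) * np.array([0.6, 1, 1]))[None]
    theta = rng.uniform(0, 2 * np.pi)
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        dz = rng.uniform(-30.0, 30.0)
        step = np.array([dz, np.sin(theta), np.cos(theta)])
        step[1:] *= np.sqrt(max(spec.lobe_spacing_nm ** 2 - dz ** 2, 1.0)) / np.hypot(*step[1:])
        pts.append(pts[-1] + step)
        theta += rng.uniform(-0.35, 0.35)  # smooth drift of direction
    pts = np.asarray(pts)
    pts += center - pts.mean(axis=0)
    pts += rng.normal(0.0, 12.0, pts.shape) * np.array([0.5, 1, 1])
    return pts


def _structure_field(spec: PhantomSpec, centers: np.ndarray,
                     zg, yg, xg) -> np.ndarray:
    """Noiseless structure signal (detector units above background)."""
    sigma = spec.blob_sigma_nm
    sat = spec.core_saturation
    out = np.zeros(np.broadcast_shapes(zg.shape, yg.shape, xg.shape))
    for c in centers:
        d2 = (zg - c[0]) ** 2 + (yg - c[1]) ** 2 + (xg - c[2]) ** 2
        lobe = spec.blob_peak * np.minimum(1.0, sat * np.exp(-d2 / (2 * sigma ** 2)))
        np.maximum(out, lobe, out=out)
    # bridge cross-section scale: must stay resolvable under the coarse
    # z-sampling (above-threshold radius comfortably over half the slice
    # pitch), or no segmentation could recover the connectivity
    sb = spec.link_sigma_nm
    for a, b in zip(centers[:-1], centers[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        pz, py, px = zg - a[0], yg - a[1], xg - a[2]
        tpar = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / L2, 0.0, 1.0)
        d2 = (pz - tpar * ab[0]) ** 2 + (py - tpar * ab[1]) ** 2 + (px - tpar * ab[2]) ** 2
        axial = spec.link_dip + (1.0 - spec.link_dip) * (2.0 * tpar - 1.0) ** 2
        bridge = spec.link_intensity * axial * np.exp(-d2 / (2 * sb ** 2))
        np.maximum(out, bridge, out=out)
    return out


def _place_specks(rng: np.random.Generator, spec: PhantomSpec,
                  structure: np.ndarray, yg, xg) -> np.ndarray:
    """Single-slice bright discs, disjoint (in 3D) from the structure and
    from each other.  Bounded retries per speck; raises if placement is
    impossible."""
    nz = spec.shape[0]
    Ly = (spec.shape[1] - 1) * spec.voxel_size[1]
    Lx = (spec.shape[2] - 1) * spec.voxel_size[2]
    r = spec.speckle_diameter_nm / 2.0
    yg2, xg2 = yg[0, :, :], xg[0, :, :]
    speck = np.zeros(spec.shape, dtype=np.float64)
    floor = 1.0  # fields below this never reach any mask threshold
    for k in range(spec.speckle_count):
        for attempt in range(200):
            zi = int(rng.integers(0, nz))
            cy, cx = rng.uniform(0, Ly), rng.uniform(0, Lx)
            d2 = (yg2 - cy) ** 2 + (xg2 - cx) ** 2
            disc = spec.speckle_peak * np.minimum(
                1.0, spec.core_saturation * np.exp(-d2 / (2 * r ** 2)))
            region = disc > floor
            z0, z1 = max(zi - 1, 0), min(zi + 2, nz)
            if (structure[z0:z1][:, region] > floor).any():
                continue
            if (speck[z0:z1][:, region] > floor).any():
                continue
            np.maximum(speck[zi], disc, out=speck[zi])
            break
        else:
            raise RuntimeError(f"could not place speck {k} without creating a "
                               "multi-slice object; volume too crowded")
    return speck


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom stack and its ground truth.

    Deterministic given ``spec.seed``: all randomness is drawn from a single
    ``numpy.random.default_rng`` (PCG64) stream in documented order (lobe
    path, lobe jitter, speck placements, detector noise).  The path is
    redrawn (bounded retries) if the structure does not span at least three
    consecutive z-slices or leaves the margin of the volume.
    """
    rng = np.random.default_rng(spec.seed)
    zg, yg, xg = _axis_grids(spec.shape, spec.voxel_size)
    Lz, Ly, Lx = ((s - 1) * v for s, v in zip(spec.shape, spec.voxel_size))
    sigma = spec.blob_sigma_nm
    margin_xy = 2.5 * sigma
    margin_z = 1.6 * sigma

    for attempt in range(60):
        if spec.blob_centers is not None:
            centers = np.asarray(spec.blob_centers, dtype=np.float64)
        else:
            centers = _sample_path(rng, spec)
        ok = (np.all(centers[:, 0] >= margin_z) and np.all(centers[:, 0] <= Lz - margin_z)
              and np.all(centers[:, 1] >= margin_xy) and np.all(centers[:, 1] <= Ly - margin_xy)
              and np.all(centers[:, 2] >= margin_xy) and np.all(centers[:, 2] <= Lx - margin_xy))
        if not ok:
            if spec.blob_centers is not None:
                raise ValueError("blob_centers leave insufficient margin inside the volume")
            continue
        structure = _structure_field(spec, centers, zg, yg, xg)
        # require a generous z-span before looking at the operating threshold
        zspan = (structure.max(axis=(1, 2)) > 0.25 * spec.blob_peak)
        if zspan.sum() >= 3:
            break
        if spec.blob_centers is not None:
            raise ValueError("blob_centers give a structure thinner than 3 z-slices")
    else:
        raise RuntimeError("could not draw a valid lobe path inside the volume")

    speck = _place_specks(rng, spec, structure, yg, xg)
    clean = spec.background_level + np.maximum(structure, speck)
    noisy = clean + rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else clean
    img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    grid = VoxelGrid(img, spec.voxel_size)

    t = max_entropy_threshold(grid)
    amp = t - spec.background_level
    if amp <= 0 or amp >= spec.blob_peak:
        raise RuntimeError(f"degenerate phantom: operating threshold {t:.1f} "
                           "does not separate structure from background")
    structure_mask = structure > amp
    noise_mask = speck > amp
    if (structure_mask & noise_mask).any():
        raise RuntimeError("speck placement failed to keep masks disjoint")

    labels = np.zeros(spec.shape, dtype=np.int16)
    idx = np.nonzero(structure_mask)
    pos = np.stack([idx[0] * spec.voxel_size[0],
                    idx[1] * spec.voxel_size[1],
                    idx[2] * spec.voxel_size[2]], axis=1)
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels[idx] = np.argmin(d2, axis=1).astype(np.int16) + 1

    return PhantomTruth(
        grid=grid, structure_mask=structure_mask, domain_labels=labels,
        noise_mask=noise_mask, truth_threshold=float(t), spec=spec,
        lobe_centers_nm=tuple(map(tuple, centers)),
    )


def suite_specs(seed: int) -> list[PhantomSpec]:
    """The fixed phantom battery: domain counts 1-4, both acquisition
    geometries (5x5x30 and 7x7x50 nm), with and without specks."""
    specs = []
    k = 0
    for vox, shape in (((30.0, 5.0, 5.0), (16, 220, 220)),
                       ((50.0, 7.0, 7.0), (11, 160, 160))):
        for n in (1, 2, 3, 4):
            for speckles in (0, 30):
                specs.append(PhantomSpec(
                    shape=shape, voxel_size=vox, n_domains=n,
                    speckle_count=speckles, seed=(seed * 1009 + k) % (2 ** 31),
                ))
                k += 1
    return specs


def phantom_suite(seed: int = 0) -> list[PhantomTruth]:
    """Generate the fixed 16-member phantom battery used by the end-to-end
    tests (see :func:`suite_specs`)."""
    return [generate_phantom(s) for s in suite_specs(seed)]
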