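"""Morphometry of segmented structures: alignment, volume, surface, form factor.

The compactness measure is the dimensionless form factor

    ff = (36 pi)^(-1/3) * S * V^(-2/3)

which equals 1 for a sphere (the isoperimetric minimum) and grows as the
shape departs from a ball.  Surfaces are measured on a marching-cubes
iso-surface of the binary mask by default; voxel-face counting is provided
for comparability with voxel-counting tools but systematically overestimates
curved surfaces (~1.5x on a ball) and can never reach the spherical anchor
ff = 1.

Principal-axis alignment orthogonalizes the structure's inertia tensor (the
second central moment tensor of the voxel distribution, intensity-weighted
by default): the eigenvector of the largest eigenvalue is rotated onto the
x-axis, the second onto y, the third onto z.  Signs follow the third central
moment (skewness) along each axis, so alignment is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .imagestack import VoxelGrid
from .preprocess import StructureMask

__all__ = [
    "MorphometryRecord",
    "AlignmentTransform",
    "inertia_align",
    "measure_volume",
    "measure_surface",
    "form_factor",
    "measure_structure",
]

_FF_CONST = (36.0 * np.pi) ** (-1.0 / 3.0)
NM3_TO_UM3 = 1e-9
NM2_TO_UM2 = 1e-6


@dataclass
class AlignmentTransform:
    """Rigid transform into the principal-axis frame."""

    rotation: np.ndarray            # 3x3 orthonormal, det +1; rows = (z', y', x') axes
    center: tuple[float, float, float]  # (z, y, x) centroid in nm
    degenerate: bool = False


@dataclass
class MorphometryRecord:
    """Per-structure measurements, with optional per-sub-domain rows."""

    structure_id: str
    n_domains: int
    morph_class: int
    volume_um3: float
    surface_um2: float
    form_factor: float
    extents_nm: tuple[float, float, float]
    per_domain: list[tuple[int, float, float]] = dfield(default_factory=list)

    @staticmethod
    def table_columns() -> list[str]:
        return ["structure_id", "n_domains", "morph_class", "volume_um3",
                "surface_um2", "form_factor", "extent1_nm", "extent2_nm",
                "extent3_nm", "domain_label", "domain_volume_um3",
                "domain_surface_um2"]

    def as_row(self) -> dict:
        e1, e2, e3 = self.extents_nm
        return {"structure_id": self.structure_id, "n_domains": self.n_domains,
                "morph_class": self.morph_class, "volume_um3": self.volume_um3,
                "surface_um2": self.surface_um2, "form_factor": self.form_factor,
                "extent1_nm": e1, "extent2_nm": e2, "extent3_nm": e3,
                "domain_label": "", "domain_volume_um3": "", "domain_surface_um2": ""}

    def as_rows(self) -> list[dict]:
        rows = [self.as_row()]
        for lab, v, s in self.per_domain:
            r = {c: "" for c in self.table_columns()}
            r.update({"structure_id": self.structure_id, "domain_label": lab,
                      "domain_volume_um3": v, "domain_surface_um2": s})
            rows.append(r)
        return rows


def _moments(grid: VoxelGrid, mask: np.ndarray, binary: bool):
    voxel = np.asarray(grid.voxel_size, dtype=np.float64)
    coords = np.argwhere(mask).astype(np.float64) * voxel  # (n, 3) nm
    w = np.ones(len(coords)) if binary else grid.data[mask].astype(np.float64)
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones(len(coords))
        wsum = w.sum()
    c = (w[:, None] * coords).sum(axis=0) / wsum
    d = coords - c
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / wsum
    return coords, w, c, cov, d


def inertia_align(grid: VoxelGrid, mask: StructureMask, *,
                  binary_moments: bool = False,
                  pad_voxels: int = 2) -> tuple[AlignmentTransform, VoxelGrid]:
    """Rotate a structure into its principal-axis frame.

    Eigenvectors of the second-moment (inertia) tensor define the frame: the
    largest-variance axis maps to x, the middle to y, the smallest to z.
    Each eigenvector is flipped so the intensity distribution's third moment
    along it is >= 0 (ties: first nonzero component positive); if the three
    sign-fixed axes form a left-handed frame, the axis with the smallest
    absolute skewness is flipped back, so the rotation determinant is +1.
    The aligned grid is produced by trilinear resampling into the rotated
    mask's bounding box padded by ``pad_voxels``.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    voxel = _iso_voxel(grid)
    coords, w, c, cov, d = _moments(grid, m, binary_moments)

    degenerate = np.allclose(cov, 0.0)
    if degenerate:
        R = np.eye(3)
    else:
        evals, evecs = np.linalg.eigh(cov)       # ascending
        order = np.argsort(evals)[::-1]          # descending variance
        axes = []
        skews = []
        for k in order:
            v = evecs[:, k]
            proj = d @ v
            m3 = float((w * proj ** 3).sum())
            if abs(m3) < 1e-9 * max(1.0, float((w * np.abs(proj) ** 3).sum())):
                nz = np.flatnonzero(np.abs(v) > 1e-12)
                if len(nz) and v[nz[0]] < 0:
                    v = -v
                m3 = 0.0
            elif m3 < 0:
                v = -v
                m3 = -m3
            axes.append(v)
            skews.append(m3)
        # axes[0] = largest-variance direction -> x; rotation rows are the
        # aligned frame's (z', y', x') axes expressed in the (z, y, x) basis
        R = np.stack([axes[2], axes[1], axes[0]], axis=0)
        if np.linalg.det(R) < 0:
            j = int(np.argmin(skews))           # least-committed sign
            R[2 - j] = -R[2 - j]
    transform = AlignmentTransform(rotation=R, center=tuple(c), degenerate=degenerate)
    aligned = apply_alignment(grid.data, m, transform, voxel, pad_voxels)
    return transform, VoxelGrid(np.clip(aligned, 0, None), (voxel,) * 3)


def apply_alignment(volume: np.ndarray, mask: np.ndarray,
                    transform: AlignmentTransform, voxel_nm: float,
                    pad_voxels: int = 2) -> np.ndarray:
    """Trilinearly resample ``volume`` into the principal-axis frame, in the
    rotated bounding box of ``mask`` padded by ``pad_voxels``."""
    R = np.asarray(transform.rotation)
    c = np.asarray(transform.center)
    mask_coords = np.argwhere(np.asarray(mask, bool)).astype(np.float64) * voxel_nm
    aligned = (mask_coords - c) @ R.T           # rows: (z', y', x') in nm
    lo = aligned.min(axis=0) - pad_voxels * voxel_nm
    hi = aligned.max(axis=0) + pad_voxels * voxel_nm
    out_shape = tuple(int(np.ceil((h - l) / voxel_nm)) + 1 for l, h in zip(lo, hi))
    # output voxel (k, j, i) sits at aligned position lo + idx * voxel;
    # input voxel index = (R^T @ p_aligned + c) / voxel
    A = R.T
    offset = (R.T @ lo + c) / voxel_nm
    return ndimage.affine_transform(np.asarray(volume, dtype=np.float64), A,
                                    offset=offset, output_shape=out_shape,
                                    order=1, mode="constant")


def _iso_voxel(grid: VoxelGrid) -> float:
    vz, vy, vx = grid.voxel_size
    if not (np.isclose(vz, vy) and np.isclose(vy, vx)):
        raise ValueError(f"isotropic grid required, got {grid.voxel_size}")
    return float(vx)


def principal_extents(mask: np.ndarray, voxel_nm: float,
                      rotation: np.ndarray, center) -> tuple[float, float, float]:
    """Extents (nm) of the mask along the aligned (x', y', z') axes, sorted
    descending."""
    coords = np.argwhere(np.asarray(mask, bool)).astype(np.float64) * voxel_nm
    aligned = (coords - np.asarray(center)) @ np.asarray(rotation).T
    spans = aligned.max(axis=0) - aligned.min(axis=0) + voxel_nm
    return tuple(sorted((float(s) for s in spans), reverse=True))  # type: ignore[return-value]


def measure_volume(labels: np.ndarray, voxel_nm: float) -> dict[int, float]:
    """Volume per label in um^3 (voxel count x voxel volume).

    A boolean mask is treated as the single label 1.  Labels absent from the
    volume report 0.
    """
    labels = np.asarray(labels)
    vox_um3 = (voxel_nm ** 3) * NM3_TO_UM3
    if labels.dtype == bool:
        return {1: float(labels.sum()) * vox_um3}
    counts = np.bincount(labels.reshape(-1))
    return {int(l): float(counts[l]) * vox_um3
            for l in range(1, len(counts))}


def measure_surface(mask: np.ndarray, voxel_nm: float,
                    method: str = "mesh") -> float:
    """Surface area of a binary mask in um^2.

    ``mesh``: marching-cubes iso-surface at level 0.5 of the lightly
    anti-aliased mask (1-voxel Gaussian; meshing the raw binary volume
    produces a stair-cased surface ~7-9% above the true area of a ball,
    which would push the spherical form-factor anchor out of reach); the
    volume is padded so border-touching masks close properly.
    ``voxel_faces``: exposed foreground faces x voxel area, the
    voxel-counting plugin convention.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    if method == "voxel_faces":
        faces = 0
        padded = np.pad(m, 1)
        for ax in range(3):
            d = np.diff(padded.astype(np.int8), axis=ax)
            faces += int(np.abs(d).sum())
        return faces * voxel_nm ** 2 * NM2_TO_UM2
    if method != "mesh":
        raise ValueError(f"unknown surface method {method!r}")
    from skimage.measure import marching_cubes, mesh_surface_area

    padded = ndimage.gaussian_filter(np.pad(m, 3).astype(np.float32), sigma=1.5)
    verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                        spacing=(voxel_nm,) * 3)
    return float(mesh_surface_area(verts, faces)) * NM2_TO_UM2


def form_factor(surface: float, volume: float) -> float:
    """ff = (36 pi)^(-1/3) S V^(-2/3); 1 for a sphere, larger otherwise.

    Unit-invariant as long as S and V use the same length unit.
    """
    if surface <= 0 or volume <= 0:
        raise ValueError("surface and volume must be positive")
    return _FF_CONST * surface * volume ** (-2.0 / 3.0)


def measure_structure(grid: VoxelGrid, mask: StructureMask,
                      labeling=None, structure_id: str = "s0",
                      surface_method: str = "mesh",
                      binary_moments: bool = False) -> MorphometryRecord:
    """Full per-structure morphometry, with per-sub-domain volume/surface
    when a labeling is supplied."""
    from .domains import classify_structure

    voxel = _iso_voxel(grid)
    m = np.asarray(mask.mask, bool)
    vol = measure_volume(m, voxel)[1]
    surf = measure_surface(m, voxel, surface_method)
    ff = form_factor(surf * 1e6, vol * 1e9)  # nm-scale values; ff unit-invariant

    transform, _ = inertia_align(grid, mask, binary_moments=binary_moments)
    extents = principal_extents(m, voxel, transform.rotation, transform.center)

    per_domain: list[tuple[int, float, float]] = []
    n_domains = 1
    if labeling is not None:
        n_domains = labeling.n_domains
        vols = measure_volume(labeling.labels, voxel)
        for lab in range(1, n_domains + 1):
            s = measure_surface(labeling.labels == lab, voxel, surface_method)
            per_domain.append((lab, vols.get(lab, 0.0), s))
    return MorphometryRecord(
        structure_id=structure_id, n_domains=n_domains,
        morph_class=classify_structure(n_domains),
        volume_um3=vol, surface_um2=surf, form_factor=ff,
        extents_nm=extents, per_domain=per_domain,
    )
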