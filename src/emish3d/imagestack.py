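"""Image-stack containers and TIFF I/O with physical voxel-size metadata.

The central container is :class:`VoxelGrid`: a 3D scalar volume in (z, y, x)
axis order together with the physical edge lengths of one voxel in
nanometres.  Serial block-face EM acquires anisotropic voxels (the slice
thickness along z is several times the in-plane pixel size), so the voxel
size travels with the data through every processing step.

Voxel sizes are supplied by the caller, never trusted from TIFF tags: tags
in EM exports are frequently wrong or missing.  On output the resolution
tags are written as a courtesy, and an authoritative plain-text sidecar
(``<name>.meta.txt``) records voxel size and origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "RoiBox",
    "read_stack",
    "write_stack",
    "write_labels",
    "write_table",
    "crop",
    "read_sidecar",
]


def _as_triple(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 entries (z, y, x), got {v!r}")
    return t  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D intensity volume with anisotropic physical voxel size.

    Parameters
    ----------
    data:
        3D array of non-negative intensities, axes ordered (z, y, x) with z
        the slicing (block-face) direction.
    voxel_size:
        Physical voxel edge lengths in nm, ordered (z, y, x).
    origin_index:
        Offset (voxel units, 0-based) of this grid within the parent stack
        it was cropped from; (0, 0, 0) for a freshly read stack.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin_index: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (z, y, x); got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every axis must have length >= 1; got {self.data.shape}")
        self.voxel_size = _as_triple(self.voxel_size, "voxel_size")
        if not all(np.isfinite(v) and v > 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size entries must be positive finite; got {self.voxel_size}")
        self.origin_index = tuple(int(i) for i in self.origin_index)  # type: ignore[assignment]
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_nm3(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def physical_extent_nm(self) -> tuple[float, float, float]:
        """Physical size of the full grid along (z, y, x) in nm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiBox:
    """Half-open cuboid ROI: ``lo`` inclusive, ``hi`` exclusive, (z, y, x)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(i) for i in self.lo))
        object.__setattr__(self, "hi", tuple(int(i) for i in self.hi))
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("lo and hi must be (z, y, x) triples")
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"RoiBox requires lo < hi componentwise; got lo={self.lo} hi={self.hi}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


def read_stack(path: str | os.PathLike, voxel_size: Sequence[float]) -> VoxelGrid:
    """Read a multi-page TIFF, or a directory of single-slice TIFFs, as a z-stack.

    Slices in a directory are stacked in lexicographic filename order (the
    acquisition order of microscope exports).  Integer 8-bit and 16-bit data
    are preserved bit-exactly.

    Raises
    ------
    ValueError
        For an empty directory, mismatched slice shapes, or a non-positive
        voxel size.
    """
    voxel_size = _as_triple(voxel_size, "voxel_size")
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.suffix.lower() in (".tif", ".tiff") and f.is_file())
        if not files:
            raise ValueError(f"no TIFF slices found in directory {p}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or any(s.ndim != 2 for s in slices):
            raise ValueError(f"slices in {p} have mismatched shapes: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{p} is not a 2D/3D grayscale TIFF (got ndim={data.ndim})")
    return VoxelGrid(data=data, voxel_size=voxel_size)


def _write_sidecar(path: Path, grid_like: VoxelGrid) -> None:
    vz, vy, vx = grid_like.voxel_size
    oz, oy, ox = grid_like.origin_index
    meta = path.with_suffix(path.suffix + ".meta.txt")
    meta.write_text(
        f"voxel_size_z_nm: {vz}\nvoxel_size_y_nm: {vy}\nvoxel_size_x_nm: {vx}\n"
        f"origin_z: {oz}\norigin_y: {oy}\norigin_x: {ox}\n"
    )


def read_sidecar(path: str | os.PathLike) -> dict[str, float]:
    """Parse a ``key: value`` sidecar written next to a TIFF by this package."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            out[k.strip()] = float(v)
    return out


def _resolution_tags(voxel_size: tuple[float, float, float]) -> dict:
    # TIFF resolution is pixels per unit; use centimetres (1 cm = 1e7 nm).
    _, vy, vx = voxel_size
    return {
        "resolution": (1e7 / vx, 1e7 / vy),
        "resolutionunit": "CENTIMETER",
    }


def write_stack(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a grid as a multi-page grayscale TIFF plus a metadata sidecar."""
    p = Path(path)
    tifffile.imwrite(p, grid.data, photometric="minisblack",
                     **_resolution_tags(grid.voxel_size))
    _write_sidecar(p, grid)


def write_labels(labels: np.ndarray, voxel_size: Sequence[float],
                 path: str | os.PathLike) -> None:
    """Write an integer label volume as a 16-bit multi-page TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16")
    g = VoxelGrid(labels.astype(np.uint16), _as_triple(voxel_size, "voxel_size"))
    write_stack(g, path)


def write_table(records, path: str | os.PathLike) -> None:
    """Write measurement records as a TSV with a header row.

    ``records`` is a sequence of objects exposing ``as_row()`` (mapping) or
    plain mappings; an empty sequence yields a header-only file when the
    record type provides ``table_columns``.
    """
    import pandas as pd

    rows = []
    for r in records:
        rows.append(r.as_row() if hasattr(r, "as_row") else dict(r))
    if rows:
        df = pd.DataFrame(rows)
    else:
        from .morphometry import MorphometryRecord
        df = pd.DataFrame(columns=MorphometryRecord.table_columns())
    df.to_csv(path, sep="\t", index=False)


def crop(grid: VoxelGrid, box: RoiBox) -> VoxelGrid:
    """Cut a cuboid ROI out of a grid; voxel size is unchanged and the
    origin index is advanced by the box start so provenance is retained."""
    for l, h, n in zip(box.lo, box.hi, grid.shape):
        if l < 0 or h > n:
            raise IndexError(f"RoiBox {box.lo}..{box.hi} outside grid of shape {grid.shape}")
    sub = grid.data[box.slices()]
    origin = tuple(o + l for o, l in zip(grid.origin_index, box.lo))
    return VoxelGrid(data=sub.copy(), voxel_size=grid.voxel_size, origin_index=origin)
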