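"""End-to-end convenience pipeline: raw anisotropic stack -> morphometry record.

Chains the stages in acquisition order: maximum-entropy threshold, consecutive
-layer noise filter, largest component, isotropic resampling, per-slice
Gaussian smoothing, maximum-filter seeding, seeded diffusion, labeling, and
morphometry.  Each stage remains independently accessible in its own module;
this wrapper only fixes the plumbing between them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .imagestack import VoxelGrid
from .preprocess import SegmentationResult, segment_stack
from .domains import DomainLabeling, SeedSet, decompose
from .morphometry import MorphometryRecord, measure_structure

__all__ = ["PipelineResult", "analyze_stack"]


@dataclass
class PipelineResult:
    segmentation: SegmentationResult
    seeds: SeedSet
    labeling: DomainLabeling
    record: MorphometryRecord


def analyze_stack(grid: VoxelGrid, *, structure_id: str = "s0",
                  min_layers: int = 2, target_nm: float = 5.0,
                  sigma_nm: float = 5.0, cutoff_nm: float = 135.0,
                  sigma_init_nm: float = 10.0, eps: float = 1e-12,
                  max_steps: int = 1_000_000,
                  surface_method: str = "mesh") -> PipelineResult:
    """Run the full analysis on one raw ROI stack."""
    seg = segment_stack(grid, min_layers=min_layers, target_nm=target_nm,
                        sigma_nm=sigma_nm)
    seeds, labeling = decompose(seg.iso, seg.mask, cutoff_nm=cutoff_nm,
                                sigma_init_nm=sigma_init_nm, eps=eps,
                                max_steps=max_steps)
    record = measure_structure(seg.iso, seg.mask, labeling,
                               structure_id=structure_id,
                               surface_method=surface_method)
    return PipelineResult(segmentation=seg, seeds=seeds, labeling=labeling,
                          record=record)
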