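import numpy as np
import pytest
from scipy import ndimage

from emish3d.imagestack import VoxelGrid
from emish3d.preprocess import StructureMask, segment_stack
from emish3d.domains import (assign_labels, classify_structure, decompose,
                             diffuse, find_seeds, init_fields, smooth_structure)


def iso_mask(mask, voxel=5.0, threshold=0.0):
    return StructureMask(mask, (voxel,) * 3, threshold_value=threshold)


def bar_mask(nz=7, ny=7, nx=31):
    m = np.zeros((nz + 2, ny + 2, nx + 2), bool)
    m[1:nz + 1, 1:ny + 1, 1:nx + 1] = True
    return m


class TestSmoothStructure:
    def test_constant_structure_unchanged_inside(self):
        m = bar_mask()
        g = VoxelGrid(np.where(m, 100.0, 0.0), (5, 5, 5))
        out = smooth_structure(g, iso_mask(m), cutoff_nm=15)
        assert (out.data[m] == 100.0).all()

    def test_impulse_becomes_cube(self):
        m = np.ones((15, 15, 15), bool)
        data = np.zeros(m.shape)
        data[7, 7, 7] = 50.0
        out = smooth_structure(VoxelGrid(data, (5, 5, 5)), iso_mask(m), cutoff_nm=25)
        assert (out.data == 50.0).sum() == 5 ** 3
        assert (out.data[5:10, 5:10, 5:10] == 50.0).all()

    def test_matches_naive_sliding_window(self, rng):
        data = rng.uniform(0, 255, (20, 20, 20))
        m = np.ones(data.shape, bool)
        out = smooth_structure(VoxelGrid(data, (5, 5, 5)), iso_mask(m), cutoff_nm=15)
        r = 1  # edge 3 voxels
        padded = np.pad(data, r, constant_values=0)
        naive = np.empty_like(data)
        for z in range(20):
            for y in range(20):
                for x in range(20):
                    naive[z, y, x] = padded[z:z + 2 * r + 1, y:y + 2 * r + 1,
                                            x:x + 2 * r + 1].max()
        np.testing.assert_array_equal(out.data, naive)

    def test_cutoff_below_voxel_errors(self):
        g = VoxelGrid(np.ones((3, 3, 3)), (5, 5, 5))
        with pytest.raises(ValueError):
            smooth_structure(g, iso_mask(np.ones((3, 3, 3), bool)), cutoff_nm=2)


class TestFindSeeds:
    def test_constant_ball_single_plateau(self):
        m = np.zeros((21, 21, 21), bool)
        z, y, x = np.indices(m.shape) - 10
        m[z ** 2 + y ** 2 + x ** 2 <= 64] = True
        g = VoxelGrid(np.where(m, 100.0, 0.0), (5, 5, 5))
        seeds = find_seeds(smooth_structure(g, iso_mask(m), 15), iso_mask(m), 30)
        assert len(seeds) == 1

    def test_two_separated_maxima(self):
        m = bar_mask(nz=5, ny=5, nx=61)
        data = np.where(m, 10.0, 0.0)
        data[3, 3, 10] = 200.0
        data[3, 3, 50] = 150.0
        g = VoxelGrid(data, (5, 5, 5))
        seeds = find_seeds(smooth_structure(g, iso_mask(m), 25), iso_mask(m), 25)
        assert len(seeds) == 2
        assert seeds.points[0] == (3, 3, 10)   # descending density order
        assert seeds.points[1] == (3, 3, 50)

    def test_close_maxima_merge_to_higher(self):
        m = bar_mask(nz=5, ny=5, nx=61)
        data = np.where(m, 10.0, 0.0)
        data[3, 3, 20] = 200.0
        data[3, 3, 24] = 150.0   # 20 nm away at 5 nm voxels
        g = VoxelGrid(data, (5, 5, 5))
        seeds = find_seeds(smooth_structure(g, iso_mask(m), 15), iso_mask(m),
                           min_separation_nm=60)
        assert len(seeds) == 1
        assert seeds.points[0] == (3, 3, 20)

    def test_empty_mask_errors(self):
        g = VoxelGrid(np.ones((3, 3, 3)), (5, 5, 5))
        with pytest.raises(ValueError):
            find_seeds(g, iso_mask(np.zeros((3, 3, 3), bool)), 30)


class TestDiffusion:
    def _field(self, mask, data=None, seeds_pts=None, voxel=5.0):
        from emish3d.domains import SeedSet
        if data is None:
            data = np.where(mask, 100.0, 0.0)
        seeds = SeedSet(points=seeds_pts, densities=[0.0] * len(seeds_pts),
                        smoothing_cutoff_nm=135.0)
        return init_fields(seeds, iso_mask(mask, voxel), VoxelGrid(data, (voxel,) * 3))

    def test_init_unit_mass_and_argmax_at_seed(self):
        m = bar_mask()
        fld = self._field(m, seeds_pts=[(3, 3, 5), (3, 3, 25)])
        np.testing.assert_allclose(fld.masses(), 1.0, atol=1e-9)
        for i, pt in enumerate(fld.seeds.points):
            v = fld.volume(i)
            assert np.unravel_index(v.argmax(), v.shape) == pt

    def test_mass_conserved_and_nonnegative(self):
        m = bar_mask()
        fld = self._field(m, seeds_pts=[(3, 3, 5), (3, 3, 25)])
        out = diffuse(fld, iso_mask(m), eps=1e-12)
        np.testing.assert_allclose(out.masses(), 1.0, rtol=1e-6)
        assert (out.u >= 0).all()

    def test_symmetric_seeds_split_bar_at_midplane(self):
        m = bar_mask(nz=5, ny=5, nx=31)   # interior x: 1..31, midplane x=16
        fld = self._field(m, seeds_pts=[(3, 3, 6), (3, 3, 26)])
        out = diffuse(fld, iso_mask(m), eps=1e-12)
        u1 = out.volume(0)[m]
        u2 = out.volume(1)[m]
        mid = out.volume(0)[:, :, 16][m[:, :, 16]]
        mid2 = out.volume(1)[:, :, 16][m[:, :, 16]]
        np.testing.assert_allclose(mid, mid2, rtol=1e-6)

    def test_uniform_density_matches_geodesic_voronoi(self):
        """With constant D, diffusion labeling equals the in-mask nearest-seed
        geodesic partition (independent multi-source Dijkstra oracle on the
        26-connected mask graph with Euclidean step weights), away from the
        near-equidistant interface band."""
        import heapq

        m = np.zeros((12, 26, 26), bool)
        m[2:10, 2:24, 2:24] = True
        seeds_pts = [(5, 6, 6), (5, 18, 18), (7, 6, 20)]
        fld = self._field(m, seeds_pts=seeds_pts)
        out = diffuse(fld, iso_mask(m), eps=1e-12)
        labeling = assign_labels(out, iso_mask(m))

        offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
        weights = [np.sqrt(dz * dz + dy * dy + dx * dx) for dz, dy, dx in offs]
        # per-seed geodesic distance field (Dijkstra from each seed)
        dists = []
        for pt in seeds_pts:
            dist = np.full(m.shape, np.inf)
            dist[pt] = 0.0
            heap = [(0.0, pt)]
            while heap:
                d, v = heapq.heappop(heap)
                if d > dist[v]:
                    continue
                for o, w in zip(offs, weights):
                    u = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                    if all(0 <= ui < si for ui, si in zip(u, m.shape)) and m[u]:
                        nd = d + w
                        if nd < dist[u]:
                            dist[u] = nd
                            heapq.heappush(heap, (nd, u))
            dists.append(dist)
        dists = np.stack(dists)
        oracle = dists.argmin(axis=0) + 1
        srt = np.sort(dists, axis=0)
        # exclude the near-equidistant interface (within one diagonal step)
        with np.errstate(invalid="ignore"):
            gap = np.where(np.isfinite(srt[1]), srt[1] - srt[0], np.inf)
        sel = m & (gap > np.sqrt(3.0))
        agree = (labeling.labels[sel] == oracle[sel]).mean()
        assert agree == 1.0

    def test_nonconvergence_reports_empty_voxels(self):
        m = bar_mask(nz=3, ny=3, nx=41)
        fld = self._field(m, seeds_pts=[(2, 2, 2)])
        with pytest.raises(RuntimeError, match="voxels still empty"):
            diffuse(fld, iso_mask(m), eps=1e-12, max_steps=2)


class TestAssignAndClassify:
    def test_single_seed_labels_whole_mask(self):
        m = bar_mask(nz=3, ny=3, nx=11)
        from emish3d.domains import SeedSet
        seeds = SeedSet([(2, 2, 5)], [1.0], 135.0)
        fld = init_fields(seeds, iso_mask(m), VoxelGrid(np.where(m, 50.0, 0.0), (5,) * 3))
        out = diffuse(fld, iso_mask(m))
        labeling = assign_labels(out, iso_mask(m))
        assert (labeling.labels[m] == 1).all()
        assert labeling.residual_unlabeled == 0

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 3), (4, 4), (5, 4), (7, 4)])
    def test_classify(self, n, expected):
        assert classify_structure(n) == expected

    def test_classify_invalid(self):
        with pytest.raises(ValueError):
            classify_structure(0)


class TestEndToEnd:
    def test_three_lobe_phantom_recovery(self, small_phantom):
        p = small_phantom
        seg = segment_stack(p.grid)
        seeds, labeling = decompose(seg.iso, seg.mask)
        assert labeling.n_domains == 3
        # seed positions approximate the lobe centres (within 50 nm)
        centers = np.asarray(p.lobe_centers_nm)
        pts = np.asarray(seeds.points, float) * 5.0
        d = np.sqrt(((pts[:, None, :] - centers[None]) ** 2).sum(axis=2))
        assert (d.min(axis=1) < 50).all()

    def test_per_domain_jaccard_against_truth(self, small_phantom):
        from emish3d.preprocess import resample_isotropic
        from emish3d.imagestack import VoxelGrid as VG
        p = small_phantom
        seg = segment_stack(p.grid)
        _, labeling = decompose(seg.iso, seg.mask)
        n = labeling.n_domains
        # resample per-label indicators (interpolating integer labels would
        # fabricate intermediate labels at boundaries), then argmax
        fields = np.stack([
            resample_isotropic(
                VG((p.domain_labels == t).astype(np.float32),
                   p.spec.voxel_size), 5.0).data
            for t in range(1, n + 1)])
        truth = np.where(fields.max(axis=0) >= 0.5, fields.argmax(axis=0) + 1, 0)
        # match predicted to truth labels by majority overlap
        best = []
        for lab in range(1, n + 1):
            pred = labeling.labels == lab
            scores = []
            for t in range(1, n + 1):
                tr = truth == t
                scores.append((pred & tr).sum() / max((pred | tr).sum(), 1))
            best.append(max(scores))
        assert min(best) >= 0.8

    def test_determinism(self, small_phantom):
        p = small_phantom
        seg = segment_stack(p.grid)
        _, lab1 = decompose(seg.iso, seg.mask)
        _, lab2 = decompose(seg.iso, seg.mask)
        np.testing.assert_array_equal(lab1.labels, lab2.labels)

    def test_seed_count_monotone_in_cutoff(self, small_phantom):
        from emish3d.domains import find_seeds, smooth_structure
        p = small_phantom
        seg = segment_stack(p.grid)
        counts = []
        for cutoff in (45, 90, 135, 270):
            sm = smooth_structure(seg.iso, seg.mask, cutoff)
            counts.append(len(find_seeds(sm, seg.mask, cutoff / 2)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
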