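import numpy as np
import pytest
from skimage.measure import label as cc_label

import surseg as ss


def _assert_partition_valid(p):
    """Exact cover, contiguous ids, every supervoxel 26-connected."""
    assert p.labels.min() == 0 and p.labels.max() == p.K - 1
    assert (p.sizes() > 0).all()
    comps = cc_label(p.labels, connectivity=3, background=-1)
    # one connected component per supervoxel id
    assert comps.max() == p.K


class TestSlic:
    def test_constant_volume_gives_seed_lattice_cuboids(self):
        p = ss.slic_supervoxels(np.zeros((20, 20, 20)))
        assert p.K == 8
        assert set(p.sizes()) == {1000}
        _assert_partition_valid(p)

    def test_mean_size_tracks_seed_spacing(self):
        rng = np.random.default_rng(0)
        vol = ss.gaussian(rng.normal(size=(40, 40, 40)), 2.0)
        p = ss.slic_supervoxels(vol, seed_spacing=(10, 10, 10))
        expected_k = 4 * 4 * 4
        assert abs(p.K - expected_k) <= 0.2 * expected_k
        _assert_partition_valid(p)

    def test_boundary_recall_on_two_phase(self, two_phase, two_phase_partition):
        _, gt = two_phase
        recall = ss.boundary_recall(two_phase_partition.labels, gt)
        assert recall >= 0.95
        _assert_partition_valid(two_phase_partition)

    def test_comparable_to_reference_slic(self, two_phase):
        """Independent cross-check: skimage's SLIC on the same volume yields
        a similar region count; ours adheres to the phase boundary at least
        as well as a pure lattice would."""
        from skimage.segmentation import slic as sk_slic
        v, gt = two_phase
        ch = ss.gaussian(v, 1.0)
        ours = ss.slic_supervoxels(ch)
        theirs = sk_slic(np.asarray(ch, dtype=np.float64), n_segments=ours.K,
                         compactness=0.1, channel_axis=None)
        n_theirs = np.unique(theirs).size
        assert abs(ours.K - n_theirs) <= 0.5 * ours.K
        lattice = np.zeros_like(gt)
        # pure 10-voxel lattice partition ignores the boundary entirely
        z, y, x = np.indices(gt.shape) // 10
        lattice = (z * 16 + y * 4 + x).astype(np.int32)
        assert (ss.boundary_recall(ours.labels, gt)
                >= ss.boundary_recall(lattice, gt))

    def test_spacing_validation(self):
        with pytest.raises(ValueError):
            ss.slic_supervoxels(np.zeros((20, 20, 20)), seed_spacing=(1, 10, 10))
        with pytest.raises(ValueError):
            ss.slic_supervoxels(np.zeros((8, 8, 8)), seed_spacing=(10, 10, 10))
        with pytest.raises(ValueError):
            ss.slic_supervoxels(np.full((20, 20, 20), np.nan))

    def test_deterministic_no_rng(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(24, 24, 24))
        a = ss.slic_supervoxels(vol)
        b = ss.slic_supervoxels(vol)
        assert np.array_equal(a.labels, b.labels)


class TestRegionGraph:
    def test_split_plane_single_edge_exact_count(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[2:] = 1
        g = ss.build_region_graph(labels, connectivity=6)
        assert g.n_nodes == 2
        assert g.edges.tolist() == [[0, 1]]
        assert g.boundary_counts.tolist() == [16]

    def test_single_region_no_edges(self):
        g = ss.build_region_graph(np.zeros((3, 3, 3), dtype=np.int32))
        assert g.edges.shape == (0, 2)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force_neighbour_scan(self, connectivity):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 5, size=(5, 5, 5)).astype(np.int32)
        g = ss.build_region_graph(labels, connectivity=connectivity)
        # brute force over all voxel pairs
        offsets = {
            6: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
            18: [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, -1, 0),
                 (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
            26: [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, -1, 0),
                 (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1), (1, 1, 1),
                 (1, 1, -1), (1, -1, 1), (1, -1, -1)],
        }[connectivity]
        counts: dict[tuple, int] = {}
        nz, ny, nx = labels.shape
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    for dz, dy, dx in offsets:
                        z2, y2, x2 = z + dz, y + dy, x + dx
                        if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                            continue
                        a, b = labels[z, y, x], labels[z2, y2, x2]
                        if a != b:
                            key = (min(a, b), max(a, b))
                            counts[key] = counts.get(key, 0) + 1
        got = {tuple(e): int(c) for e, c in zip(g.edges, g.boundary_counts)}
        assert got == counts

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            ss.build_region_graph(np.zeros((3, 3, 3), dtype=np.int32), 4)

    def test_checkerboard_blocks(self):
        labels = np.indices((4, 2, 2)).sum(axis=0) % 2
        g = ss.build_region_graph(labels.astype(np.int32), connectivity=6)
        assert g.n_nodes == 2 and len(g.edges) == 1


class TestMegavoxels:
    def _partition_and_desc(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(8), 8).reshape(4, 4, 4).astype(np.int32)
        p = ss.SupervoxelPartition(labels=labels, K=8, seed_spacing=(2, 2, 2),
                                   compactness=30.0)
        desc = rng.normal(size=(8, 3))
        return p, desc

    def test_tiny_threshold_is_identity(self):
        p, desc = self._partition_and_desc()
        mv = ss.megavoxels(p, desc, similarity_threshold=1e-12)
        assert mv.M == p.K

    def test_huge_threshold_single_megavoxel(self):
        p, desc = self._partition_and_desc()
        mv = ss.megavoxels(p, desc, similarity_threshold=1e12)
        assert mv.M == 1

    def test_two_phase_recovers_two_megavoxels(self, two_phase,
                                               two_phase_partition):
        v, gt = two_phase
        p = two_phase_partition
        fs = ss.FeatureStack(shape=v.shape)
        fs.add("g", ss.gaussian(v, 1.0))
        d = ss.supervoxel_mean(fs, p)
        mv = ss.megavoxels(p, d.X, similarity_threshold=0.5)
        assert mv.M == 2
        resolved = mv.resolve(p)
        # megavoxel boundary equals phase boundary up to supervoxel precision
        sv_phase = np.round(d.X[:, 0]).astype(int)
        expected = sv_phase[p.labels]
        agree = np.mean((resolved == resolved[0, 0, 0]) == (expected == 0))
        assert agree > 0.99

    def test_megavoxels_are_connected(self, two_phase, two_phase_partition):
        v, _ = two_phase
        p = two_phase_partition
        fs = ss.FeatureStack(shape=v.shape)
        fs.add("g", ss.gaussian(v, 1.0))
        d = ss.supervoxel_mean(fs, p)
        mv = ss.megavoxels(p, d.X, similarity_threshold=0.5)
        resolved = mv.resolve(p)
        comps = cc_label(resolved, connectivity=3, background=-1)
        assert comps.max() == mv.M

    def test_hierarchy_consistency(self, two_phase, two_phase_partition):
        """Every megavoxel is a union of whole supervoxels."""
        v, _ = two_phase
        p = two_phase_partition
        fs = ss.FeatureStack(shape=v.shape)
        fs.add("g", ss.gaussian(v, 1.0))
        mv = ss.megavoxels(p, ss.supervoxel_mean(fs, p).X, 0.5)
        resolved = mv.resolve(p)
        for sv in range(p.K):
            vals = np.unique(resolved[p.labels == sv])
            assert vals.size == 1

    def test_min_size_enforced(self):
        p, desc = self._partition_and_desc()
        mv = ss.megavoxels(p, desc, similarity_threshold=1e-12, min_size=2)
        counts = np.bincount(mv.sv_to_mv)
        assert (counts >= 2).all()

    def test_threshold_validation(self):
        p, desc = self._partition_and_desc()
        with pytest.raises(ValueError):
            ss.megavoxels(p, desc, similarity_threshold=0.0)
        with pytest.raises(ValueError):
            ss.megavoxels(p, desc[:4], similarity_threshold=1.0)
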