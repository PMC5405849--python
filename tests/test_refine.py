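import itertools

import numpy as np
import pytest

import surseg as ss
from surseg.model import ProbabilityField
from surseg.refine import MRFProblem, build_mrf, energy, solve_mrf


def _random_problem(rng, n_max=12, n_labels=2, edge_p=0.4):
    n = int(rng.integers(2, n_max + 1))
    unary = rng.uniform(0, 2, (n, n_labels))
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                      if rng.random() < edge_p], dtype=np.int64).reshape(-1, 2)
    w = rng.uniform(0, 1, len(edges))
    return MRFProblem(unary=unary, edges=edges, weights=w,
                      lam=float(rng.uniform(0.2, 2.0)),
                      label_ids=np.arange(n_labels))


def _brute_force_minimum(m):
    best = np.inf
    for c in itertools.product(range(m.n_labels), repeat=m.n_nodes):
        best = min(best, energy(m, np.array(c)))
    return best


class TestBuildMRF:
    def _pf(self, probs):
        probs = np.asarray(probs, dtype=float)
        return ProbabilityField(probs=probs, label_ids=np.arange(probs.shape[1]))

    def test_two_node_hand_formula(self):
        """w_pq = (b/b_max) * exp(-d^2 / (2 sigma^2)) evaluated by hand."""
        pf = self._pf([[0.9, 0.1], [0.2, 0.8]])
        g = ss.RegionGraph(n_nodes=2, edges=np.array([[0, 1]]),
                           boundary_counts=np.array([4]))
        desc = ss.DescriptorMatrix(X=np.array([[0.0], [2.0]]), method="mean")
        m = build_mrf(pf, g, desc, lam=1.5, sigma_w=2.0)
        assert np.allclose(m.unary, -np.log([[0.9, 0.1], [0.2, 0.8]]))
        expected_w = 1.0 * np.exp(-4.0 / (2 * 4.0))
        assert m.weights[0] == pytest.approx(expected_w)
        assert m.lam == 1.5

    def test_identical_descriptors_uniform_weights(self):
        pf = self._pf(np.full((4, 2), 0.5))
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        g = ss.RegionGraph(n_nodes=4, edges=edges,
                           boundary_counts=np.array([3, 3, 3]))
        desc = ss.DescriptorMatrix(X=np.ones((4, 2)), method="mean")
        m = build_mrf(pf, g, desc)
        assert np.allclose(m.weights, m.weights[0])

    def test_certain_probability_zero_unary(self):
        pf = self._pf([[1.0, 0.0], [0.0, 1.0]])
        g = ss.RegionGraph(n_nodes=2, edges=np.array([[0, 1]]),
                           boundary_counts=np.array([1]))
        desc = ss.DescriptorMatrix(X=np.zeros((2, 1)), method="mean")
        m = build_mrf(pf, g, desc)
        assert m.unary[0, 0] == 0.0
        assert np.isfinite(m.unary).all()  # p=0 clamped by the floor

    def test_row_mismatch(self):
        pf = self._pf(np.full((3, 2), 0.5))
        g = ss.RegionGraph(n_nodes=2, edges=np.empty((0, 2), dtype=np.int64),
                           boundary_counts=np.empty(0, dtype=np.int64))
        desc = ss.DescriptorMatrix(X=np.zeros((3, 1)), method="mean")
        with pytest.raises(ValueError):
            build_mrf(pf, g, desc)


class TestEnergy:
    def test_single_node(self):
        m = MRFProblem(unary=np.array([[0.3, 0.9]]),
                       edges=np.empty((0, 2), dtype=np.int64),
                       weights=np.empty(0), lam=1.0, label_ids=np.arange(2))
        assert energy(m, np.array([0])) == pytest.approx(0.3)

    def test_two_node_agreement_unaries_only(self):
        m = MRFProblem(unary=np.array([[0.5, 1.0], [0.25, 2.0]]),
                       edges=np.array([[0, 1]]), weights=np.array([10.0]),
                       lam=1.0, label_ids=np.arange(2))
        assert energy(m, np.array([0, 0])) == pytest.approx(0.75)

    def test_triangle_hand_computed(self):
        unary = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        edges = np.array([[0, 1], [1, 2], [0, 2]])
        w = np.array([1.0, 2.0, 3.0])
        m = MRFProblem(unary=unary, edges=edges, weights=w, lam=0.5,
                       label_ids=np.arange(2))
        # labelling (0,1,0): unaries 0.1+0.4+0.5; disagreeing edges 01 and 12
        assert energy(m, np.array([0, 1, 0])) == pytest.approx(
            1.0 + 0.5 * (1.0 + 2.0))

    def test_invalid_label(self):
        m = MRFProblem(unary=np.array([[0.1, 0.2]]),
                       edges=np.empty((0, 2), dtype=np.int64),
                       weights=np.empty(0), lam=1.0, label_ids=np.arange(2))
        with pytest.raises(ValueError):
            energy(m, np.array([2]))


class TestSolve:
    def test_lambda_zero_is_argmax_bit_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = _random_problem(rng, n_labels=int(rng.integers(2, 5)))
            m.lam = 0.0
            lab, e = solve_mrf(m)
            assert np.array_equal(lab, np.argmin(m.unary, axis=1))

    def test_two_label_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            m = _random_problem(rng, n_labels=2)
            _, e = solve_mrf(m)
            assert e == pytest.approx(_brute_force_minimum(m), abs=1e-9)

    def test_three_label_not_worse_than_icm(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = _random_problem(rng, n_labels=3)
            _, ea = solve_mrf(m, "alpha_expansion")
            _, ei = solve_mrf(m, "icm")
            assert ea <= ei + 1e-9

    def test_huge_lambda_single_label_lowest_total_unary(self):
        rng = np.random.default_rng(3)
        n, L = 6, 3
        unary = rng.uniform(0, 1, (n, L))
        edges = np.array([(i, i + 1) for i in range(n - 1)])  # connected path
        m = MRFProblem(unary=unary, edges=edges, weights=np.ones(n - 1),
                       lam=1e6, label_ids=np.arange(L))
        lab, e = solve_mrf(m)
        assert np.unique(lab).size == 1
        best_const = min(unary[:, l].sum() for l in range(L))
        assert e == pytest.approx(best_const, abs=1e-9)

    def test_energy_never_above_argmax_energy(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = _random_problem(rng, n_labels=3)
            _, e = solve_mrf(m)
            assert e <= energy(m, np.argmin(m.unary, axis=1)) + 1e-12

    def test_reported_energy_is_recomputed(self):
        rng = np.random.default_rng(5)
        m = _random_problem(rng)
        lab, e = solve_mrf(m)
        assert e == pytest.approx(energy(m, lab), abs=1e-12)

    def test_unknown_method(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            solve_mrf(_random_problem(rng), method="fastpd")


class TestRefineToVoxels:
    def test_constant_labelling(self, block_partition):
        grid = ss.refine_to_voxels(np.array([3, 3]), block_partition)
        assert (grid == 3).all()

    def test_histogram_conservation(self, block_partition):
        lab = np.array([0, 1])
        grid = ss.refine_to_voxels(lab, block_partition)
        sizes = block_partition.sizes()
        assert np.bincount(grid.ravel()).tolist() == sizes.tolist()

    def test_spot_lookup_and_label_ids(self, block_partition):
        grid = ss.refine_to_voxels(np.array([1, 0]), block_partition,
                                   label_ids=np.array([10, 20]))
        assert grid[0, 0, 0] == 20 and grid[3, 3, 3] == 10

    def test_incomplete_labelling(self, block_partition):
        with pytest.raises(ValueError):
            ss.refine_to_voxels(np.array([0]), block_partition)


def test_refinement_cleans_label_flip_noise():
    """Flipping probabilities of scattered supervoxels is repaired by the
    MRF: refined voxel accuracy >= raw argmax accuracy."""
    rng = np.random.default_rng(7)
    v, gt = ss.make_two_phase((32, 32, 32), seed=3)
    p = ss.slic_supervoxels(ss.gaussian(v, 1.0), seed_spacing=(8, 8, 8))
    g = ss.build_region_graph(p.labels)
    fs = ss.FeatureStack(shape=v.shape)
    fs.add("g", ss.gaussian(v, 1.0))
    d = ss.supervoxel_mean(fs, p)
    truth = np.array([int(round(x)) for x in d.X[:, 0]])
    probs = np.where(truth[:, None] == np.arange(2)[None, :], 0.9, 0.1)
    flip = rng.random(p.K) < 0.15
    probs[flip] = probs[flip, ::-1]
    pf = ProbabilityField(probs=probs, label_ids=np.arange(2))
    m = build_mrf(pf, g, d, lam=2.0)
    lab, _ = solve_mrf(m)
    refined = ss.refine_to_voxels(lab, p)
    raw = ss.refine_to_voxels(np.argmax(probs, axis=1), p)
    gt_sv = ss.refine_to_voxels(truth, p)
    acc_ref = np.mean(refined == gt_sv)
    acc_raw = np.mean(raw == gt_sv)
    assert acc_ref >= acc_raw
    assert acc_ref > 0.95
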