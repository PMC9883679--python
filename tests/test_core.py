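import numpy as np
import pytest

import mndiff as m
from conftest import random_instance


class TestNeighborTopk:
    def test_triangle_k1_takes_neighbour_max(self, triangle):
        X = np.array([[0.2], [0.9], [0.4]])  # A, B, C
        T = m.neighbor_topk(X, triangle, k=1).T
        assert T[triangle.index_of("A"), 0] == pytest.approx(0.9)

    def test_triangle_k2_sums_two_largest(self, triangle):
        X = np.array([[0.2], [0.9], [0.4]])
        T = m.neighbor_topk(X, triangle, k=2).T
        assert T[triangle.index_of("A"), 0] == pytest.approx(1.3)

    def test_star_clamps_k_to_degree(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        net = m.from_edges(edges)
        vals = {"hub": 0.5, "leaf0": 0.9, "leaf1": 0.8, "leaf2": 0.7,
                "leaf3": 0.2, "leaf4": 0.1}
        X = np.array([[vals[g]] for g in net.genes])
        res = m.neighbor_topk(X, net, k=3)
        assert res.T[net.index_of("hub"), 0] == pytest.approx(0.9 + 0.8 + 0.7)
        # leaves have degree 1 -> k_i = 1 -> the hub's own value
        assert res.T[net.index_of("leaf3"), 0] == pytest.approx(0.5)
        assert res.k_i[net.index_of("leaf3")] == 1

    def test_isolated_gene_gets_zero(self):
        net = m.from_edges([("A", "B"), ("Z", "Z")])
        res = m.neighbor_topk(np.ones((3, 1)), net, k=3)
        assert res.T[net.index_of("Z"), 0] == 0
        assert res.k_i[net.index_of("Z")] == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(50):
            net, sm = random_instance(rng, n_min=8, n_max=25, p=0.25)
            if net.degrees.max(initial=0) > 12:
                continue
            Xstar = m.column_normalize(sm.X)
            fast = m.neighbor_topk(Xstar, net, k=k).T
            slow = m.neighbor_topk_bruteforce(Xstar, net, k=k)
            assert np.array_equal(fast, slow)

    def test_bruteforce_guards(self, triangle):
        with pytest.raises(ValueError, match="k <= 4"):
            m.neighbor_topk_bruteforce(np.ones((3, 1)), triangle, k=5)


class TestMndScore:
    def test_two_layer_arithmetic(self):
        res = m.mnd_score(np.array([[0.5, 1.0]]), np.array([[1.2, 0.8]]),
                          np.array([2]))
        assert res.mND[0] == pytest.approx(0.5 * 1.5 * 2.0)

    def test_single_layer_reduction(self):
        res = m.mnd_score(np.array([[0.6]]), np.array([[0.9]]), np.array([3]))
        assert res.mND[0] == pytest.approx(0.6 * 0.9 / 3)

    def test_zero_ki_gives_zero(self):
        res = m.mnd_score(np.array([[1.0]]), np.array([[0.0]]), np.array([0]))
        assert res.mND[0] == 0

    def test_bounded_by_L_squared(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            net, sm = random_instance(rng)
            Xstar = m.diffuse_closed_form(sm, m.normalize(net)).Xstar
            summ = m.neighbor_topk(Xstar, net, k=3)
            res = m.mnd_score(Xstar, summ.T, summ.k_i)
            L = sm.n_layers
            assert np.all(res.mND >= 0) and np.all(res.mND <= L**2 + 1e-12)
            assert np.all(summ.T >= 0) and np.all(summ.T <= summ.k_i[:, None] + 1e-12)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            m.mnd_score(np.ones((2, 2)), np.ones((2, 2)), np.array([1, 1]),
                        layer_weights=np.array([1.0, 0.0]))

    def test_layer_weights_scale_the_sums(self):
        x = np.array([[0.5, 1.0]])
        T = np.array([[1.2, 0.8]])
        res = m.mnd_score(x, T, np.array([2]), layer_weights=np.array([2.0, 1.0]))
        assert res.mND[0] == pytest.approx((1 / 2) * (1.0 + 1.0) * (2.4 + 0.8))


class TestTransforms:
    def test_mndp_values(self):
        assert m.mndp(np.array([0.001]), np.array([2.0]))[0] == pytest.approx(6.0)
        assert m.mndp(np.array([1.0]), np.array([5.0]))[0] == 0.0
        assert m.mndp(np.array([0.1]), np.array([0.5]))[0] == pytest.approx(0.5)

    def test_mndp_rejects_zero_p(self):
        with pytest.raises(ValueError):
            m.mndp(np.array([0.0]), np.array([1.0]))

    def test_tp_values_and_tie_breaking(self):
        tp = m.tp_score(np.array([[1.5], [1.5]]), np.array([[0.01], [0.5]]))
        assert tp[0, 0] == pytest.approx(3.0)
        assert tp[0, 0] != tp[1, 0]  # equal T, different significance
        assert m.tp_score(np.array([[2.0]]), np.array([[1.0]]))[0, 0] == 0.0


class TestPermutationSignificance:
    def _setup(self, seed=0, n=40, L=2):
        rng = np.random.default_rng(seed)
        net, sm = random_instance(rng, n_min=n, n_max=n, L=L)
        return net, sm, m.normalize(net)

    def test_p_floor_is_one_over_P(self):
        net, sm, W = self._setup()
        res, summ, _ = m.permutation_significance(sm, W, net, n_perm=20, seed=1)
        assert np.all(res.p >= 1 / 20 - 1e-15) and np.all(res.p <= 1)
        assert np.all(summ.pt >= 1 / 20 - 1e-15) and np.all(summ.pt <= 1)

    def test_constant_scores_give_p_one(self):
        net, sm, W = self._setup()
        const = m.ScoreMatrix(sm.genes, sm.layers, np.ones_like(sm.X))
        res, summ, _ = m.permutation_significance(const, W, net, n_perm=10, seed=2)
        assert np.all(res.p == 1.0)
        assert np.all(res.mNDp == 0.0)

    def test_identical_seed_reproduces_bitwise(self):
        net, sm, W = self._setup()
        a = m.permutation_significance(sm, W, net, n_perm=15, seed=3)
        b = m.permutation_significance(sm, W, net, n_perm=15, seed=3)
        assert np.array_equal(a[0].p, b[0].p)
        assert np.array_equal(a[1].pt, b[1].pt)

    def test_schemes_differ_but_both_valid(self):
        net, sm, W = self._setup(seed=5)
        joint = m.permutation_significance(sm, W, net, n_perm=30, seed=4,
                                           scheme="joint-rows")[0].p
        per = m.permutation_significance(sm, W, net, n_perm=30, seed=4,
                                         scheme="per-layer")[0].p
        assert not np.array_equal(joint, per)

    def test_kernel_and_iterative_routes_agree(self):
        net, sm, W = self._setup(seed=6)
        a = m.permutation_significance(sm, W, net, n_perm=10, seed=7, use_kernel=True)
        b = m.permutation_significance(sm, W, net, n_perm=10, seed=7, use_kernel=False)
        assert np.array_equal(a[0].p, b[0].p)
        assert np.max(np.abs(a[0].mND - b[0].mND)) < 1e-5

    def test_n_perm_one_gives_all_ones(self):
        net, sm, W = self._setup()
        res, _, _ = m.permutation_significance(sm, W, net, n_perm=1, seed=0)
        assert np.all(res.p == 1.0)

    def test_invalid_args_rejected(self):
        net, sm, W = self._setup()
        with pytest.raises(ValueError, match="n_perm"):
            m.permutation_significance(sm, W, net, n_perm=0)
        with pytest.raises(ValueError, match="scheme"):
            m.permutation_significance(sm, W, net, n_perm=2, scheme="bogus")

    def test_layer_scale_invariance_of_mnd(self):
        net, sm, W = self._setup(seed=8)
        res_a = m.permutation_significance(sm, W, net, n_perm=5, seed=9)[0]
        scaled = m.ScoreMatrix(sm.genes, sm.layers, sm.X * np.array([100.0, 0.1]))
        res_b = m.permutation_significance(scaled, W, net, n_perm=5, seed=9)[0]
        assert np.max(np.abs(res_a.mND - res_b.mND)) < 1e-9


class TestRunMnd:
    def test_requires_alignment(self):
        net = m.from_edges([("A", "B")])
        sm = m.ScoreMatrix(["B", "A"], ["L1"], [[1.0], [2.0]])
        with pytest.raises(ValueError, match="aligned"):
            m.run_mnd(sm, net, n_perm=2)

    def test_full_run_outputs_consistent(self):
        rng = np.random.default_rng(31)
        net, sm = random_instance(rng, n_min=30, n_max=30)
        res, summ, Xstar = m.run_mnd(sm, net, n_perm=25, seed=12)
        assert np.allclose(res.mNDp, -np.log10(res.p) * res.mND)
        assert np.allclose(summ.tp, -np.log10(summ.pt) * summ.T)
        assert Xstar.shape == sm.X.shape
        assert Xstar.max(axis=0) == pytest.approx([1.0, 1.0])
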