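"""Inference-method unit tests against closed forms and brute-force oracles."""

import numpy as np
import pytest

from disimir import ExpressionMatrix
from disimir.network_inference import (ConsensusConfig,
                                       MutualInformationMatrix, aracne, clr,
                                       consensus, discretize, genie3, mrnet,
                                       mrnetb, mutual_information_matrix,
                                       scale_network)
from disimir.network_inference import WeightedDirectedNetwork

from conftest import aracne_oracle, mi_oracle


def make_mim(mat):
    mat = np.asarray(mat, dtype=float)
    np.fill_diagonal(mat, 0.0)
    return MutualInformationMatrix([f"m{i}" for i in range(len(mat))], mat)


class TestDiscretize:
    def test_median_split(self):
        out = discretize(np.array([[1.0, 2.0, 3.0, 4.0]]), 2)
        np.testing.assert_array_equal(out[0], [0, 0, 1, 1])

    def test_constant_row_all_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = discretize(np.array([[2.0] * 6, [1, 2, 3, 4, 5, 6.0]]), 2)
        np.testing.assert_array_equal(out[0], 0)
        assert "constant" in caplog.text

    def test_auto_bins_floor_sqrt(self):
        out = discretize(np.tile(np.arange(9.0), (2, 1)), "auto")
        assert out.max() == 2  # floor(sqrt(9)) = 3 bins -> levels 0..2

    def test_equal_frequency(self):
        out = discretize(np.arange(12.0)[None, :], 3)
        assert all((out[0] == b).sum() == 4 for b in range(3))


class TestMutualInformation:
    def test_identical_rows_log2_plus_correction(self):
        disc = np.array([[0, 1, 0, 1, 0, 1, 0, 1]] * 2)
        mim = mutual_information_matrix(disc)
        # plug-in MI = ln 2; MM term = (2 + 2 - 2 - 1) / (2 * 8)
        assert mim.mim[0, 1] == pytest.approx(np.log(2) + 1 / 16, abs=1e-12)

    def test_independent_rows_near_zero(self):
        rng = np.random.default_rng(3)
        disc = rng.integers(0, 2, size=(2, 4000))
        mim = mutual_information_matrix(disc)
        assert mim.mim[0, 1] < 0.01

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        disc = rng.integers(0, 3, size=(3, 8))
        mim = mutual_information_matrix(disc)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mim.mim[i, j] == pytest.approx(
                    mi_oracle(disc[i], disc[j]), abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            mutual_information_matrix(np.zeros((2, 2), dtype=int))

    def test_invariants_on_construction(self):
        with pytest.raises(ValueError, match="symmetric"):
            make_mim([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="negative"):
            make_mim([[0, -1], [-1, 0]])


class TestCLR:
    def test_flat_mim_gives_zero_network(self):
        net = clr(make_mim(np.full((4, 4), 0.5)))
        assert not net.weights.any()

    def test_elevated_pair_dominates(self):
        m = np.full((4, 4), 0.2)
        m[0, 1] = m[1, 0] = 0.9
        net = clr(make_mim(m))
        assert net.weights[0, 1] == net.weights.max()

    def test_closed_form_z(self):
        m = np.full((4, 4), 0.2)
        m[0, 1] = m[1, 0] = 0.9
        np.fill_diagonal(m, 0.0)
        row = m[0, [1, 2, 3]]
        z = max(0.0, (0.9 - row.mean()) / row.std())
        expected = np.sqrt(2) * z  # symmetric instance: z_i = z_j
        net = clr(make_mim(m))
        assert net.weights[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_row_logged(self, caplog):
        with caplog.at_level("WARNING"):
            clr(make_mim(np.full((3, 3), 0.4)))
        assert "zero MI variance" in caplog.text


class TestAracne:
    def test_chain_indirect_edge_removed(self):
        m = np.array([[0.0, 0.8, 0.2], [0.8, 0.0, 0.7], [0.2, 0.7, 0.0]])
        net = aracne(make_mim(m), 0.0)
        assert net.weights[0, 2] == 0.0
        assert net.weights[0, 1] == 0.8 and net.weights[1, 2] == 0.7

    def test_all_equal_triangle_kept(self):
        m = np.full((3, 3), 0.5)
        net = aracne(make_mim(m), 0.0)
        assert (net.weights[~np.eye(3, dtype=bool)] == 0.5).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        net = aracne(make_mim(m), 0.0)
        np.testing.assert_allclose(net.weights, aracne_oracle(m), atol=1e-12)

    def test_pruning_never_adds(self):
        rng = np.random.default_rng(9)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        net = aracne(make_mim(m), 0.0)
        assert set(zip(*np.nonzero(net.weights))) <= \
            set(zip(*np.nonzero(m)))


class TestMRNET:
    def test_two_variables_weight_is_mi(self):
        m = np.array([[0.0, 0.42], [0.42, 0.0]])
        net = mrnet(make_mim(m))
        assert net.weights[0, 1] == pytest.approx(0.42)

    def test_three_variable_manual_forward_selection(self):
        # target = 2; relevances 0.8 (var0), 0.5 (var1); red(0,1) = 0.6
        m = np.array([[0.0, 0.6, 0.8],
                      [0.6, 0.0, 0.5],
                      [0.8, 0.5, 0.0]])
        net = mrnet(make_mim(m))
        # var0 picked first with score 0.8; var1 then scores 0.5 - 0.6 < 0
        assert net.weights[0, 2] == pytest.approx(0.8)
        assert net.weights[1, 2] == pytest.approx(
            max(net.weights[1, 2], 0.0))
        # symmetrized by max; check the raw target-2 column logic via
        # the known selection order: weight[1,2] comes from target 0/1 runs
        from disimir.network_inference import _mrmr_forward
        scores = _mrmr_forward(m[:, 2], m, 2)
        assert scores[0] == pytest.approx(0.8)
        assert scores[1] == pytest.approx(0.0)  # max(0, 0.5 - 0.6)

    def test_mrnetb_two_variables(self):
        m = np.array([[0.0, 0.42], [0.42, 0.0]])
        net = mrnetb(make_mim(m))
        assert net.weights[0, 1] == pytest.approx(0.42)

    def test_forward_selection_matches_exhaustive_first_pick(self):
        # the first variable chosen must be the relevance argmax —
        # exhaustively true for MRMR on any instance without ties
        rng = np.random.default_rng(2)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        from disimir.network_inference import _mrmr_forward
        for j in range(4):
            scores = _mrmr_forward(m[:, j], m, j)
            others = [i for i in range(4) if i != j]
            best = max(others, key=lambda i: m[i, j])
            assert scores[best] == pytest.approx(m[best, j])


class TestGENIE3:
    def make_planted(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 40))
        x[4] = x[0]  # target row copies predictor 0 exactly
        return ExpressionMatrix([f"m{i}" for i in range(5)],
                                [f"s{j}" for j in range(40)], x)

    def test_planted_predictor_dominates(self):
        net = genie3(self.make_planted(), n_trees=100, k="all", seed=1)
        assert net.weights[0, 4] > 0.8

    def test_deterministic_given_seed(self):
        em = self.make_planted(3)
        a = genie3(em, n_trees=20, k="sqrt", seed=5)
        b = genie3(em, n_trees=20, k="sqrt", seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_noise_importances_near_uniform(self):
        rng = np.random.default_rng(8)
        em = ExpressionMatrix([f"m{i}" for i in range(6)],
                              [f"s{j}" for j in range(50)],
                              rng.normal(size=(6, 50)))
        net = genie3(em, n_trees=100, k="sqrt", seed=2)
        # per target importances sum to 1 over 5 predictors; none should
        # exceed 5x the uniform share
        assert net.weights.max() < 5 / 5

    def test_too_few_trees(self):
        with pytest.raises(ValueError, match="n_trees"):
            genie3(self.make_planted(), n_trees=5, k="sqrt", seed=0)


class TestScaleAndConsensus:
    def test_min_max_affine(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 0] = 5.0, 10.0  # off-diagonal range {0, 5, 10}
        net = scale_network(WeightedDirectedNetwork(list("abc"), w))
        assert net.weights[0, 1] == 0.5 and net.weights[1, 0] == 1.0

    def test_constant_nonzero_scales_to_zero(self, caplog):
        w = np.full((3, 3), 0.4)
        with caplog.at_level("WARNING"):
            net = scale_network(WeightedDirectedNetwork(list("abc"), w))
        assert not net.weights.any()

    def test_already_unit_range_unchanged(self):
        w = np.array([[0, 1.0, 0.3], [0.0, 0, 0.5], [0.2, 0.0, 0]])
        net = scale_network(WeightedDirectedNetwork(list("abc"), w))
        np.testing.assert_allclose(net.weights, w)

    def _edge_nets(self, values):
        nets = []
        for v in values:
            w = np.zeros((2, 2))
            w[0, 1] = v
            nets.append(WeightedDirectedNetwork(["a", "b"], w))
        return nets

    def test_mean_of_equal_edges_retained(self):
        net = consensus(self._edge_nets([0.8] * 5), ConsensusConfig())
        assert net.weights[0, 1] == pytest.approx(0.8)

    def test_boundary_inclusive(self):
        net = consensus(self._edge_nets([1, 1, 1, 0.5, 0]),
                        ConsensusConfig())
        assert net.weights[0, 1] == pytest.approx(0.7)

    def test_below_threshold_pruned(self):
        net = consensus(self._edge_nets([1, 1, 1, 0.4, 0]),
                        ConsensusConfig())
        assert net.weights[0, 1] == 0.0

    def test_mismatched_ids_rejected(self):
        a = WeightedDirectedNetwork(["a", "b"], np.zeros((2, 2)))
        b = WeightedDirectedNetwork(["b", "a"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="mismatched"):
            consensus([a, a, a, a, b], ConsensusConfig())

    def test_consensus_weights_zero_or_above_threshold(self):
        rng = np.random.default_rng(4)
        nets = [WeightedDirectedNetwork(
            list("abcde"), rng.random((5, 5))) for _ in range(5)]
        net = consensus(nets, ConsensusConfig())
        w = net.weights[net.weights > 0]
        assert (w >= 0.7).all() and (w <= 1.0).all()


def test_pipeline_determinism(small_expression):
    cfg = ConsensusConfig(genie3_n_trees=20, seed=13)
    from disimir.network_inference import consensus_network
    a = consensus_network(small_expression, cfg)
    b = consensus_network(small_expression, cfg)
    np.testing.assert_array_equal(a.weights, b.weights)


def test_single_hub_edges_rank_high_before_pruning():
    """A hub driving 5 targets should put its edges in the top decile of
    consensus weights before thresholding (50 samples, mild noise)."""
    from disimir.network_inference import consensus_network
    hits = 0
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        m, n = 20, 50
        x = rng.normal(size=(m, n))
        for t in range(1, 6):
            x[t] = x[0] + 0.3 * rng.normal(size=n)
        em = ExpressionMatrix([f"m{i}" for i in range(m)],
                              [f"s{j}" for j in range(n)], x + 10)
        cfg = ConsensusConfig(threshold=0.3, genie3_n_trees=50, seed=seed)
        disc_cfg = ConsensusConfig(threshold=0.3, genie3_n_trees=50,
                                   seed=seed)
        net = consensus_network(em, disc_cfg)
        # rank hub edges among all off-diagonal mean weights pre-pruning
        from disimir.network_inference import (aracne, clr,
                                               discretize, genie3, mrnet,
                                               mrnetb,
                                               mutual_information_matrix,
                                               scale_network)
        disc = discretize(em, "auto")
        mim = mutual_information_matrix(disc, list(em.mirna_ids))
        mats = [scale_network(f(mim)).weights
                for f in (clr, mrnet, mrnetb, lambda x: aracne(x, 0.0))]
        mats.append(scale_network(
            genie3(em, 50, "all", seed)).weights)
        mean = np.mean(mats, axis=0)
        off = mean[~np.eye(m, dtype=bool)]
        decile = np.quantile(off, 0.9)
        if all(mean[0, t] >= decile for t in range(1, 6)):
            hits += 1
    assert hits >= 2
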