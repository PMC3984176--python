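"""Two-block PLS core: SVD, scores, r_PLS, and the permutation test."""

import numpy as np
import pytest

import phylopls as pp
from conftest import random_traits, star_tree


def orthonormal_columns(n, k, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


class TestPartition:
    def setup_method(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4))
        self.R = pp.EvolCovariance(R=A @ A.T)

    def test_contiguous_blocks(self):
        bs = pp.BlockSpec(block1=(0, 1), block2=(2, 3))
        R11, R12, R22 = pp.partition(self.R, bs)
        assert np.array_equal(R12, self.R.R[:2, 2:])
        assert np.array_equal(R11, self.R.R[:2, :2])

    def test_non_contiguous_lookup(self):
        bs = pp.BlockSpec(block1=(0, 2), block2=(1, 3))
        _, R12, _ = pp.partition(self.R, bs)
        for a, i in enumerate((0, 2)):
            for b, j in enumerate((1, 3)):
                assert R12[a, b] == self.R.R[i, j]

    def test_swapped_blocks_transpose(self):
        bs = pp.BlockSpec(block1=(0, 1), block2=(2, 3))
        _, R12, _ = pp.partition(self.R, bs)
        _, R21, _ = pp.partition(self.R, bs.swapped())
        assert np.array_equal(R21, R12.T)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(pp.PhyloError, match="overlap"):
            pp.BlockSpec(block1=(0, 1), block2=(1, 3))


class TestDecomposeCrossBlock:
    def test_rank_one_recovery(self):
        u = orthonormal_columns(4, 1, seed=1)[:, 0]
        v = orthonormal_columns(5, 1, seed=2)[:, 0]
        R12 = 2.5 * np.outer(u, v)
        axes, sing = pp.decompose_cross_block(R12)
        assert sing.d[0] == pytest.approx(np.linalg.norm(R12), abs=1e-12)
        assert np.allclose(sing.d[1:], 0.0, atol=1e-12)
        # first axes recover u, v up to a joint sign
        s = np.sign(axes.U[:, 0] @ u)
        assert np.allclose(s * axes.U[:, 0], u, atol=1e-10)
        assert np.allclose(s * axes.V[:, 0], v, atol=1e-10)

    def test_zero_matrix_all_zero(self):
        _, sing = pp.decompose_cross_block(np.zeros((3, 4)))
        assert np.all(sing.d == 0.0)

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(9)
        axes, _ = pp.decompose_cross_block(rng.standard_normal((4, 6)))
        for k in range(axes.U.shape[1]):
            j = np.argmax(np.abs(axes.U[:, k]))
            assert axes.U[j, k] > 0

    def test_singular_values_sorted_descending(self):
        _, sing = pp.decompose_cross_block(
            np.random.default_rng(4).standard_normal((5, 5))
        )
        assert np.all(np.diff(sing.d) <= 0)
        assert np.all(sing.d >= 0)

    def test_leading_value_dominates_random_search(self):
        """d[0] is the max of a'R12 b over unit vectors: a random-direction
        search must never exceed it and should come close."""
        rng = np.random.default_rng(11)
        R12 = rng.standard_normal((4, 5))
        _, sing = pp.decompose_cross_block(R12)
        a = rng.standard_normal((10000, 4))
        b = rng.standard_normal((10000, 5))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        sampled = np.abs(np.einsum("ki,ij,kj->k", a, R12, b))
        assert sampled.max() <= sing.d[0] + 1e-12
        assert sampled.max() > 0.8 * sing.d[0]


class TestOrdinaryPLS:
    def test_duplicated_block_perfect_correlation(self):
        rng = np.random.default_rng(5)
        Y1 = rng.standard_normal((12, 3))
        tm = pp.TraitMatrix(
            np.hstack([Y1, Y1]),
            tuple(f"s{i}" for i in range(12)),
            tuple(f"x{i}" for i in range(6)),
        )
        res = pp.ordinary_pls(tm, pp.BlockSpec.halves(6), n_permutations=49, seed=1)
        assert res.r_pls == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_cross_covariance_by_construction(self):
        # build data whose S12 is exactly diag(3, 1): orthogonal mean-zero
        # unit-variance score vectors z1, z2, block2 = (3 z1, 1 z2)
        n = 9
        q = orthonormal_columns(n, 3, seed=8)
        ones = np.ones(n) / np.sqrt(n)
        # remove any component along 1 so columns are mean-zero
        z = q - np.outer(ones, ones @ q)
        z, _ = np.linalg.qr(z)
        z1, z2 = z[:, 0] * np.sqrt(n - 1), z[:, 1] * np.sqrt(n - 1)
        Y = np.column_stack([z1, z2, 3 * z1, 1 * z2])
        tm = pp.TraitMatrix(
            Y, tuple(f"s{i}" for i in range(n)), ("a", "b", "c", "d")
        )
        res = pp.ordinary_pls(tm, pp.BlockSpec.halves(4), n_permutations=9, seed=0)
        assert np.allclose(res.singular_values.d, [3.0, 1.0], atol=1e-9)
        assert np.allclose(np.abs(res.axes.U), np.eye(2), atol=1e-9)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)

    def test_independent_blocks_small_r(self):
        rng = np.random.default_rng(6)
        tm = pp.TraitMatrix(
            rng.standard_normal((300, 4)),
            tuple(f"s{i:03d}" for i in range(300)),
            ("a", "b", "c", "d"),
        )
        res = pp.ordinary_pls(tm, pp.BlockSpec.halves(4), n_permutations=199, seed=2)
        assert res.r_pls < 0.35
        assert res.p_value > 0.01

    def test_constant_block_rejected(self):
        tm = pp.TraitMatrix(
            np.column_stack(
                [np.random.default_rng(1).standard_normal(6), np.ones(6)]
            ),
            tuple(f"s{i}" for i in range(6)),
            ("a", "b"),
        )
        with pytest.raises(pp.DegenerateBlockError):
            pp.ordinary_pls(
                tm, pp.BlockSpec(block1=(0,), block2=(1,)),
                n_permutations=9, seed=0,
            )


class TestPhyloPLS:
    def test_deterministic_given_seed(self, blocks6):
        tree = pp.random_tree(12, seed=1)
        traits = random_traits(tree, p=6, b=0.4, seed=2)
        a = pp.phylo_pls(traits, tree, blocks6, n_permutations=99, seed=42)
        b = pp.phylo_pls(traits, tree, blocks6, n_permutations=99, seed=42)
        assert a.r_pls == b.r_pls
        assert np.array_equal(a.null_distribution, b.null_distribution)
        assert a.p_value == b.p_value

    def test_p_value_bounds(self, blocks6):
        tree = pp.random_tree(12, seed=3)
        traits = random_traits(tree, p=6, b=0.9, seed=4)
        res = pp.phylo_pls(traits, tree, blocks6, n_permutations=99, seed=5)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_min_p_with_99_permutations(self):
        # strongly integrated data: observed r should beat every permutation
        tree = pp.random_tree(32, seed=6)
        rng = np.random.default_rng(7)
        base = pp.simulate_bm(tree, np.eye(3), seed=8)
        Y = np.hstack([base.values, base.values + 0.01 * rng.standard_normal((32, 3))])
        tm = pp.TraitMatrix(Y, base.row_labels, tuple(f"x{i}" for i in range(6)))
        res = pp.phylo_pls(tm, tree, pp.BlockSpec.halves(6), n_permutations=99, seed=9)
        assert res.p_value == pytest.approx(1 / 100)

    def test_r_pls_non_negative(self, blocks6):
        for seed in range(8):
            tree = pp.random_tree(10, seed=seed)
            traits = random_traits(tree, p=6, b=0.0, seed=seed + 50)
            res = pp.phylo_pls(traits, tree, blocks6, n_permutations=9, seed=0)
            assert res.r_pls >= -1e-12

    def test_degenerate_block_rejected(self):
        tree = pp.random_tree(8, seed=1)
        labels = tuple(sorted(tree.tip_labels))
        Y = np.column_stack(
            [np.random.default_rng(2).standard_normal(8), np.full(8, 7.0)]
        )
        tm = pp.TraitMatrix(Y, labels, ("a", "b"))
        with pytest.raises(pp.DegenerateBlockError):
            pp.phylo_pls(
                tm, tree, pp.BlockSpec(block1=(0,), block2=(1,)),
                n_permutations=9, seed=0,
            )

    def test_block_relabeling_invariance(self, blocks6):
        tree = pp.random_tree(10, seed=10)
        traits = random_traits(tree, p=6, b=0.5, seed=11)
        a = pp.phylo_pls(traits, tree, blocks6, n_permutations=9, seed=1)
        b = pp.phylo_pls(traits, tree, blocks6.swapped(), n_permutations=9, seed=1)
        assert a.r_pls == pytest.approx(b.r_pls, abs=1e-12)

    def test_column_permutation_within_block_invariance(self):
        tree = pp.random_tree(10, seed=12)
        traits = random_traits(tree, p=6, b=0.5, seed=13)
        shuffled = pp.TraitMatrix(
            traits.values[:, [2, 0, 1, 3, 4, 5]],
            traits.row_labels,
            tuple(traits.col_labels[i] for i in [2, 0, 1, 3, 4, 5]),
        )
        bs = pp.BlockSpec.halves(6)
        a = pp.phylo_pls(traits, tree, bs, n_permutations=9, seed=1)
        b = pp.phylo_pls(shuffled, tree, bs, n_permutations=9, seed=1)
        assert a.r_pls == pytest.approx(b.r_pls, abs=1e-12)

    def test_whole_dataset_rescaling_invariance(self, blocks6):
        tree = pp.random_tree(10, seed=14)
        traits = random_traits(tree, p=6, b=0.5, seed=15)
        scaled = pp.TraitMatrix(
            traits.values * 2.5, traits.row_labels, traits.col_labels
        )
        a = pp.phylo_pls(traits, tree, blocks6, n_permutations=9, seed=1)
        b = pp.phylo_pls(scaled, tree, blocks6, n_permutations=9, seed=1)
        assert a.r_pls == pytest.approx(b.r_pls, abs=1e-12)

    def test_single_column_blocks_scale_invariance(self):
        # with one column per block r_PLS is a plain correlation, so
        # rescaling either column cannot change it
        tree = pp.random_tree(10, seed=16)
        traits = random_traits(tree, p=2, b=0.5, seed=17)
        scaled = pp.TraitMatrix(
            traits.values * np.array([1.0, 37.0]),
            traits.row_labels, traits.col_labels,
        )
        bs = pp.BlockSpec(block1=(0,), block2=(1,))
        a = pp.phylo_pls(traits, tree, bs, n_permutations=9, seed=1)
        b = pp.phylo_pls(scaled, tree, bs, n_permutations=9, seed=1)
        assert a.r_pls == pytest.approx(b.r_pls, abs=1e-12)


class TestPermutationTest:
    def test_add_one_rule_minimum(self):
        tree = pp.random_tree(10, seed=1)
        traits = random_traits(tree, p=4, b=0.2, seed=2)
        C, tm = pp.align(tree, traits)
        bs = pp.BlockSpec.halves(4)
        p, null = pp.permutation_test(tm, C, bs, observed=2.0, n_permutations=99, seed=3)
        assert p == pytest.approx(1 / 100)  # nothing can beat observed=2
        assert null.size == 99

    def test_identical_seed_identical_null(self):
        tree = pp.random_tree(10, seed=4)
        traits = random_traits(tree, p=4, b=0.2, seed=5)
        C, tm = pp.align(tree, traits)
        bs = pp.BlockSpec.halves(4)
        _, n1 = pp.permutation_test(tm, C, bs, 0.5, 49, seed=9)
        _, n2 = pp.permutation_test(tm, C, bs, 0.5, 49, seed=9)
        assert np.array_equal(n1, n2)

    def test_consistent_with_phylo_pls(self, blocks6):
        tree = pp.random_tree(12, seed=6)
        traits = random_traits(tree, p=6, b=0.3, seed=7)
        res = pp.phylo_pls(traits, tree, blocks6, n_permutations=99, seed=8)
        C, tm = pp.align(tree, traits)
        p, null = pp.permutation_test(
            tm, C, blocks6, res.r_pls, n_permutations=99, seed=8
        )
        assert p == res.p_value
        assert np.array_equal(null, res.null_distribution)

    def test_null_p_values_approximately_uniform(self):
        """Under independent blocks evolving by Brownian motion the
        permutation p-value must be (sub)uniform: the KS distance from
        U(0,1) over simulated datasets stays below the 5% critical value
        plus the lattice width of the discrete p-values."""
        n_data, B = 400, 99
        rng = np.random.default_rng(123)
        bs = pp.BlockSpec.halves(6)
        pvals = np.empty(n_data)
        for k in range(n_data):
            s = rng.integers(2**31, size=3)
            tree = pp.random_tree(32, int(s[0]))
            traits = pp.simulate_bm(tree, pp.build_input_cov(6, 0.0), int(s[1]))
            pvals[k] = pp.phylo_pls(
                traits, tree, bs, n_permutations=B, seed=int(s[2])
            ).p_value
        grid = np.sort(pvals)
        ks = np.max(
            np.maximum(
                np.abs(grid - np.arange(1, n_data + 1) / n_data),
                np.abs(grid - np.arange(n_data) / n_data),
            )
        )
        critical = 1.358 / np.sqrt(n_data) + 1 / (2 * (B + 1))
        assert ks < critical


class TestStarTreeReduction:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_ordinary_pls(self, seed):
        star = star_tree(12)
        traits = random_traits(star, p=6, b=0.4, seed=seed)
        bs = pp.BlockSpec.halves(6)
        a = pp.phylo_pls(traits, star, bs, n_permutations=49, seed=seed)
        b = pp.ordinary_pls(traits, bs, n_permutations=49, seed=seed)
        assert abs(a.r_pls - b.r_pls) < 1e-12
        assert a.p_value == b.p_value
        assert np.max(np.abs(a.null_distribution - b.null_distribution)) < 1e-12
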