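import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstab import (OtuTable, ValidationError, DissimilarityMatrix,
                       dissimilarity, hill_number, lcbd, ses_phylo)
from microstab.diversity import sample_seed, top_abundant_otus
from microstab.synthetic import random_coalescent_tree


class TestHillNumbers:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2, 3])
    def test_uniform_community(self, q):
        assert hill_number(np.full(4, 0.25), q) == pytest.approx(4.0)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_single_species(self, q):
        assert hill_number(np.array([1.0]), q) == pytest.approx(1.0)

    def test_inverse_simpson_hand_value(self):
        assert hill_number(np.array([0.9, 0.1]), 2) == pytest.approx(
            1 / 0.82, abs=1e-10)

    def test_q1_is_exp_shannon(self):
        p = np.array([0.5, 0.3, 0.2])
        expected = np.exp(-np.sum(p * np.log(p)))
        assert hill_number(p, 1) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_non_increasing_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 10)) * 0.5)
        values = [hill_number(p, q) for q in (0, 1, 2)]
        assert values[0] >= values[1] - 1e-9 >= values[2] - 2e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            hill_number(np.array([]), 1)
        with pytest.raises(ValidationError):
            hill_number(np.array([0.4, 0.4]), 1)  # does not sum to 1


# ---------------------------------------------------------------------------
# brute-force per-branch UniFrac oracle, independent of the implementation

def _branches(tree):
    for node in tree.tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        yield float(node.length), tips


def brute_unweighted_unifrac(tree, present_a, present_b):
    unique = shared = 0.0
    for l, tips in _branches(tree):
        in_a, in_b = bool(tips & present_a), bool(tips & present_b)
        if in_a and in_b:
            shared += l
        elif in_a or in_b:
            unique += l
    total = unique + shared
    return unique / total if total else 0.0


def brute_weighted_unifrac(tree, prop_a, prop_b):
    num = den = 0.0
    for l, tips in _branches(tree):
        pa = sum(prop_a.get(t, 0.0) for t in tips)
        pb = sum(prop_b.get(t, 0.0) for t in tips)
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    return num / den if den else 0.0


class TestDissimilarity:
    def test_identical_samples_all_metrics_zero(self, four_leaf_tree):
        t = OtuTable([[5, 3, 2, 1], [5, 3, 2, 1]], ["a", "b"],
                     list("ABCD"))
        for metric in ("bray_curtis", "hellinger", "unifrac_unweighted",
                       "unifrac_weighted"):
            dm = dissimilarity(t, metric, four_leaf_tree)
            assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_bray_curtis_hand_value(self):
        t = OtuTable([[2, 2], [1, 3]], ["a", "b"], ["x", "y"])
        dm = dissimilarity(t, "bray_curtis")
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_hellinger_bound(self):
        t = OtuTable([[10, 0], [0, 10]], ["a", "b"], ["x", "y"])
        dm = dissimilarity(t, "hellinger")
        assert dm.values[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_disjoint_support_star_tree_unifrac_one(self, star_tree):
        t = OtuTable([[5, 5, 0, 0], [0, 0, 7, 3]], ["a", "b"], list("ABCD"))
        dm = dissimilarity(t, "unifrac_unweighted", star_tree)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_unifrac_requires_tree(self, small_table):
        with pytest.raises(ValidationError):
            dissimilarity(small_table, "unifrac_weighted")

    def test_tree_missing_otus_rejected(self, small_table, tmp_path):
        bad = random_coalescent_tree(["A", "B"], seed=0)
        with pytest.raises(ValidationError, match="missing"):
            dissimilarity(small_table, "unifrac_unweighted", bad)

    @pytest.mark.parametrize("tree_seed", range(5))
    def test_unifrac_matches_per_branch_oracle(self, tree_seed):
        leaves = list("ABCDE")
        tree = random_coalescent_tree(leaves, seed=tree_seed)
        rng = np.random.default_rng(100 + tree_seed)
        counts = rng.integers(0, 30, (4, 5))
        counts[:, 0] += 1  # no empty samples
        t = OtuTable(counts, [f"s{i}" for i in range(4)], leaves)
        dm_u = dissimilarity(t, "unifrac_unweighted", tree)
        dm_w = dissimilarity(t, "unifrac_weighted", tree)
        props = counts / counts.sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(4), 2):
            pa = set(np.array(leaves)[counts[i] > 0])
            pb = set(np.array(leaves)[counts[j] > 0])
            assert dm_u.values[i, j] == pytest.approx(
                brute_unweighted_unifrac(tree, pa, pb), abs=1e-10)
            da = dict(zip(leaves, props[i]))
            db = dict(zip(leaves, props[j]))
            assert dm_w.values[i, j] == pytest.approx(
                brute_weighted_unifrac(tree, da, db), abs=1e-10)

    def test_weighted_unifrac_star_tree_is_bray_on_proportions(self, star_tree):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 40, (3, 4))
        t = OtuTable(counts, ["a", "b", "c"], list("ABCD"))
        dm = dissimilarity(t, "unifrac_weighted", star_tree)
        p = counts / counts.sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(3), 2):
            bc = np.abs(p[i] - p[j]).sum() / (p[i] + p[j]).sum()
            assert dm.values[i, j] == pytest.approx(bc, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_unifrac_agrees_with_skbio_on_bifurcating_trees(self, seed):
        # independent cross-check against the scikit-bio implementation
        # (restricted to strictly bifurcating trees, which it requires)
        from skbio.diversity import beta_diversity
        leaves = [f"o{j}" for j in range(6)]
        tree = random_coalescent_tree(leaves, seed=seed)  # binary by design
        rng = np.random.default_rng(300 + seed)
        counts = rng.integers(0, 40, (4, 6)) + 1
        t = OtuTable(counts, [f"s{i}" for i in range(4)], leaves)
        ours_u = dissimilarity(t, "unifrac_unweighted", tree).values
        ours_w = dissimilarity(t, "unifrac_weighted", tree).values
        ref_u = beta_diversity("unweighted_unifrac", counts,
                               taxa=leaves, tree=tree.tree).data
        ref_w = beta_diversity("weighted_unifrac", counts, taxa=leaves,
                               tree=tree.tree, normalized=True).data
        np.testing.assert_allclose(ours_u, ref_u, atol=1e-10)
        np.testing.assert_allclose(ours_w, ref_w, atol=1e-10)

    def test_invariants_hold_on_random_tables(self):
        rng = np.random.default_rng(17)
        leaves = [f"o{j}" for j in range(6)]
        tree = random_coalescent_tree(leaves, seed=2)
        counts = rng.integers(0, 50, (5, 6)) + 1
        t = OtuTable(counts, [f"s{i}" for i in range(5)], leaves)
        for metric in ("bray_curtis", "hellinger", "unifrac_unweighted",
                       "unifrac_weighted"):
            dissimilarity(t, metric, tree)  # validates in __post_init__


class TestLcbd:
    def test_hand_checked_three_samples(self):
        D = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        dm = DissimilarityMatrix(D, ["a", "b", "c"], "bray_curtis")
        np.testing.assert_allclose(lcbd(dm), [2 / 3, 1 / 6, 1 / 6],
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 60, (6, 8)) + 1
        t = OtuTable(counts, [f"s{i}" for i in range(6)],
                     [f"o{j}" for j in range(8)])
        vals = lcbd(dissimilarity(t, "hellinger"))
        assert vals.sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_samples_equal_contribution(self):
        counts = np.array([[5, 5], [5, 5], [1, 9]])
        t = OtuTable(counts, ["a", "b", "c"], ["x", "y"])
        vals = lcbd(dissimilarity(t, "bray_curtis"))
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_no_beta_diversity_raises(self):
        D = np.zeros((3, 3))
        dm = DissimilarityMatrix(D, ["a", "b", "c"], "bray_curtis")
        with pytest.raises(ValidationError, match="beta"):
            lcbd(dm)


class TestSesPhylo:
    def test_matches_exhaustive_enumeration(self, four_leaf_tree):
        # 4-leaf pool, 2 present: null = all C(4,2) pairs, enumerable exactly
        counts = np.array([[3, 0, 9, 0]])
        t = OtuTable(counts, ["s"], list("ABCD"))
        dist = four_leaf_tree.patristic_distances(list("ABCD"))
        for metric in ("MPD", "MNTD"):
            res = ses_phylo(t, four_leaf_tree, metric, n_null=100000,
                            top_k=4, seed=0)[0]
            null = []
            for pair in itertools.combinations(range(4), 2):
                d = dist[pair[0], pair[1]]
                null.append(d)  # MPD == MNTD for 2 present taxa
            # the 6 pairs are equally likely: population mean and sd
            exact_ses = (res.observed - np.mean(null)) / np.std(null)
            assert res.ses == pytest.approx(exact_ses, abs=0.05)
            assert res.index_value == pytest.approx(-res.ses, abs=1e-12)

    def test_entire_pool_flagged_undefined(self, four_leaf_tree):
        t = OtuTable(np.ones((1, 4), dtype=int), ["s"], list("ABCD"))
        res = ses_phylo(t, four_leaf_tree, "MPD", n_null=99, top_k=4,
                        seed=1)[0]
        assert not res.defined and np.isnan(res.index_value)

    def test_star_tree_flagged_undefined(self, star_tree):
        t = OtuTable(np.array([[1, 1, 0, 0]]), ["s"], list("ABCD"))
        res = ses_phylo(t, star_tree, "MPD", n_null=99, top_k=4, seed=1)[0]
        assert not res.defined

    def test_mean_ses_near_zero_under_null(self):
        # samples drawn from the null itself: mean SES within +-0.1
        leaves = [f"o{j}" for j in range(20)]
        tree = random_coalescent_tree(leaves, seed=7)
        rng = np.random.default_rng(42)
        counts = np.zeros((200, 20), dtype=int)
        for i in range(200):
            present = rng.choice(20, size=rng.integers(3, 10), replace=False)
            counts[i, present] = 1
        t = OtuTable(counts, [f"s{i}" for i in range(200)], leaves)
        res = ses_phylo(t, tree, "MPD", n_null=199, top_k=20, seed=5)
        mean_ses = np.mean([r.ses for r in res if r.defined])
        assert abs(mean_ses) < 0.1

    def test_per_sample_seed_order_independent(self):
        assert sample_seed(3, "s1") == sample_seed(3, "s1")
        assert sample_seed(3, "s1") != sample_seed(3, "s2")

    def test_top_k_pool_tie_break(self):
        counts = np.array([[5, 5, 2, 7]])
        t = OtuTable(counts, ["s"], ["b", "a", "c", "d"])
        assert top_abundant_otus(t, 2) == ["d", "a"]
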