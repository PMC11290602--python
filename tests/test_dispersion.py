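"""Patristic distances, MPD, permutation nulls, tree-set dispersion, trend."""

import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from divarrest import dispersion as dsp
from divarrest.errors import ConfigurationError, UndefinedMPDError
from divarrest.famsim import simulate_pure_birth, rescale_tree
from divarrest.treeio import TreeSet

from conftest import tree_from


def brute_force_mpd(tree, tip_labels):
    """O(n^2) oracle: pairwise path sums via per-tip ancestor paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in tip_labels:
            continue
        path = {}
        node, total = leaf, 0.0
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            path[id(node.parent_node)] = total
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    total, count = 0.0, 0
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            shared = set(paths[a]) & set(paths[b])
            d = min(paths[a][s] + paths[b][s] for s in shared)
            total += d
            count += 1
    return total / count


class TestPatristicMatrix:
    def test_cherry(self, cherry):
        labels, D = dsp.patristic_distance_matrix(cherry)
        assert D[labels.index("A"), labels.index("B")] == 20.0

    def test_three_tip_path_sums(self, three_tip):
        labels, D = dsp.patristic_distance_matrix(three_tip)
        i = {lab: k for k, lab in enumerate(labels)}
        assert D[i["A"], i["B"]] == 8.0
        assert D[i["A"], i["C"]] == 20.0
        assert D[i["B"], i["C"]] == 20.0

    def test_symmetric_zero_diagonal(self):
        t = simulate_pure_birth(20, 1.0, default_rng(0))
        _, D = dsp.patristic_distance_matrix(t)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_ultrametric_bound(self):
        t = simulate_pure_birth(20, 1.0, default_rng(1))
        from divarrest.famsim import tree_height
        _, D = dsp.patristic_distance_matrix(t)
        assert D.max() <= 2 * tree_height(t) + 1e-9

    def test_subset_tracking(self):
        t = simulate_pure_birth(30, 1.0, default_rng(2))
        all_labels, D_all = dsp.patristic_distance_matrix(t)
        subset = all_labels[::3]
        labels, D_sub = dsp.patristic_distance_matrix(t, labels=subset)
        idx = [all_labels.index(l) for l in subset]
        assert np.allclose(D_sub, D_all[np.ix_(idx, idx)])

    def test_agrees_with_dendropy_oracle(self):
        tree = simulate_pure_birth(15, 1.0, default_rng(3))
        labels, D = dsp.patristic_distance_matrix(tree)
        pdm = tree.phylogenetic_distance_matrix()
        tn = tree.taxon_namespace
        for i in range(15):
            for j in range(i + 1, 15):
                ref = pdm.patristic_distance(tn.get_taxon(labels[i]),
                                             tn.get_taxon(labels[j]))
                assert D[i, j] == pytest.approx(ref, rel=1e-9)


class TestMPD:
    def test_single_pair(self, cherry):
        labels, D = dsp.patristic_distance_matrix(cherry)
        assert dsp.mpd(D, [0, 1]) == 20.0

    def test_three_tip_brute_force(self, three_tip):
        labels, D = dsp.patristic_distance_matrix(three_tip)
        assert dsp.mpd(D, [0, 1, 2]) == pytest.approx((8 + 20 + 20) / 3)

    def test_star_tree_all_pairs_equal(self):
        star = tree_from("(A:7,B:7,C:7,D:7,E:7);")
        labels, D = dsp.patristic_distance_matrix(star)
        for size in (2, 3, 5):
            assert dsp.mpd(D, list(range(size))) == pytest.approx(14.0)

    def test_undefined_below_two(self, cherry):
        _, D = dsp.patristic_distance_matrix(cherry)
        with pytest.raises(UndefinedMPDError):
            dsp.mpd(D, [0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = default_rng(seed)
        tree = simulate_pure_birth(25, 1.0, rng)
        labels, D = dsp.patristic_distance_matrix(tree)
        pick = rng.choice(25, size=8, replace=False)
        expected = brute_force_mpd(tree, {labels[i] for i in pick})
        # brute force iterates sorted labels; map indices accordingly
        assert dsp.mpd(D, sorted(pick)) == pytest.approx(expected, rel=1e-9)


class TestPermutationNull:
    def test_star_tree_degenerate_interval(self):
        star = tree_from("(A:5,B:5,C:5,D:5,E:5,F:5);")
        _, D = dsp.patristic_distance_matrix(star)
        null = dsp.permutation_null(D, [3, 3], n_reps=50, rng=0)
        assert np.allclose(null.replicates, 10.0)
        assert np.allclose(null.lower, 10.0)
        assert np.allclose(null.upper, 10.0)

    def test_same_seed_identical(self):
        t = simulate_pure_birth(20, 1.0, default_rng(5))
        _, D = dsp.patristic_distance_matrix(t)
        a = dsp.permutation_null(D, [5, 5, 5, 5], n_reps=100, rng=42)
        b = dsp.permutation_null(D, [5, 5, 5, 5], n_reps=100, rng=42)
        assert np.array_equal(a.replicates, b.replicates)

    def test_exchangeability_mean_equals_whole_tree_mpd(self):
        """A uniformly random bin's expected MPD is the whole-tree MPD."""
        t = simulate_pure_birth(20, 1.0, default_rng(6))
        _, D = dsp.patristic_distance_matrix(t)
        whole = dsp.mpd(D, range(20))
        null = dsp.permutation_null(D, [4] * 5, n_reps=4000, rng=7)
        se = null.replicates.std() / np.sqrt(null.replicates.size)
        assert abs(null.replicates.mean() - whole) < 5 * se

    def test_bin_size_validation(self):
        t = simulate_pure_birth(10, 1.0, default_rng(8))
        _, D = dsp.patristic_distance_matrix(t)
        with pytest.raises(ConfigurationError):
            dsp.permutation_null(D, [9, 1], n_reps=10)
        with pytest.raises(ConfigurationError):
            dsp.permutation_null(D, [4, 4], n_reps=10)

    def test_scale_equivariance(self):
        tree = simulate_pure_birth(16, 1.0, default_rng(9))
        doubled = rescale_tree(tree, 2 * _height(tree))
        _, D1 = dsp.patristic_distance_matrix(tree)
        _, D2 = dsp.patristic_distance_matrix(doubled)
        n1 = dsp.permutation_null(D1, [4] * 4, n_reps=200, rng=3)
        n2 = dsp.permutation_null(D2, [4] * 4, n_reps=200, rng=3)
        assert np.allclose(2 * n1.replicates, n2.replicates)
        assert np.allclose(2 * n1.upper, n2.upper)


def _height(tree):
    from divarrest.famsim import tree_height
    return tree_height(tree)


def _rate_table(families, values, k=2):
    from divarrest.rates import assign_quantiles
    s = pd.Series(values, index=families, dtype=float)
    return pd.DataFrame({
        "family": families,
        "rate": s.values,
        "quantile": assign_quantiles(s, k=k).values,
    })


class TestDispersionOverTreeSet:
    def test_single_tree_reduces_to_per_tree(self):
        tree = simulate_pure_birth(12, 1.0, default_rng(10))
        ts = TreeSet(trees=[tree])
        families = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        rt = _rate_table(families, np.arange(12), k=3)
        res = dsp.dispersion_over_tree_set(ts, rt, n_reps=200, seed=1)
        assert set(res.per_tree["tree_index"]) == {0}
        assert len(res.per_tree) == 3
        labels, D = dsp.patristic_distance_matrix(tree)
        q1 = rt.loc[rt["quantile"] == 1, "family"]
        obs = dsp.mpd(D, [labels.index(f) for f in q1])
        assert res.per_tree.loc[res.per_tree["quantile"] == 1,
                                "mpd_obs"].iloc[0] == pytest.approx(obs)

    def test_union_of_bins_is_whole_tree_mpd(self):
        tree = simulate_pure_birth(12, 1.0, default_rng(11))
        labels, D = dsp.patristic_distance_matrix(tree)
        whole = dsp.mpd(D, range(12))
        union = dsp.mpd(D, list(range(12)))
        assert union == pytest.approx(whole)

    def test_null_bounds_ordered_and_reproducible(self):
        trees = [simulate_pure_birth(10, 1.0, default_rng(s))
                 for s in (12, 13)]
        ts = TreeSet(trees=trees)
        fams = sorted(lf.taxon.label for lf in trees[0].leaf_node_iter())
        # both trees must share labels: rename second tree's tips
        for lf, name in zip(trees[1].leaf_node_iter(), fams):
            lf.taxon.label = name
        rt = _rate_table(fams, np.arange(10), k=2)
        r1 = dsp.dispersion_over_tree_set(ts, rt, n_reps=100, seed=5)
        r2 = dsp.dispersion_over_tree_set(ts, rt, n_reps=100, seed=5)
        assert (r1.per_tree["null_lo"] <= r1.per_tree["null_hi"]).all()
        pd.testing.assert_frame_equal(r1.per_tree, r2.per_tree)


class TestTrend:
    def _result_from(self, mpds_by_tree):
        rows = []
        for ti, mpds in enumerate(mpds_by_tree):
            for q, m in enumerate(mpds, start=1):
                rows.append({"tree_index": ti, "quantile": q, "mpd_obs": m,
                             "null_lo": 0.0, "null_hi": 1.0, "flag": "ns"})
        return dsp.DispersionResult(per_tree=pd.DataFrame(rows),
                                    pooled=pd.DataFrame(), trend={},
                                    n_permutations=0, seed=0)

    def test_perfect_monotone_decrease(self):
        res = self._result_from([[5, 4, 3, 2, 1]] * 4)
        trend = dsp.trend_test(res, n_reps=500, rng=0)
        assert trend["statistic"] == pytest.approx(-1.0)
        assert trend["direction"] == "decreasing"
        assert trend["p_value"] < 0.01

    def test_single_tree_rank_minus_one(self):
        res = self._result_from([[5, 4, 3, 2, 1]])
        trend = dsp.trend_test(res, n_reps=200, rng=0)
        assert trend["statistic"] == pytest.approx(-1.0)

    def test_constant_mpds_degenerate(self):
        res = self._result_from([[2, 2, 2, 2, 2]] * 3)
        trend = dsp.trend_test(res, n_reps=100, rng=0)
        assert trend["p_value"] == 1.0
        assert trend["degenerate"]

    def test_null_calibration_p_roughly_uniform(self):
        """Shuffled labels give small p-values at roughly nominal rate."""
        rng = default_rng(14)
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            mpds = rng.normal(10, 1, size=(3, 5))
            res = self._result_from(mpds.tolist())
            trend = dsp.trend_test(res, n_reps=199, rng=rng)
            if trend["p_value"] <= 0.1:
                hits += 1
        # nominal 10%; binomial 99% envelope around 10 of 100
        assert 2 <= hits <= 20
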