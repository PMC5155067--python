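"""Diversity metrics, singleton removal, and the UPGMA distance tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy

from binquant.ecology import (
    bray_curtis_matrix, distance_tree, diversity_report, pielou,
    remove_singletons, richness, shannon,
)

counts_strategy = st.lists(st.integers(0, 500), min_size=2, max_size=30).filter(
    lambda c: sum(c) > 0)


class TestAlphaDiversity:
    def test_uniform_community_maximum_evenness(self):
        h = shannon([25, 25, 25, 25])
        assert h == pytest.approx(np.log(4))
        assert pielou(h, 4) == pytest.approx(1.0)

    def test_matches_scipy_natural_log(self, rng):
        x = rng.integers(1, 100, size=20)
        assert shannon(x) == pytest.approx(entropy(x))  # scipy uses ln

    def test_richness_counts_positive_taxa(self):
        assert richness([0, 3, 0, 1, 2]) == 3

    def test_pielou_undefined_for_single_taxon(self):
        assert pielou(0.0, 1) is None

    @settings(deadline=None, max_examples=150)
    @given(counts_strategy)
    def test_bounds_h_le_ln_s_and_j_in_unit_interval(self, counts):
        h = shannon(counts)
        s = richness(counts)
        assert h <= np.log(s) + 1e-9
        if s >= 2:
            j = pielou(h, s)
            assert -1e-9 <= j <= 1.0 + 1e-9

    @settings(deadline=None, max_examples=100)
    @given(counts_strategy, st.floats(0.1, 1000))
    def test_shannon_scale_invariant(self, counts, c):
        x = np.asarray(counts, dtype=float)
        assert shannon(x * c) == pytest.approx(shannon(x), abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(counts_strategy, st.randoms(use_true_random=False))
    def test_shannon_permutation_invariant(self, counts, rnd):
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert shannon(shuffled) == pytest.approx(shannon(counts))


class TestSingletons:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["A", "B"])

    def test_global_singleton_removed(self):
        t = self._table([[1, 0], [5, 5]])
        out = remove_singletons(t)
        assert list(out.index) == [1]

    def test_count_split_across_samples_retained(self):
        t = self._table([[1, 1]])
        assert len(remove_singletons(t)) == 1

    def test_empty_table_passthrough(self):
        t = pd.DataFrame(columns=["A"])
        assert remove_singletons(t).empty

    def test_never_increases_richness_and_idempotent(self, rng):
        t = pd.DataFrame(rng.poisson(0.7, size=(50, 3)), columns=list("ABC"))
        once = remove_singletons(t)
        for col in t:
            assert richness(once[col]) <= richness(t[col])
        pd.testing.assert_frame_equal(remove_singletons(once), once)


# --- distance tree --------------------------------------------------------


def upgma_oracle(dist, names):
    """Brute-force size-weighted average-linkage agglomeration.

    Returns the set of (merge height, frozenset of leaves) pairs, which
    characterises an ultrametric tree up to leaf order.
    """
    clusters = {i: frozenset([n]) for i, n in enumerate(names)}
    d = {(i, j): dist[i][j] for i in range(len(names)) for j in range(i + 1, len(names))}
    merges = []
    nxt = len(names)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        merges.append((h, merged))
        si, sj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        newd = {}
        for (a, b), v in d.items():
            if {a, b} & {i, j}:
                continue
            newd[(a, b)] = v
        for k in clusters:
            da = d[(min(i, k), max(i, k))]
            db = d[(min(j, k), max(j, k))]
            newd[(min(k, nxt), max(k, nxt))] = (si * da + sj * db) / (si + sj)
        clusters[nxt] = merged
        d = newd
        nxt += 1
    return merges


def tree_merges(tree):
    """(height, leafset) pairs for internal nodes of an ultrametric tree."""
    out = []
    for node in tree.non_tips(include_self=True):
        tips = list(node.tips())
        height = tips[0].accumulate_to_ancestor(node)
        out.append((height, frozenset(t.name for t in tips)))
    return sorted(out, key=lambda x: x[0])


class TestDistanceTree:
    def test_identical_samples_zero_distance(self):
        t = pd.DataFrame({"A": [3, 1], "B": [6, 2]})  # same relative profile
        dm = bray_curtis_matrix(t)
        assert dm.loc["A", "B"] == pytest.approx(0.0)
        tree = distance_tree(t)
        heights = [h for h, _ in tree_merges(tree)]
        assert min(heights) == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_clusters_before_disjoint_sample(self):
        t = pd.DataFrame({"A": [5, 5, 0], "B": [5, 5, 0], "C": [0, 0, 7]})
        tree = distance_tree(t)
        merges = tree_merges(tree)
        assert merges[0][1] == frozenset({"A", "B"})

    def test_bray_curtis_matrix_properties(self, rng):
        t = pd.DataFrame(rng.integers(0, 50, size=(20, 4)), columns=list("ABCD"))
        t.iloc[0] += 1  # keep totals positive
        dm = bray_curtis_matrix(t).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
        assert (dm >= -1e-12).all() and (dm <= 1 + 1e-12).all()

    def test_upgma_matches_bruteforce_oracle_on_random_instances(self):
        """scipy average-linkage agglomeration vs a brute-force UPGMA oracle
        on 100 random 4-sample abundance tables."""
        rng = np.random.default_rng(99)
        names = list("WXYZ")
        for _ in range(100):
            table = pd.DataFrame(rng.uniform(0, 10, size=(6, 4)), columns=names)
            tree = distance_tree(table, relative=False)
            dm = bray_curtis_matrix(table, relative=False).to_numpy()
            expected = upgma_oracle(dm.tolist(), names)
            got = tree_merges(tree)
            for (h1, s1), (h2, s2) in zip(sorted(expected), got):
                assert s1 == s2
                assert h1 / 2 == pytest.approx(h2, abs=1e-9)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            distance_tree(pd.DataFrame({"A": [1, 2]}))


class TestDiversityReport:
    def test_report_shape_and_singleton_handling(self):
        t = pd.DataFrame({"A": [10, 5, 1, 0], "B": [10, 5, 0, 0]},
                         index=[f"o{i}" for i in range(4)])
        rep = diversity_report(t)
        assert list(rep.index) == ["A", "B"]
        assert rep.loc["A", "richness"] == 2  # the singleton o2 is dropped
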