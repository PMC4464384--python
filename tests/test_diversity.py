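"""Unit tests for OTU clustering and alpha diversity.

Cross-checks: scipy's hierarchical complete linkage on unique-distance
instances, skbio's alpha-diversity estimators, brute-force partition
enumeration, and Monte-Carlo rarefaction.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from dwbiofilm.diversity import (DistanceMatrix, chao1,
                                 cluster_complete_linkage, pairwise_distance,
                                 rarefaction, shannon_pielou, summarize,
                                 summary_frame)
from dwbiofilm.records import SeqRead


def _random_dm(n, rng):
    """Symmetric distance matrix with all-distinct off-diagonal values."""
    vals = rng.permutation(n * (n - 1) // 2) / (n * n) + \
        rng.uniform(0, 1e-4)
    d = squareform(vals)
    return DistanceMatrix(tuple(f"r{i:02d}" for i in range(n)), d)


class TestPairwiseDistance:
    def test_identical_reads_distance_zero(self):
        dm = pairwise_distance([SeqRead("a", "ACGTACGT"),
                                SeqRead("b", "ACGTACGT")])
        assert dm.value("a", "b") == 0.0

    def test_three_mismatches_in_hundred(self):
        a = "ACGT" * 25
        b = list(a)
        for pos, sub in [(10, "A"), (40, "G"), (70, "C")]:
            assert b[pos] != sub
            b[pos] = sub
        dm = pairwise_distance([SeqRead("a", a), SeqRead("b", "".join(b))])
        assert dm.value("a", "b") == pytest.approx(0.03)

    def test_terminal_gaps_excluded_prefix_case(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        dm = pairwise_distance([SeqRead("a", a), SeqRead("p", a[:20])])
        assert dm.value("a", "p") == 0.0

    def test_aligned_mode_counts_columns(self):
        rows = [SeqRead("a", "ACGT-ACGT"), SeqRead("b", "ACGTTACGT")]
        dm = pairwise_distance(rows, mode="aligned")
        # 9 columns, 1 differing (internal gap counts as a difference)
        assert dm.value("a", "b") == pytest.approx(1 / 9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_distance([SeqRead("a", ""), SeqRead("b", "ACGT")])


class TestCompleteLinkage:
    def test_spec_triangle_example(self):
        d = np.array([[0.00, 0.02, 0.05],
                      [0.02, 0.00, 0.05],
                      [0.05, 0.05, 0.00]])
        dm = DistanceMatrix(("A", "B", "C"), d)
        table = cluster_complete_linkage(dm, 0.03)
        assert sorted(sorted(c) for c in table.clusters) == \
            [["A", "B"], ["C"]]

    def test_threshold_zero_separates_distinct_reads(self):
        rng = np.random.default_rng(0)
        dm = _random_dm(6, rng)
        table = cluster_complete_linkage(dm, 0.0)
        assert table.n_otus == 6

    def test_constraint_holds_on_random_instances(self):
        """Every emitted OTU's max intra-distance is <= the threshold."""
        rng = np.random.default_rng(1)
        for n in (5, 8, 12):
            dm = _random_dm(n, rng)
            for t in (0.01, 0.05, 0.2):
                table = cluster_complete_linkage(dm, t)
                idx = {rid: i for i, rid in enumerate(dm.ids)}
                for c in table.clusters:
                    for a, b in itertools.combinations(sorted(c), 2):
                        assert dm.d[idx[a], idx[b]] <= t

    def test_matches_scipy_on_unique_distances(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            n = int(rng.integers(4, 10))
            dm = _random_dm(n, rng)
            t = float(rng.uniform(0.01, 0.3))
            mine = cluster_complete_linkage(dm, t)
            z = linkage(squareform(dm.d), method="complete")
            labels = fcluster(z, t=t, criterion="distance")
            scipy_parts = {}
            for rid, lab in zip(dm.ids, labels):
                scipy_parts.setdefault(lab, set()).add(rid)
            assert sorted(map(sorted, mine.clusters)) == \
                sorted(map(sorted, scipy_parts.values()))

    def test_brute_force_partition_oracle_small(self):
        """On <= 6 reads the emitted partition is a valid complete-linkage
        partition and no cluster could absorb another without violating the
        threshold (maximality of the agglomeration)."""
        rng = np.random.default_rng(3)
        dm = _random_dm(6, rng)
        t = 0.15
        table = cluster_complete_linkage(dm, t)
        idx = {rid: i for i, rid in enumerate(dm.ids)}

        def diameter(group):
            return max((dm.d[idx[a], idx[b]] for a, b in
                        itertools.combinations(group, 2)), default=0.0)

        for c in table.clusters:
            assert diameter(c) <= t
        for c1, c2 in itertools.combinations(table.clusters, 2):
            assert diameter(c1 | c2) > t

    def test_coarser_threshold_never_more_otus(self):
        rng = np.random.default_rng(4)
        dm = _random_dm(10, rng)
        fine = cluster_complete_linkage(dm, 0.03)
        coarse = cluster_complete_linkage(dm, 0.06)
        assert coarse.n_otus <= fine.n_otus

    def test_per_sample_counts(self):
        d = np.array([[0.0, 0.01], [0.01, 0.0]])
        dm = DistanceMatrix(("a", "b"), d)
        table = cluster_complete_linkage(dm, 0.03,
                                         sample_of={"a": "s1", "b": "s2"})
        assert table.counts.to_numpy().sum() == 2
        assert set(table.counts.columns) == {"s1", "s2"}


class TestChao1:
    def test_no_singletons_equals_observed(self):
        assert chao1(np.array([5, 5, 5])) == 3.0

    def test_classic_formula(self):
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1(counts) == pytest.approx(10 + 16 / 4)  # 14

    def test_bias_corrected_formula(self):
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1(counts, bias_corrected=True) == \
            pytest.approx(10 + 4 * 3 / 6)  # 12

    def test_classic_without_doubletons_falls_back(self):
        counts = np.array([1, 1, 3, 4])
        with pytest.warns(UserWarning, match="doubletons"):
            got = chao1(counts)
        assert got == pytest.approx(4 + 2 * 1 / 2)

    def test_agrees_with_skbio(self):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        rng = np.random.default_rng(5)
        for _ in range(10):
            counts = rng.integers(1, 8, size=20)
            counts = np.asarray(counts, dtype=np.int64)
            assert chao1(counts, bias_corrected=True) == \
                pytest.approx(skbio_chao1(counts, bias_corrected=True))
            if (counts == 2).sum() > 0:
                assert chao1(counts) == \
                    pytest.approx(skbio_chao1(counts, bias_corrected=False))

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            counts = np.asarray(rng.integers(1, 10, size=15), dtype=np.int64)
            s_obs = (counts > 0).sum()
            assert chao1(counts, bias_corrected=True) >= s_obs


class TestShannonPielou:
    def test_uniform_four(self):
        h, j = shannon_pielou([10, 10, 10, 10])
        assert h == pytest.approx(math.log(4))
        assert j == pytest.approx(1.0)

    def test_single_otu(self):
        h, j = shannon_pielou([42])
        assert h == 0.0 and j == 0.0

    def test_hand_summation(self):
        counts = [90, 5, 5]
        p = np.array(counts) / 100
        h_hand = -sum(pi * math.log(pi) for pi in p)
        h, j = shannon_pielou(counts)
        assert h == pytest.approx(h_hand)
        assert j == pytest.approx(h_hand / math.log(3))

    def test_agrees_with_skbio(self):
        from skbio.diversity.alpha import pielou_e, shannon

        counts = np.array([13, 7, 1, 1, 2, 30], dtype=np.int64)
        h, j = shannon_pielou(counts)
        assert h == pytest.approx(shannon(counts, base=math.e))
        assert j == pytest.approx(pielou_e(counts))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon_pielou([0, 0])


class TestRarefaction:
    def test_full_depth_gives_observed(self):
        curve = rarefaction([4, 3, 2], [9])
        assert curve.expected_otus.iloc[0] == pytest.approx(3.0)

    def test_depth_one_gives_one(self):
        curve = rarefaction([4, 3, 2], [1])
        assert curve.expected_otus.iloc[0] == pytest.approx(1.0)

    def test_tiny_enumeration_case(self):
        # counts [2,1], n=2: of the C(3,2)=3 subsamples, 2 contain both OTUs
        curve = rarefaction([2, 1], [2])
        assert curve.expected_otus.iloc[0] == pytest.approx(1 + 2 / 3)

    def test_monotone_nondecreasing(self):
        counts = [20, 10, 5, 2, 1, 1]
        curve = rarefaction(counts, list(range(1, 40)))
        assert (np.diff(curve.expected_otus) >= -1e-12).all()

    def test_monte_carlo_agreement(self):
        """Closed form within 3 standard errors of 10,000 random draws."""
        counts = np.array([20, 10, 5, 2, 1, 1])
        depth = 15
        rng = np.random.default_rng(7)
        pool = np.repeat(np.arange(counts.size), counts)
        draws = np.array([
            np.unique(rng.choice(pool, size=depth, replace=False)).size
            for _ in range(10_000)])
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        exact = rarefaction(counts, [depth]).expected_otus.iloc[0]
        assert abs(exact - draws.mean()) <= 3 * se

    def test_depth_beyond_total_raises(self):
        with pytest.raises(ValueError):
            rarefaction([2, 1], [4])


def test_summary_frame_layout():
    d = np.array([[0.0, 0.02, 0.10],
                  [0.02, 0.0, 0.09],
                  [0.10, 0.09, 0.0]])
    dm = DistanceMatrix(("a", "b", "c"), d)
    sample_of = {"a": "s1", "b": "s1", "c": "s1"}
    tables = {t: cluster_complete_linkage(dm, t, sample_of)
              for t in (0.03, 0.06)}
    frame = summary_frame(tables)
    assert list(frame.index) == ["s1"]
    assert set(frame.columns.get_level_values("threshold")) == {0.03, 0.06}
    s = summarize(np.array([2, 1], dtype=np.int64))
    assert frame.loc["s1", (0.03, "chao1")] == pytest.approx(s.chao1)
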