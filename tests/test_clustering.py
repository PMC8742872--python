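import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cageshift.clustering import (TagCluster, cluster_ctss, dominant_ctss,
                                  filter_clusters, group_promoters, normalize_tpm)
from cageshift.model import CtssMatrix

from conftest import union_find_components


def _matrix(positions, counts=None, samples=("s1", "s2"), strand="+"):
    counts = counts or {p: [1] * len(samples) for p in positions}
    return CtssMatrix.from_entries(
        {("chr1", p, strand): counts[p] for p in positions}, list(samples))


def _spans(clusters):
    return {(tc.start, tc.end) for tc in clusters}


class TestClusterCtss:
    def test_gap_breaks_chain(self):
        clusters = cluster_ctss(_matrix([100, 112, 140]), gap=20)
        assert _spans(clusters) == {(100, 112), (140, 140)}

    def test_boundary_inclusive_chain(self):
        clusters = cluster_ctss(_matrix([100, 120, 140]), gap=20)
        assert _spans(clusters) == {(100, 140)}

    def test_singleton(self):
        (tc,) = cluster_ctss(_matrix([100]), gap=20)
        assert tc.start == tc.end == tc.dominant_pos == 100

    def test_empty_matrix(self):
        assert cluster_ctss(CtssMatrix.empty(["s1"]), gap=20) == []

    def test_strand_partition(self):
        m = CtssMatrix.from_entries(
            {("chr1", 100, "+"): [1], ("chr1", 100, "-"): [1]}, ["s1"])
        assert len(cluster_ctss(m, gap=20)) == 2

    def test_gap_zero_gives_singletons(self):
        clusters = cluster_ctss(_matrix([100, 101, 102, 110]), gap=0)
        assert _spans(clusters) == {(100, 100), (101, 101), (102, 102), (110, 110)}

    def test_every_ctss_in_exactly_one_cluster(self):
        rng = np.random.default_rng(0)
        pos = sorted(rng.choice(np.arange(1, 2000), 60, replace=False))
        clusters = cluster_ctss(_matrix([int(p) for p in pos]), gap=20)
        members = sorted(p for tc in clusters for p in tc.member_positions)
        assert members == sorted(pos)

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(1, 500), min_size=1, max_size=40),
           st.integers(0, 30))
    def test_oracle_transitive_closure(self, pos_set, gap):
        positions = sorted(pos_set)
        clusters = cluster_ctss(_matrix(positions), gap=gap)
        comps = union_find_components(
            len(positions),
            lambda i, j: abs(positions[i] - positions[j]) <= gap)
        expected = {frozenset(positions[i] for i in c) for c in comps}
        got = {frozenset(int(p) for p in tc.member_positions) for tc in clusters}
        assert got == expected

    def test_permutation_invariance(self):
        import pandas as pd
        positions = [100, 105, 130, 131, 200]
        m = _matrix(positions)
        shuffled = CtssMatrix(m.df.sample(frac=1.0, random_state=7), m.samples)
        assert _spans(cluster_ctss(m, 20)) == _spans(cluster_ctss(shuffled, 20))

    def test_gap_monotonicity_refinement(self):
        rng = np.random.default_rng(3)
        positions = sorted(int(p) for p in rng.choice(np.arange(1, 3000), 80, replace=False))
        coarse = cluster_ctss(_matrix(positions), gap=40)
        fine = cluster_ctss(_matrix(positions), gap=10)
        coarse_sets = [set(tc.member_positions) for tc in coarse]
        for tc in fine:
            fine_set = set(tc.member_positions)
            assert sum(fine_set <= c for c in coarse_sets) == 1


class TestTpm:
    def test_simple_value(self):
        (tc,) = cluster_ctss(_matrix([100], {100: [50, 0]}), gap=20)
        normalize_tpm([tc], {"s1": 1_000_000, "s2": 1_000_000})
        assert tc.tpm.tolist() == [50.0, 0.0]

    def test_zero_total_errors(self):
        (tc,) = cluster_ctss(_matrix([100], {100: [50, 0]}), gap=20)
        with pytest.raises(ValueError, match="s2"):
            normalize_tpm([tc], {"s1": 100, "s2": 0})

    def test_conservation(self):
        # per-sample sum of cluster TPMs == 1e6 * clustered / total counts
        rng = np.random.default_rng(9)
        positions = sorted(int(p) for p in rng.choice(np.arange(1, 5000), 100, replace=False))
        counts = {p: rng.poisson(4, 2) + 1 for p in positions}
        m = _matrix(positions, counts)
        totals = {s: float(m.sample_totals[s]) * 2 for s in m.samples}  # half clustered
        clusters = normalize_tpm(cluster_ctss(m, 20), totals)
        tpm_sums = np.sum([tc.tpm for tc in clusters], axis=0)
        expected = 1e6 * m.sample_totals.to_numpy() / np.array(list(totals.values()))
        assert np.allclose(tpm_sums, expected)


class TestFilterClusters:
    def test_boundary_inclusive(self):
        (tc,) = cluster_ctss(_matrix([100], {100: [1, 0]}), gap=20)
        tc.tpm = np.array([0.9, 1.0])
        assert filter_clusters([tc], min_tpm=1.0) == [tc]

    def test_all_zero_removed(self):
        (tc,) = cluster_ctss(_matrix([100], {100: [1, 0]}), gap=20)
        tc.tpm = np.array([0.0, 0.0])
        assert filter_clusters([tc], min_tpm=1.0) == []

    def test_matches_threshold_scan(self):
        rng = np.random.default_rng(4)
        clusters = cluster_ctss(
            _matrix(list(range(100, 4000, 50)),
                    {p: rng.poisson(2, 2) for p in range(100, 4000, 50)}), gap=20)
        for tc in clusters:
            tc.tpm = rng.random(2) * 3
        kept = filter_clusters(clusters, min_tpm=1.0, min_samples=1)
        expected = [tc for tc in clusters if (tc.tpm >= 1.0).sum() >= 1]
        assert kept == expected


class TestGroupPromoters:
    def _clusters(self, spans, strand="+"):
        out = []
        for i, (s, e) in enumerate(spans):
            out.append(TagCluster(
                tc_id=f"TC{i}", chrom="chr1", strand=strand, start=s, end=e,
                member_positions=[s, e] if e > s else [s],
                member_counts=[[1]] * (2 if e > s else 1), samples=["s1"]))
        return out

    def test_edge_distance_merge(self):
        proms = group_promoters(self._clusters([(100, 120), (190, 210)]), gap=100)
        assert len(proms) == 1 and (proms[0].start, proms[0].end) == (100, 210)

    def test_distant_clusters_stay_separate(self):
        proms = group_promoters(self._clusters([(100, 120), (300, 310)]), gap=100)
        assert len(proms) == 2

    def test_opposite_strands_never_merge(self):
        plus = self._clusters([(100, 120)], "+")
        minus = self._clusters([(100, 120)], "-")
        assert len(group_promoters(plus + minus, gap=100)) == 2

    def test_oracle_interval_closure(self):
        rng = np.random.default_rng(8)
        spans = []
        x = 10
        for _ in range(30):
            x += int(rng.integers(10, 200))
            w = int(rng.integers(0, 40))
            spans.append((x, x + w))
            x += w
        clusters = self._clusters(spans)
        gap = 100

        def connected(i, j):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            return max(s1, s2) - min(e1, e2) <= gap

        comps = union_find_components(len(spans), connected)
        expected = {frozenset(spans[i] for i in c) for c in comps}
        got = {frozenset((tc.start, tc.end) for tc in p.clusters)
               for p in group_promoters(clusters, gap)}
        assert got == expected

    def test_expression_sums_members(self):
        clusters = self._clusters([(100, 120), (150, 160)])
        for tc in clusters:
            tc.tpm = np.array([2.5])
        (p,) = group_promoters(clusters, gap=100)
        assert p.expression.tolist() == [5.0]


class TestDominant:
    def test_argmax(self):
        m = _matrix([100, 110], {100: [5, 0], 110: [9, 0]})
        (tc,) = cluster_ctss(m, gap=20)
        assert dominant_ctss(tc, m) == 110

    def test_tie_breaks_to_smaller_coordinate(self):
        m = _matrix([100, 110], {100: [5, 0], 110: [5, 0]})
        (tc,) = cluster_ctss(m, gap=20)
        assert dominant_ctss(tc, m) == 100

    def test_random_equals_argmax_of_summed_rows(self):
        rng = np.random.default_rng(2)
        positions = list(range(500, 520))
        counts = {p: rng.poisson(3, 2) for p in positions}
        m = _matrix(positions, counts)
        (tc,) = cluster_ctss(m, gap=20)
        sums = {p: sum(counts[p]) for p in positions}
        best = min(p for p in positions if sums[p] == max(sums.values()))
        assert dominant_ctss(tc, m) == best
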