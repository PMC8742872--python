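import numpy as np
import pandas as pd
import pytest

from cageshift.annotation import (assign_and_rank, classify_arch,
                                  classify_proximity, classify_tss_distance,
                                  feature_distance, gene_region, has_tata)
from cageshift.clustering import TagCluster, PromoterRegion
from cageshift.model import GeneModel


def make_promoter(start, end, strand="+", chrom="chr1", tpm=(10.0,), pid="P1",
                  dominant=None):
    dom = dominant if dominant is not None else start
    positions = sorted({start, dom, end})
    counts = [[5] if p == dom else [1] for p in positions]
    tc = TagCluster(tc_id=pid + "_tc", chrom=chrom, strand=strand,
                    start=start, end=end, member_positions=positions,
                    member_counts=counts, samples=["s1"])
    tc.tpm = np.array(tpm)
    return PromoterRegion(promoter_id=pid, chrom=chrom, strand=strand,
                          start=start, end=end, clusters=[tc])


class TestGeneRegion:
    def test_plus_strand_upstream_extension(self):
        g = GeneModel("g", "chr1", "+", 5000, 10000)
        assert gene_region(g, 1000) == (4000, 10000)

    def test_minus_strand_upstream_extension(self):
        g = GeneModel("g", "chr1", "-", 5000, 10000)
        assert gene_region(g, 1000) == (5000, 11000)


class TestAssignAndRank:
    def test_minus_strand_assignment(self):
        g = GeneModel("g", "chr1", "-", 5000, 10000, {10000})
        p = make_promoter(10400, 10500, strand="-")
        (ann,) = assign_and_rank([p], [g])
        assert ann.gene_id == "g" and p.rank == 1

    def test_rank_by_descending_expression(self):
        g = GeneModel("g", "chr1", "+", 100, 9000, {100})
        ps = [make_promoter(200, 210, tpm=(10.0,), pid="a"),
              make_promoter(400, 410, tpm=(30.0,), pid="b"),
              make_promoter(600, 610, tpm=(5.0,), pid="c")]
        assign_and_rank(ps, [g])
        assert [p.rank for p in ps] == [2, 1, 3]

    def test_wrong_strand_is_intergenic(self):
        g = GeneModel("g", "chr1", "-", 5000, 10000)
        p = make_promoter(6000, 6010, strand="+")
        (ann,) = assign_and_rank([p], [g])
        assert ann.gene_id is None and ann.tss_class == "intergenic"
        assert p.rank == 1  # intergenic promoters keep a P1 rank

    def test_multi_gene_overlap_resolves_to_nearest_region_start(self):
        g1 = GeneModel("g1", "chr1", "+", 1000, 4000)
        g2 = GeneModel("g2", "chr1", "+", 2900, 8000)
        p = make_promoter(3000, 3010)
        (ann,) = assign_and_rank([p], [g1, g2])
        assert ann.gene_id == "g2"

    def test_ranks_gap_free_and_sorted(self):
        rng = np.random.default_rng(0)
        g = GeneModel("g", "chr1", "+", 100, 90_000, {100})
        ps = [make_promoter(200 + 300 * i, 210 + 300 * i,
                            tpm=(float(rng.integers(1, 50)),), pid=f"p{i}")
              for i in range(8)]
        assign_and_rank(ps, [g])
        ranks = sorted(p.rank for p in ps)
        assert ranks == list(range(1, 9))
        by_rank = sorted(ps, key=lambda p: p.rank)
        expr = [p.mean_expression for p in by_rank]
        assert expr == sorted(expr, reverse=True)


class TestTssDistance:
    def test_containment_is_exact(self):
        assert classify_tss_distance(make_promoter(200, 230), {210}) == "exact"

    def test_within_100(self):
        assert classify_tss_distance(make_promoter(200, 230), {150}) == "within_100"

    def test_unannotated_far(self):
        assert classify_tss_distance(make_promoter(200, 230), {5000}) == "unannotated"

    def test_within_1000(self):
        assert classify_tss_distance(make_promoter(200, 230), {1100}) == "within_1000"

    def test_boundaries_inclusive(self):
        assert classify_tss_distance(make_promoter(200, 230), {100}) == "within_100"
        assert classify_tss_distance(make_promoter(200, 230), {99}) == "within_1000"

    def test_bin_monotonicity(self):
        # widening a bin never decreases its count
        rng = np.random.default_rng(5)
        promoters = [make_promoter(int(s), int(s) + 30, pid=f"p{i}")
                     for i, s in enumerate(rng.integers(1000, 50_000, 40))]
        tss = {int(t) for t in rng.integers(1000, 50_000, 10)}
        narrow = sum(classify_tss_distance(p, tss, (0, 50, 1000)) == "within_100"
                     for p in promoters)
        wide = sum(classify_tss_distance(p, tss, (0, 100, 1000)) == "within_100"
                   for p in promoters)
        assert wide >= narrow


class TestProximity:
    def test_overlap_bin_zero(self):
        p = make_promoter(200, 230)
        assert classify_proximity([p], {230})[p.promoter_id] == 0

    def test_outside_all_bins(self):
        p = make_promoter(200, 230)
        assert classify_proximity([p], {800})[p.promoter_id] is None

    def test_counts_match_all_pairs_scan(self):
        rng = np.random.default_rng(6)
        promoters = [make_promoter(int(s), int(s) + 20, pid=f"p{i}")
                     for i, s in enumerate(rng.integers(100, 20_000, 30))]
        tss = sorted(int(t) for t in rng.integers(100, 20_000, 15))
        got = classify_proximity(promoters, tss, (0, 100, 500))
        for p in promoters:
            d = min(max(t - p.end, p.start - t, 0) for t in tss)
            expected = 0 if d == 0 else 100 if d <= 100 else 500 if d <= 500 else None
            assert got[p.promoter_id] == expected


class TestArchitecture:
    GENOME = {"chr1": "G" * 3000}

    def test_cpg_flank_overlap(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1500]})
        p = make_promoter(1600, 1650)
        assert classify_arch(p, islands, self.GENOME, cpg_flank=200) == "CpG_only"

    def test_tata_consensus_match(self):
        seq = "G" * 1000 + "TATAAATA" + "G" * 1000
        p = make_promoter(1100, 1120, dominant=1100)
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
        assert classify_arch(p, islands, {"chr1": seq}) == "TATA_only"

    def test_tata_on_minus_strand_window(self):
        # motif on the promoter (minus) strand downstream in coordinates
        from cageshift.annotation import revcomp
        motif = revcomp("TATAAATA")
        seq = "G" * 1130 + motif + "G" * 1000
        p = make_promoter(1100, 1120, strand="-", dominant=1100)
        assert has_tata(p, {"chr1": seq})

    def test_neither(self):
        p = make_promoter(1600, 1650)
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
        assert classify_arch(p, islands, self.GENOME) == "neither"

    def test_both(self):
        seq = "G" * 1000 + "TATATAAG" + "G" * 1000
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [1090], "end": [1130]})
        p = make_promoter(1100, 1120, dominant=1100)
        assert classify_arch(p, islands, {"chr1": seq}) == "both"

    def test_window_truncated_at_chromosome_edge(self):
        p = make_promoter(10, 20, dominant=10)
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
        assert classify_arch(p, islands, {"chr1": "G" * 100}) == "neither"

    def test_pluggable_matcher(self):
        p = make_promoter(1600, 1650)
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
        assert classify_arch(p, islands, self.GENOME,
                             tata_matcher=lambda s: True) == "TATA_only"

    def test_classes_partition(self, sim_experiment):
        _, exp = sim_experiment
        from cageshift.ctss import filter_ctss
        from cageshift.clustering import cluster_ctss, normalize_tpm, group_promoters
        m = filter_ctss(exp.matrix)
        clusters = normalize_tpm(cluster_ctss(m), m.sample_totals)
        promoters = group_promoters(clusters)
        classes = [classify_arch(p, exp.cpg_islands, exp.genome) for p in promoters]
        counts = {c: classes.count(c) for c in set(classes)}
        assert sum(counts.values()) == len(promoters)


class TestFeatureDistance:
    def test_worked_example_346(self):
        assert feature_distance(1_816_432, 1_816_086, "-") == (346, "upstream")

    def test_worked_example_414(self):
        assert feature_distance(1_816_500, 1_816_086, "-") == (414, "upstream")

    def test_same_position(self):
        assert feature_distance(5, 5, "+") == (0, "same")

    def test_plus_strand_orientation(self):
        assert feature_distance(100, 200, "+") == (100, "upstream")
        assert feature_distance(300, 200, "+") == (100, "downstream")

    def test_minus_strand_downstream(self):
        assert feature_distance(100, 200, "-") == (100, "downstream")

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            feature_distance(1, 2, ".")
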