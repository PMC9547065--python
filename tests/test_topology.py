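"""SE/TAD/loop topology statistics vs all-pairs oracles and planted truth."""

import numpy as np
import pytest

from chromhub.core import GenomicInterval, GeneRecord, Loop
from chromhub.matrix import CompartmentCall
from chromhub.synth import conserved_genome_pair
from chromhub.topology import (
    classify_tads,
    crossing_fraction,
    gene_pair_conservation,
    geneset_tss_overlap_fraction,
    mean_expression_in_regions,
    place_regions_in_tads,
    region_contact_features,
    region_loop_summary,
    tad_loop_stats,
)


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def _loop(s1, s2, chrom="chr1", w=5000):
    return Loop(GenomicInterval(chrom, s1, s1 + w), GenomicInterval(chrom, s2, s2 + w))


TADS = [_iv(0, 500_000), _iv(500_000, 1_200_000), _iv(1_200_000, 2_000_000)]


class TestPlacement:
    def test_edge_and_non_edge(self):
        pl = place_regions_in_tads([_iv(100_000, 120_000), _iv(200_000, 220_000)],
                                   [_iv(100_000, 500_000)])
        assert pl[0].position_class == "edge" and pl[0].boundary_distance == 0
        assert pl[1].position_class == "non_edge" and pl[1].boundary_distance == 100_000

    def test_outside_and_spanning(self):
        pl = place_regions_in_tads([_iv(490_000, 510_000), _iv(2_100_000, 2_150_000)], TADS)
        assert pl[0].position_class == "spanning_boundary"
        assert pl[1].position_class == "outside_tad"

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError):
            place_regions_in_tads([], [_iv(0, 100), _iv(50, 200)])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(43)
        regions = []
        for _ in range(500):
            s = int(rng.integers(0, 1_990_000))
            regions.append(_iv(s, s + int(rng.integers(1000, 60_000))))
        placements = place_regions_in_tads(regions, TADS, edge_threshold=5000)
        for r, pl in zip(regions, placements):
            host = next((t for t in TADS if t.start <= r.start and r.end <= t.end), None)
            touching = [t for t in TADS if r.start < t.end and t.start < r.end]
            if host:
                d = min(r.start - host.start, host.end - r.end)
                want = "edge" if d < 5000 else "non_edge"
                assert pl.position_class == want and pl.boundary_distance == d
            elif touching:
                assert pl.position_class == "spanning_boundary"
            else:
                assert pl.position_class == "outside_tad"

    def test_classes_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(47)
        regions = [_iv(int(s), int(s) + 10_000) for s in rng.integers(0, 1_900_000, 300)]
        placements = place_regions_in_tads(regions, TADS)
        assert len(placements) == len(regions)
        assert all(pl.position_class in
                   {"edge", "non_edge", "outside_tad", "spanning_boundary"}
                   for pl in placements)


class TestClassifyTads:
    def _compartments(self):
        segs = [(_iv(0, 1_200_000), "A", 1.0), (_iv(1_200_000, 2_000_000), "B", -1.0)]
        return CompartmentCall("chr1", 5000, np.array([]), [], segs)

    def test_planted_groups(self):
        comp = self._compartments()
        ses = [_iv(2000, 20_000), _iv(700_000, 720_000)]
        pl = place_regions_in_tads(ses, TADS)
        out = classify_tads(TADS, comp, pl)
        assert [c.group for c in out] == ["A_edge_SE", "A_nonedge_SE", "B_compartment"]

    def test_straddling_tad_unassigned(self):
        segs = [(_iv(0, 300_000), "A", 1.0), (_iv(300_000, 2_000_000), "B", -1.0)]
        comp = CompartmentCall("chr1", 5000, np.array([]), [], segs)
        out = classify_tads(TADS, comp, [])
        assert out[0].group == "unassigned"

    def test_no_ses_collapses_groups(self):
        comp = self._compartments()
        ses = [_iv(2000, 20_000), _iv(700_000, 720_000)]
        with_se = classify_tads(TADS, comp, place_regions_in_tads(ses, TADS))
        without = classify_tads(TADS, comp, [])
        assert [c.group for c in without] == ["A_no_SE", "A_no_SE", "B_compartment"]
        # A/B split identical
        a_with = sum(c.group.startswith("A") for c in with_se)
        a_without = sum(c.group.startswith("A") for c in without)
        assert a_with == a_without

    def test_planted_truth_recovery_on_bundle(self, bundle):
        comp = {}
        for chrom in bundle.build.chromosomes:
            segs = [(seg, lab, 1.0 if lab == "A" else -1.0)
                    for seg, lab in bundle.compartment_segments if seg.chrom == chrom]
            comp[chrom] = CompartmentCall(chrom, bundle.config.bin_size,
                                          np.array([]), [], segs)
        ses = [GenomicInterval(s["chrom"], s["start"], s["end"]) for s in bundle.truth.ses]
        placements = place_regions_in_tads(ses, bundle.tads)
        out = classify_tads(bundle.tads, comp, placements)
        for cls in out:
            key = f"{cls.tad.chrom}:{cls.tad.start}-{cls.tad.end}"
            assert cls.group == bundle.truth.tad_groups[key]


class TestLoopStats:
    def test_contact_and_crossing_definitions(self):
        loops = [_loop(100_000, 200_000), _loop(450_000, 550_000)]
        out = tad_loop_stats([TADS[0]], loops)
        assert out[0].n_loops_in_contact == 2
        assert out[0].pct_crossing == pytest.approx(50.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(53)
        loops = []
        for _ in range(50):
            s1 = int(rng.integers(0, 1_800_000))
            s2 = s1 + int(rng.integers(20_000, 150_000))
            loops.append(_loop(s1, s2))
        tads5 = [_iv(i * 400_000, (i + 1) * 400_000) for i in range(5)]
        out = tad_loop_stats(tads5, loops)
        for tad, st in zip(tads5, out):
            contact = [lp for lp in loops
                       if lp.footA.overlaps(tad) or lp.footB.overlaps(tad)]
            crossing = [lp for lp in contact
                        if lp.footA.overlaps(tad) != lp.footB.overlaps(tad)]
            assert st.n_loops_in_contact == len(contact)
            if contact:
                assert st.mean_loop_size == pytest.approx(np.mean([lp.size for lp in contact]))
                assert st.pct_crossing == pytest.approx(100 * len(crossing) / len(contact))


class TestRegionLoopSummary:
    def test_internal_vs_touching(self):
        region = _iv(100_000, 150_000)
        internal = _loop(105_000, 140_000)
        touching = _loop(120_000, 400_000)
        out = region_loop_summary([region], [internal, touching])
        assert out.touching_counts == [2]
        assert out.internal_counts == [1]

    def test_straddling_loop_touches_both_regions(self):
        regions = [_iv(0, 50_000), _iv(400_000, 450_000)]
        out = region_loop_summary(regions, [_loop(10_000, 410_000)])
        assert out.touching_counts == [1, 1]
        assert out.internal_counts == [0, 0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(59)
        regions = [_iv(int(s), int(s) + 50_000) for s in rng.integers(0, 1_900_000, 30)]
        loops = []
        for _ in range(200):
            s1 = int(rng.integers(0, 1_800_000))
            loops.append(_loop(s1, s1 + int(rng.integers(10_000, 120_000))))
        out = region_loop_summary(regions, loops)
        for i, r in enumerate(regions):
            touch = sum(lp.footA.overlaps(r) or lp.footB.overlaps(r) for lp in loops)
            internal = sum(r.contains(lp.footA) and r.contains(lp.footB) for lp in loops)
            assert out.touching_counts[i] == touch
            assert out.internal_counts[i] == internal


class TestContactFeatures:
    def test_unique_counting(self):
        se = _iv(0, 50_000)
        cre = _iv(300_000, 302_000)
        genes = [GeneRecord("g1", "g1", "+", _iv(299_000, 320_000)),
                 GeneRecord("g2", "g2", "+", _iv(301_000, 330_000))]
        loops = [_loop(10_000, 298_000), _loop(20_000, 298_000)]
        out = region_contact_features([se], loops, [cre], genes)
        assert out.unique_cres == 1   # both loops reach the same CRE
        assert out.unique_tss == 2    # TSSs of g1 and g2 inside [298,000,303,000)

    def test_se_to_se_contacts(self):
        regions = [_iv(0, 50_000), _iv(400_000, 450_000)]
        out = region_contact_features(regions, [_loop(10_000, 410_000)], [], [])
        assert out.unique_regions == 2  # each sees the other


class TestCrossingFraction:
    def test_extremes(self):
        regions = [_iv(100_000, 150_000)]
        intra = [_loop(110_000, 300_000)]
        cross = [_loop(110_000, 600_000)]
        assert crossing_fraction(regions, intra, TADS) == 0.0
        assert crossing_fraction(regions, cross, TADS) == 100.0

    def test_no_touching_loops_flagged(self):
        assert np.isnan(crossing_fraction([_iv(0, 1000)], [_loop(500_000, 600_000)], TADS))


class TestExpression:
    def _genes(self):
        return [GeneRecord("a", "a", "+", _iv(10_000, 30_000), expression=10.0),
                GeneRecord("b", "b", "+", _iv(50_000, 70_000), expression=20.0),
                GeneRecord("c", "c", "+", _iv(300_000, 320_000), expression=5.0)]

    def test_fold_arithmetic(self):
        out = mean_expression_in_regions(self._genes(), [_iv(0, 100_000)],
                                         [_iv(290_000, 310_000)])
        assert out["mean"] == pytest.approx(15.0)
        assert out["fold"] == pytest.approx(3.0)

    def test_identical_sets_fold_one(self):
        out = mean_expression_in_regions(self._genes(), [_iv(0, 100_000)], [_iv(0, 100_000)])
        assert out["fold"] == pytest.approx(1.0)

    def test_gene_counted_once_with_overlapping_regions(self):
        out = mean_expression_in_regions(self._genes(), [_iv(0, 100_000), _iv(5000, 60_000)])
        assert out["n_genes"] == 2

    def test_planted_boost_recovered(self, bundle):
        ses = [GenomicInterval(s["chrom"], s["start"], s["end"]) for s in bundle.truth.ses]
        se_spans = set()
        for s in ses:
            se_spans.add((s.chrom, s.start, s.end))
        # comparison: typical-enhancer CREs (never SE-boosted)
        typ = [GenomicInterval(c, s, e) for c, s, e in bundle.truth.typical]
        boosted_mean = np.mean([g.expression for g in bundle.genes
                                if g.gene_id in set(bundle.truth.boosted_genes)])
        other_mean = np.mean([g.expression for g in bundle.genes
                              if g.gene_id not in set(bundle.truth.boosted_genes)])
        assert 1.6 <= boosted_mean / other_mean <= 2.4


class TestGenesetOverlap:
    def test_extremes_and_oracle(self):
        genes = [GeneRecord(f"g{i}", f"g{i}", "+", _iv(i * 10_000, i * 10_000 + 5000))
                 for i in range(10)]
        all_cover = [_iv(0, 200_000)]
        assert geneset_tss_overlap_fraction(genes, all_cover) == 100.0
        assert geneset_tss_overlap_fraction(genes, [_iv(900_000, 910_000)]) == 0.0
        some = [_iv(0, 25_000)]  # covers TSS of g0,g1,g2
        assert geneset_tss_overlap_fraction(genes, some) == pytest.approx(30.0)

    def test_empty_geneset_errors(self):
        with pytest.raises(ValueError):
            geneset_tss_overlap_fraction([], [_iv(0, 10)])


class TestConservation:
    def test_identity_map_full_conservation(self):
        tads_a, loops_a, genes_a, tads_b, loops_b, genes_b, omap = conserved_genome_pair(
            n_pairs=10, tad_fraction=1.0, loop_fraction=1.0, seed=1)
        out = gene_pair_conservation(tads_a, loops_a, genes_a,
                                     tads_b, loops_b, genes_b, omap)
        assert out.frac_shared_tad_conserved == 1.0
        assert out.frac_loop_conserved == 1.0

    def test_no_shared_pairs(self):
        out_ = conserved_genome_pair(n_pairs=10, tad_fraction=0.0, loop_fraction=0.0, seed=2)
        res = gene_pair_conservation(*out_)
        assert res.frac_shared_tad_conserved == 0.0
        assert res.frac_loop_conserved == 0.0

    def test_planted_fraction_recovered_exactly(self):
        out_ = conserved_genome_pair(n_pairs=20, tad_fraction=0.4, loop_fraction=0.4, seed=3)
        res = gene_pair_conservation(*out_)
        assert res.n_pairs_shared_tad_b == 20
        assert res.frac_shared_tad_conserved == pytest.approx(0.4)
        assert res.frac_loop_conserved == pytest.approx(0.4)

    def test_non_bijective_map_rejected(self):
        t = conserved_genome_pair(n_pairs=4, seed=4)
        bad = dict(t[6])
        keys = list(bad)
        bad[keys[0]] = bad[keys[1]]
        with pytest.raises(ValueError):
            gene_pair_conservation(t[0], t[1], t[2], t[3], t[4], t[5], bad)
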