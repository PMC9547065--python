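"""ROSE-style super-enhancer stage: state merging, TSS exclusion,
stitching, constituent signal, and the rank-curve elbow cutoff."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromhub.core import GenomeBuild, GenomicInterval, GeneRecord, SignalTrack
from chromhub.se import (
    CRE,
    ChromatinStateSegment,
    StitchedRegion,
    exclude_tss_cres,
    merge_active_states,
    region_signal,
    rose_cutoff,
    se_summary,
    stitch,
)


def _seg(start, end, state, chrom="chr1"):
    return ChromatinStateSegment(GenomicInterval(chrom, start, end), state)


def _cre(start, end, chrom="chr1"):
    return CRE(GenomicInterval(chrom, start, end), ("enhancer_1",), False)


def _regions(signals):
    return [
        StitchedRegion(GenomicInterval("chr1", i * 10_000, i * 10_000 + 1000),
                       [_cre(i * 10_000, i * 10_000 + 1000)],
                       case_signal=float(s), control_signal=0.0)
        for i, s in enumerate(signals)
    ]


class TestMergeActiveStates:
    def test_adjacent_active_merge(self):
        cres = merge_active_states([_seg(0, 500, "enhancer_1"), _seg(500, 900, "enhancer_2")])
        assert [(c.interval.start, c.interval.end) for c in cres] == [(0, 900)]

    def test_inactive_excluded(self):
        cres = merge_active_states([_seg(0, 500, "enhancer_1"), _seg(500, 900, "heterochromatin")])
        assert [(c.interval.start, c.interval.end) for c in cres] == [(0, 500)]

    def test_promoter_flag(self):
        cres = merge_active_states([_seg(0, 500, "promoter"), _seg(500, 900, "enhancer_1")])
        assert cres[0].is_promoter_state

    def test_unknown_active_label_errors(self):
        with pytest.raises(ValueError):
            merge_active_states([_seg(0, 10, "promoter")], active_states={"nonsense"})

    def test_matches_union_oracle(self):
        rng = np.random.default_rng(21)
        states = ["promoter", "enhancer_1", "enhancer_2", "heterochromatin", "low_1"]
        segs = []
        pos = 0
        while pos < 500_000:
            length = int(rng.integers(200, 3000))
            segs.append(_seg(pos, pos + length, states[rng.integers(0, len(states))]))
            pos += length
        active = {"promoter", "enhancer_1", "enhancer_2"}
        cres = merge_active_states(segs, active)
        paint = np.zeros(500_000 + 3000, dtype=bool)
        for s in segs:
            if s.state in active:
                paint[s.interval.start : s.interval.end] = True
        runs = []
        i = 0
        while i < len(paint):
            if paint[i]:
                j = i
                while j < len(paint) and paint[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        assert [(c.interval.start, c.interval.end) for c in cres] == runs


class TestExcludeTss:
    def _genes(self):
        return [GeneRecord("g", "g", "+", GenomicInterval("chr1", 2500, 20_000))]

    def test_contained_removed_partial_kept(self):
        # promoter window is [0, 5000) for TSS 2500, halfwidth 2500
        kept = exclude_tss_cres([_cre(1000, 2000), _cre(4000, 7000)], self._genes())
        assert [(c.interval.start, c.interval.end) for c in kept] == [(4000, 7000)]

    def test_matches_containment_oracle(self):
        rng = np.random.default_rng(23)
        genes = [GeneRecord(f"g{i}", f"g{i}", "+",
                            GenomicInterval("chr1", int(p), int(p) + 10_000))
                 for i, p in enumerate(rng.integers(5000, 900_000, size=20))]
        cres = [_cre(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 950_000, size=100),
                                rng.integers(100, 8000, size=100))]
        kept = exclude_tss_cres(cres, genes)
        expect = []
        for c in cres:
            windows = [(g.tss - 2500, g.tss + 2500) for g in genes]
            contained = any(w0 <= c.interval.start and c.interval.end <= w1
                            for w0, w1 in windows)
            if not contained:
                expect.append(c)
        assert kept == expect


class TestStitch:
    def test_gap_arithmetic(self):
        stitched = stitch([_cre(0, 1000), _cre(5000, 6000), _cre(30_000, 31_000)], 12_500)
        spans = [(r.interval.start, r.interval.end) for r in stitched]
        assert spans == [(0, 6000), (30_000, 31_000)]
        assert len(stitched[0].constituents) == 2

    def test_zero_distance_is_identity(self):
        cres = [_cre(0, 1000), _cre(1000, 2000), _cre(5000, 6000)]
        assert len(stitch(cres, 0)) == 3

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(31)
        starts = np.sort(rng.choice(np.arange(0, 2_000_000, 100), size=200, replace=False))
        cres = [_cre(int(s), int(s) + int(rng.integers(100, 2000))) for s in starts]
        cres = [c for i, c in enumerate(cres)
                if i == 0 or c.interval.start >= cres[i - 1].interval.end]
        d = 12_500
        stitched = stitch(cres, d)
        # oracle: transitive closure of gap<d on the sorted list
        groups, cur = [], [cres[0]]
        for c in cres[1:]:
            if c.interval.start - cur[-1].interval.end < d:
                cur.append(c)
            else:
                groups.append(cur)
                cur = [c]
        groups.append(cur)
        assert [(r.interval.start, r.interval.end) for r in stitched] == [
            (g[0].interval.start, g[-1].interval.end) for g in groups
        ]

    def test_monotone_region_count(self):
        rng = np.random.default_rng(37)
        starts = np.sort(rng.choice(np.arange(0, 1_000_000, 50), size=150, replace=False))
        cres = [_cre(int(s), int(s) + 40) for s in starts]
        counts = [len(stitch(cres, d)) for d in (0, 1000, 5000, 12_500, 50_000)]
        assert counts == sorted(counts, reverse=True)


class TestRegionSignal:
    def test_constituent_only_sum_and_floor(self, small_build):
        case = SignalTrack(small_build, 100,
                           {c: np.full(-(-small_build[c] // 100), 2.0) for c in small_build})
        ctrl = SignalTrack(small_build, 100,
                           {c: np.full(-(-small_build[c] // 100), 1.0) for c in small_build})
        region = StitchedRegion(GenomicInterval("chr1", 0, 10_000),
                                [_cre(0, 400), _cre(9000, 9600)])
        region_signal([region], case, ctrl)
        assert region.net_signal == pytest.approx(1000.0)  # 1000 bp constituents
        region_signal([region], ctrl, case)  # control > case
        assert region.net_signal == 0.0

    def test_matches_per_bp_oracle(self, small_build):
        rng = np.random.default_rng(41)
        vals = {c: rng.random(-(-small_build[c] // 250)) for c in small_build}
        case = SignalTrack(small_build, 250, vals)
        per_bp = {c: np.repeat(v, 250)[: small_build[c]] for c, v in vals.items()}
        cres = [_cre(int(s), int(s) + int(rng.integers(100, 3000)))
                for s in rng.integers(0, 900_000, size=30)]
        region = StitchedRegion(GenomicInterval("chr1", 0, 1_000_000), cres)
        region_signal([region], case, None)
        want = sum(per_bp["chr1"][c.interval.start : c.interval.end].sum() for c in cres)
        assert region.case_signal == pytest.approx(want)


class TestRoseCutoff:
    def test_all_equal_signals_no_se(self):
        with pytest.warns(UserWarning):
            call = rose_cutoff(_regions([5, 5, 5, 5]))
        assert call.n_se == 0

    def test_linear_signals_no_se(self):
        call = rose_cutoff(_regions([0, 1, 2, 3, 4]))
        assert call.n_se == 0  # y == x everywhere; tie rule takes last index

    def test_hockey_stick_matches_exhaustive_scan(self):
        signals = [1, 1, 1, 1, 2, 3, 50, 60, 100]
        call = rose_cutoff(_regions(signals))
        s = np.sort(np.array(signals, dtype=float))
        x = np.arange(len(s)) / (len(s) - 1)
        y = (s - s[0]) / (s[-1] - s[0])
        diffs = y - x
        k = max(i for i, d in enumerate(diffs) if d == diffs.min())
        assert call.cutoff_index == k
        assert call.n_se == int((s > s[k]).sum())
        assert call.n_se == 3

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=40),
           st.floats(0.1, 100), st.floats(0, 1e3))
    def test_affine_rescaling_invariance(self, signals, scale, shift):
        call1 = rose_cutoff(_regions(signals))
        call2 = rose_cutoff(_regions([s * scale + shift for s in signals]))
        assert call1.cutoff_index == call2.cutoff_index
        assert np.array_equal(call1.is_se, call2.is_se)

    def test_se_subset_of_regions(self):
        regions = _regions([1, 2, 3, 4, 100, 200])
        call = rose_cutoff(regions)
        assert set(id(r) for r in call.super_enhancers) <= set(id(r) for r in call.regions)
        assert call.n_se + int((~call.is_se).sum()) == len(regions)


class TestSeSummary:
    def _call(self, per_chrom, build):
        regions = []
        for chrom, n in per_chrom.items():
            for i in range(n):
                regions.append(StitchedRegion(
                    GenomicInterval(chrom, i * 20_000, i * 20_000 + 10_000),
                    [_cre(i * 20_000, i * 20_000 + 10_000, chrom)],
                    case_signal=1000.0 + i,
                ))
        x = np.arange(len(regions), dtype=float)
        from chromhub.se import SuperEnhancerCall
        return SuperEnhancerCall(regions, x, x, 0, -1.0, np.ones(len(regions), dtype=bool))

    def test_proportional_counts_r2_one(self):
        build = GenomeBuild({"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 3_000_000})
        call = self._call({"chr1": 5, "chr2": 10, "chr3": 15}, build)
        out = se_summary(call, build, [])
        assert out["r2_vs_chrom_size"] == pytest.approx(1.0)

    def test_constant_counts_flagged(self):
        build = GenomeBuild({"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 3_000_000})
        call = self._call({"chr1": 5, "chr2": 5, "chr3": 5}, build)
        out = se_summary(call, build, [])
        assert out["r2_vs_chrom_size"] is None and out["flagged"]

    def test_gene_tracking_counts_beat_size_correlation(self):
        # SE counts planted proportional to per-chromosome gene counts that
        # are deliberately decoupled from chromosome size
        build = GenomeBuild({"chr1": 4_000_000, "chr2": 3_000_000,
                             "chr3": 2_000_000, "chr4": 1_000_000})
        gene_counts = {"chr1": 2, "chr2": 12, "chr3": 4, "chr4": 9}
        genes = []
        for chrom, n in gene_counts.items():
            for i in range(n):
                genes.append(GeneRecord(f"{chrom}_g{i}", f"{chrom}_g{i}", "+",
                                        GenomicInterval(chrom, i * 30_000, i * 30_000 + 10_000),
                                        expression=5.0))
        call = self._call({c: 2 * n for c, n in gene_counts.items()}, build)
        out = se_summary(call, build, genes)
        assert out["r2_vs_expressed_genes"] == pytest.approx(1.0)
        assert out["r2_vs_expressed_genes"] > out["r2_vs_chrom_size"]
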