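"""CRE derivation and ROSE-style super-enhancer calling.

Active chromatin-state segments merge into cis-regulatory elements (CREs);
CREs within a stitching distance chain into stitched regions; each stitched
region is scored by case-minus-control H3K27Ac coverage summed over its
constituent CREs; and the super-enhancer cutoff is the discrete
tangent-slope-1 elbow of the min-max-scaled ascending rank/signal curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    GenomeBuild,
    GenomicInterval,
    GeneRecord,
    IntervalIndex,
    SignalTrack,
    interval_signal,
    promoter_window,
)

__all__ = [
    "ChromatinStateSegment",
    "CRE",
    "StitchedRegion",
    "SuperEnhancerCall",
    "DEFAULT_ACTIVE_STATES",
    "merge_active_states",
    "exclude_tss_cres",
    "stitch",
    "region_signal",
    "rose_cutoff",
    "call_super_enhancers",
    "se_summary",
]

DEFAULT_ACTIVE_STATES = frozenset(
    ["promoter", "enhancer_1", "enhancer_2", "enhancer_3", "enhancer_4", "enhancer_5"]
)

STATE_VOCABULARY = frozenset(
    list(DEFAULT_ACTIVE_STATES)
    + ["heterochromatin", "low_1", "low_2", "low_3"]
)


@dataclass(frozen=True)
class ChromatinStateSegment:
    interval: GenomicInterval
    state: str


@dataclass(frozen=True)
class CRE:
    interval: GenomicInterval
    source_states: tuple[str, ...]
    is_promoter_state: bool


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituents: list[CRE]
    case_signal: float = 0.0
    control_signal: float = 0.0

    @property
    def net_signal(self) -> float:
        return max(self.case_signal - self.control_signal, 0.0)


@dataclass
class SuperEnhancerCall:
    """Ranked stitched regions with the elbow cutoff applied.

    ``regions`` is sorted ascending by net signal; ``x``/``y`` are the
    min-max-scaled rank and signal; regions strictly above the cutoff
    signal are flagged as super-enhancers.
    """

    regions: list[StitchedRegion]
    x: np.ndarray
    y: np.ndarray
    cutoff_index: int
    cutoff_signal: float
    is_se: np.ndarray

    @property
    def super_enhancers(self) -> list[StitchedRegion]:
        return [r for r, flag in zip(self.regions, self.is_se) if flag]

    @property
    def n_se(self) -> int:
        return int(self.is_se.sum())


def merge_active_states(
    segments: list[ChromatinStateSegment],
    active_states: frozenset[str] | set[str] = DEFAULT_ACTIVE_STATES,
    vocabulary: frozenset[str] | None = STATE_VOCABULARY,
) -> list[CRE]:
    """Merge overlapping/adjacent active-state segments into CREs."""
    if vocabulary is not None:
        unknown = set(active_states) - set(vocabulary)
        if unknown:
            raise ValueError(f"active states not in vocabulary: {sorted(unknown)}")
    active = [s for s in segments if s.state in active_states]
    per_chrom: dict[str, list[ChromatinStateSegment]] = {}
    for s in active:
        per_chrom.setdefault(s.interval.chrom, []).append(s)
    out: list[CRE] = []
    for chrom in per_chrom:
        segs = sorted(per_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        cur = [segs[0]]
        for s in segs[1:]:
            if s.interval.start <= max(x.interval.end for x in cur):  # overlap or touch
                cur.append(s)
            else:
                out.append(_make_cre(chrom, cur))
                cur = [s]
        out.append(_make_cre(chrom, cur))
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out


def _make_cre(chrom: str, segs: list[ChromatinStateSegment]) -> CRE:
    start = min(s.interval.start for s in segs)
    end = max(s.interval.end for s in segs)
    states = tuple(s.state for s in segs)
    return CRE(GenomicInterval(chrom, start, end), states, "promoter" in states)


def exclude_tss_cres(
    cres: list[CRE],
    genes: list[GeneRecord],
    promoter_halfwidth: int = 2500,
    build: GenomeBuild | None = None,
) -> list[CRE]:
    """Drop CREs fully contained in any TSS +/- halfwidth window.

    Partial overlaps are retained: only unambiguous promoter loci leave the
    enhancer pool.
    """
    windows = [promoter_window(g, promoter_halfwidth, build) for g in genes]
    index = IntervalIndex(windows)
    out = []
    for cre in cres:
        contained = any(
            index.intervals[j].contains(cre.interval)
            for j in index.overlapping(cre.interval)
        )
        if not contained:
            out.append(cre)
    return out


def stitch(cres: list[CRE], stitch_distance: int = 12_500) -> list[StitchedRegion]:
    """Chain CREs whose inter-CRE gap is < stitch_distance into regions."""
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    per_chrom: dict[str, list[CRE]] = {}
    for c in cres:
        per_chrom.setdefault(c.interval.chrom, []).append(c)
    out: list[StitchedRegion] = []
    for chrom in per_chrom:
        chain: list[CRE] = []
        for cre in sorted(per_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end)):
            if chain and cre.interval.start - max(c.interval.end for c in chain) < stitch_distance:
                chain.append(cre)
            else:
                if chain:
                    out.append(_make_region(chrom, chain))
                chain = [cre]
        if chain:
            out.append(_make_region(chrom, chain))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def _make_region(chrom: str, chain: list[CRE]) -> StitchedRegion:
    start = min(c.interval.start for c in chain)
    end = max(c.interval.end for c in chain)
    return StitchedRegion(GenomicInterval(chrom, start, end), list(chain))


def region_signal(
    regions: list[StitchedRegion],
    case_track: SignalTrack,
    control_track: SignalTrack | None,
) -> list[StitchedRegion]:
    """Score each region by coverage over its constituent CREs only.

    Gaps between constituents do not contribute (ROSE convention); the net
    signal floors case-minus-control at zero.
    """
    for region in regions:
        case = sum(interval_signal(case_track, c.interval) for c in region.constituents)
        if control_track is not None:
            ctrl = sum(interval_signal(control_track, c.interval) for c in region.constituents)
        else:
            ctrl = 0.0
        region.case_signal = float(case)
        region.control_signal = float(ctrl)
    return regions


def rose_cutoff(regions: list[StitchedRegion]) -> SuperEnhancerCall:
    """Find the rank-curve elbow and flag super-enhancers.

    Regions are sorted ascending by net signal; with rank and signal both
    scaled to [0,1], the cutoff index is argmin(y - x) — the discrete point
    where the curve's tangent reaches slope 1 on a convex hockey-stick —
    taking the largest index on ties (conservative: fewer SEs). Regions
    with net signal strictly above the cutoff signal are super-enhancers.
    """
    if len(regions) < 3:
        raise ValueError("need >=3 stitched regions for an elbow cutoff")
    order = sorted(range(len(regions)), key=lambda i: (regions[i].net_signal, i))
    ranked = [regions[i] for i in order]
    s = np.array([r.net_signal for r in ranked], dtype=float)
    n = len(s)
    x = np.arange(n) / (n - 1)
    if s[-1] == s[0]:
        warnings.warn("all region signals identical; no super-enhancers called")
        y = np.zeros(n)
        k = n - 1
    else:
        y = (s - s[0]) / (s[-1] - s[0])
        diff = y - x
        k = int(np.flatnonzero(diff == diff.min())[-1])  # largest index on ties
    cutoff = float(s[k])
    is_se = s > cutoff
    return SuperEnhancerCall(ranked, x, y, k, cutoff, is_se)


def call_super_enhancers(
    segments: list[ChromatinStateSegment],
    genes: list[GeneRecord],
    case_track: SignalTrack,
    control_track: SignalTrack | None,
    stitch_distance: int = 12_500,
    promoter_halfwidth: int = 2500,
    build: GenomeBuild | None = None,
    active_states=DEFAULT_ACTIVE_STATES,
) -> tuple[list[CRE], SuperEnhancerCall]:
    """Full SE pipeline: merge states, drop TSS CREs, stitch, score, cut."""
    cres = merge_active_states(segments, active_states)
    kept = exclude_tss_cres(cres, genes, promoter_halfwidth, build)
    regions = stitch(kept, stitch_distance)
    regions = region_signal(regions, case_track, control_track)
    return cres, rose_cutoff(regions)


def se_summary(
    call: SuperEnhancerCall,
    build: GenomeBuild,
    genes: list[GeneRecord],
    expressed_threshold: float = 0.0,
) -> dict:
    """Per-chromosome SE counts and their correlation with chromosome size
    and expressed-gene count (Pearson r^2), plus the SE size distribution.

    r^2 values are None (flagged) with fewer than 3 chromosomes or zero
    variance in either variable.
    """
    ses = call.super_enhancers
    counts = {c: 0 for c in build.chromosomes}
    for r in ses:
        counts[r.interval.chrom] += 1
    sizes = [r.interval.length for r in ses]
    expressed = {c: 0 for c in build.chromosomes}
    for g in genes:
        if g.expression is not None and g.expression > expressed_threshold:
            expressed[g.chrom] += 1

    chroms = build.chromosomes
    se_counts = np.array([counts[c] for c in chroms], dtype=float)
    chrom_sizes = np.array([build[c] for c in chroms], dtype=float)
    gene_counts = np.array([expressed[c] for c in chroms], dtype=float)

    def _r2(xv, yv):
        if len(xv) < 3 or np.std(xv) == 0 or np.std(yv) == 0:
            return None
        r, _ = stats.pearsonr(xv, yv)
        return float(r * r)

    return {
        "counts_per_chromosome": counts,
        "sizes": sizes,
        "r2_vs_chrom_size": _r2(chrom_sizes, se_counts),
        "r2_vs_expressed_genes": _r2(gene_counts, se_counts),
        "flagged": len(chroms) < 3 or np.std(se_counts) == 0,
    }
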