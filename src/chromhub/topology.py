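"""SE-centric topology statistics: placement within TADs, TAD grouping by
compartment and SE content, loop/region contact summaries, expression
comparisons, and the cross-species gene-pair conservation metric.

Every statistic here is computable both for the observed super-enhancer set
and for random-region sets, so each feeds directly into the resampling
enrichment comparison.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, GeneRecord, IntervalIndex, Loop
from .matrix import CompartmentCall

__all__ = [
    "SEPlacement",
    "TADClass",
    "TADLoopStats",
    "SEContactSummary",
    "ConservationSummary",
    "place_regions_in_tads",
    "classify_tads",
    "tad_loop_stats",
    "region_loop_summary",
    "region_contact_features",
    "crossing_fraction",
    "mean_expression_in_regions",
    "geneset_tss_overlap_fraction",
    "gene_pair_conservation",
]


@dataclass
class SEPlacement:
    region: GenomicInterval
    host_tad: GenomicInterval | None
    boundary_distance: int | None  # bp to nearest host-TAD boundary
    position_class: str  # edge / non_edge / outside_tad / spanning_boundary


@dataclass
class TADClass:
    tad: GenomicInterval
    group: str  # B_compartment / A_no_SE / A_nonedge_SE / A_edge_SE / unassigned


@dataclass
class TADLoopStats:
    tad: GenomicInterval
    n_loops_in_contact: int
    mean_loop_size: float  # NaN with no loops
    pct_crossing: float    # NaN with no loops


@dataclass
class SEContactSummary:
    touching_counts: list[int]        # loops with >=1 foot in each region
    internal_counts: list[int]        # loops with both feet in one region
    touching_loop_sizes: list[float]  # sizes of unique loops touching any region
    unique_cres: int = 0
    unique_tss: int = 0
    unique_regions: int = 0


@dataclass
class ConservationSummary:
    n_pairs_shared_tad_b: int
    frac_shared_tad_conserved: float
    n_pairs_loop_b: int
    frac_loop_conserved: float


def _check_disjoint(tads: list[GenomicInterval]) -> None:
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        per_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in per_chrom.items():
        ts = sorted(ts, key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping TADs on {chrom}: {a} / {b}")


def place_regions_in_tads(
    regions: list[GenomicInterval],
    tads: list[GenomicInterval],
    edge_threshold: int = 5000,
) -> list[SEPlacement]:
    """Classify each region by its position relative to the TAD layout.

    Hosted regions (fully inside one TAD) are `edge` when their minimum
    distance to a host boundary is < edge_threshold, else `non_edge`.
    Regions overlapping a TAD without containment are `spanning_boundary`;
    regions overlapping no TAD are `outside_tad`.
    """
    _check_disjoint(tads)
    index = IntervalIndex(tads)
    out = []
    for region in regions:
        hits = [index.intervals[j] for j in index.overlapping(region)]
        host = next((t for t in hits if t.contains(region)), None)
        if host is not None:
            dist = min(region.start - host.start, host.end - region.end)
            cls = "edge" if dist < edge_threshold else "non_edge"
            out.append(SEPlacement(region, host, int(dist), cls))
        elif hits:
            out.append(SEPlacement(region, None, None, "spanning_boundary"))
        else:
            out.append(SEPlacement(region, None, None, "outside_tad"))
    return out


def classify_tads(
    tads: list[GenomicInterval],
    compartments: CompartmentCall | dict[str, CompartmentCall],
    placements: list[SEPlacement],
    spanning_counts_as_edge: bool = True,
) -> list[TADClass]:
    """Group TADs by compartment membership and hosted-SE position.

    A TAD joins a compartment group only when every bp lies under segments
    of a single label; TADs straddling an A/B boundary (or uncovered bins)
    are `unassigned`. A-compartment TADs subdivide by SE content: none,
    only non-edge SEs, or at least one edge SE (edge dominates). Regions
    spanning a TAD boundary count as edge SEs for every TAD they overlap
    when `spanning_counts_as_edge` (their boundary distance is below any
    threshold by construction).
    """
    if isinstance(compartments, CompartmentCall):
        compartments = {compartments.chrom: compartments}

    hosted: dict[int, list[str]] = {i: [] for i in range(len(tads))}
    tad_index = IntervalIndex(tads)
    for pl in placements:
        if pl.host_tad is not None:
            for j in tad_index.overlapping(pl.region):
                if tad_index.intervals[j] == pl.host_tad:
                    hosted[j].append(pl.position_class)
        elif pl.position_class == "spanning_boundary" and spanning_counts_as_edge:
            for j in tad_index.overlapping(pl.region):
                hosted[j].append("edge")

    out = []
    for i, tad in enumerate(tads):
        label = _uniform_compartment_label(tad, compartments.get(tad.chrom))
        if label == "B":
            group = "B_compartment"
        elif label == "A":
            classes = hosted[i]
            if not classes:
                group = "A_no_SE"
            elif "edge" in classes:
                group = "A_edge_SE"
            else:
                group = "A_nonedge_SE"
        else:
            group = "unassigned"
        out.append(TADClass(tad, group))
    return out


def _uniform_compartment_label(tad: GenomicInterval, call: CompartmentCall | None) -> str:
    """Label covering every bp of the TAD, or '' if mixed/uncovered."""
    if call is None:
        return ""
    covered_to = tad.start
    label = None
    for seg, seg_label, _ in call.segments:
        if seg.end <= covered_to or seg.start >= tad.end:
            continue
        if seg.start > covered_to:
            return ""  # gap
        if label is None:
            label = seg_label
        elif seg_label != label:
            return ""
        covered_to = seg.end
        if covered_to >= tad.end:
            return label
    return label if covered_to >= tad.end and label is not None else ""


def tad_loop_stats(tads: list[GenomicInterval], loops: list[Loop]) -> list[TADLoopStats]:
    """Per-TAD loop contact statistics.

    A loop is in contact with a TAD when at least one foot overlaps it, and
    crosses its boundary when exactly one foot overlaps. A loop touching
    two TADs is counted once per TAD.
    """
    feetA = IntervalIndex([lp.footA for lp in loops])
    out = []
    for tad in tads:
        sizes, n_contact, n_cross = [], 0, 0
        for lp in loops:
            ina = lp.footA.overlaps(tad)
            inb = lp.footB.overlaps(tad)
            if ina or inb:
                n_contact += 1
                sizes.append(lp.size)
                if ina != inb:
                    n_cross += 1
        out.append(TADLoopStats(
            tad,
            n_contact,
            float(np.mean(sizes)) if sizes else float("nan"),
            100.0 * n_cross / n_contact if n_contact else float("nan"),
        ))
    return out


def region_loop_summary(
    regions: list[GenomicInterval], loops: list[Loop]
) -> SEContactSummary:
    """Per-region touching/internal loop counts and touching-loop sizes."""
    index = IntervalIndex(regions)
    touching = [0] * len(regions)
    internal = [0] * len(regions)
    sizes = []
    for lp in loops:
        ja = set(index.overlapping(lp.footA))
        jb = set(index.overlapping(lp.footB))
        if ja or jb:
            sizes.append(lp.size)
        for j in ja | jb:
            touching[j] += 1
        for j in ja & jb:
            r = regions[j]
            if r.contains(lp.footA) and r.contains(lp.footB):
                internal[j] += 1
    return SEContactSummary(touching, internal, sizes)


def region_contact_features(
    regions: list[GenomicInterval],
    loops: list[Loop],
    cres: list[GenomicInterval],
    genes: list[GeneRecord],
) -> SEContactSummary:
    """Unique features contacted by regions through loops.

    For every loop with exactly one foot overlapping a region, the distal
    foot is intersected with CREs, TSS points, and the other regions;
    counts are of unique features over the whole region set.
    """
    summary = region_loop_summary(regions, loops)
    region_index = IntervalIndex(regions)
    cre_index = IntervalIndex(cres)
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(genes):
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, gi))
    for v in tss_by_chrom.values():
        v.sort()

    seen_cres: set[int] = set()
    seen_tss: set[int] = set()
    seen_regions: set[int] = set()
    for lp in loops:
        ja = set(region_index.overlapping(lp.footA))
        jb = set(region_index.overlapping(lp.footB))
        for near, far, jn, jf in ((lp.footA, lp.footB, ja, jb), (lp.footB, lp.footA, jb, ja)):
            # only loops leaving the region count: the near foot must touch a
            # region the far foot does not
            if not (jn - jf):
                continue
            seen_cres.update(cre_index.overlapping(far))
            seen_regions.update(jf - jn)
            pts = tss_by_chrom.get(far.chrom, [])
            lo = bisect_left(pts, (far.start, -1))
            hi = bisect_right(pts, (far.end - 1, len(genes)))
            seen_tss.update(gi for _, gi in pts[lo:hi])
    summary.unique_cres = len(seen_cres)
    summary.unique_tss = len(seen_tss)
    summary.unique_regions = len(seen_regions)
    return summary


def crossing_fraction(
    regions: list[GenomicInterval],
    loops: list[Loop],
    tads: list[GenomicInterval],
) -> float:
    """% of region-touching loops whose feet do not share a TAD.

    A loop crosses when no single TAD overlaps both feet and at least one
    foot overlaps some TAD; loops entirely outside the TAD layout are
    counted as non-crossing. Returns NaN (flagged) with no touching loops.
    """
    region_index = IntervalIndex(regions)
    tad_index = IntervalIndex(tads)
    n_touch, n_cross = 0, 0
    for lp in loops:
        if not (region_index.any_overlap(lp.footA) or region_index.any_overlap(lp.footB)):
            continue
        n_touch += 1
        ta = set(tad_index.overlapping(lp.footA))
        tb = set(tad_index.overlapping(lp.footB))
        if not (ta & tb) and (ta or tb):
            n_cross += 1
    return 100.0 * n_cross / n_touch if n_touch else float("nan")


def _genes_with_tss_in(genes: list[GeneRecord], regions: list[GenomicInterval]) -> list[GeneRecord]:
    index = IntervalIndex(regions)
    out = []
    for g in genes:
        probe = GenomicInterval(g.chrom, g.tss, g.tss + 1)
        if index.any_overlap(probe):
            out.append(g)
    return out


def mean_expression_in_regions(
    genes: list[GeneRecord],
    regions: list[GenomicInterval],
    comparison_regions: list[GenomicInterval] | None = None,
) -> dict:
    """Mean expression of genes with a TSS inside the region set.

    Each gene counts once however many regions cover its TSS. With a
    comparison set the fold-change mean(regions)/mean(comparison) is
    reported; an empty gene class leaves the fold undefined (None).
    """
    in_regions = [g for g in _genes_with_tss_in(genes, regions) if g.expression is not None]
    mean_a = float(np.mean([g.expression for g in in_regions])) if in_regions else None
    out = {"mean": mean_a, "n_genes": len(in_regions), "fold": None, "flagged": mean_a is None}
    if comparison_regions is not None:
        in_b = [g for g in _genes_with_tss_in(genes, comparison_regions) if g.expression is not None]
        mean_b = float(np.mean([g.expression for g in in_b])) if in_b else None
        out["comparison_mean"] = mean_b
        if mean_a is not None and mean_b:
            out["fold"] = mean_a / mean_b
        else:
            out["flagged"] = True
    return out


def geneset_tss_overlap_fraction(
    geneset: list[GeneRecord], regions: list[GenomicInterval]
) -> float:
    """% of genes in the set with >=1 TSS inside a region."""
    if not geneset:
        raise ValueError("empty gene set")
    hit = _genes_with_tss_in(geneset, regions)
    return 100.0 * len(hit) / len(geneset)


def _shared_tad_pairs(genes: list[GeneRecord], tads: list[GenomicInterval]) -> set[frozenset[str]]:
    index = IntervalIndex(tads)
    per_tad: dict[int, list[str]] = {}
    for g in genes:
        probe = GenomicInterval(g.chrom, g.tss, g.tss + 1)
        for j in index.overlapping(probe):
            per_tad.setdefault(j, []).append(g.gene_id)
    pairs: set[frozenset[str]] = set()
    for ids in per_tad.values():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ids[i] != ids[j]:
                    pairs.add(frozenset((ids[i], ids[j])))
    return pairs


def _loop_connected_pairs(genes: list[GeneRecord], loops: list[Loop]) -> set[frozenset[str]]:
    bodies = IntervalIndex([g.body for g in genes])
    pairs: set[frozenset[str]] = set()
    for lp in loops:
        ga = {genes[j].gene_id for j in bodies.overlapping(lp.footA)}
        gb = {genes[j].gene_id for j in bodies.overlapping(lp.footB)}
        for a in ga:
            for b in gb:
                if a != b:
                    pairs.add(frozenset((a, b)))
    return pairs


def gene_pair_conservation(
    tads_a: list[GenomicInterval],
    loops_a: list[Loop],
    genes_a: list[GeneRecord],
    tads_b: list[GenomicInterval],
    loops_b: list[Loop],
    genes_b: list[GeneRecord],
    ortholog_map: dict[str, str],
) -> ConservationSummary:
    """Conservation of gene-pair topology from species B into species A.

    `ortholog_map` maps species-B gene ids one-to-one onto species-A ids.
    A species-B pair shares a TAD when both TSS fall in the same TAD; it is
    loop-connected when some loop joins the two gene bodies. The reported
    fractions are the share of species-B pairs whose mapped species-A pair
    satisfies the same predicate.
    """
    if len(set(ortholog_map.values())) != len(ortholog_map):
        raise ValueError("ortholog map is not one-to-one")
    tad_b = _shared_tad_pairs(genes_b, tads_b)
    tad_a = _shared_tad_pairs(genes_a, tads_a)
    loop_b = _loop_connected_pairs(genes_b, loops_b)
    loop_a = _loop_connected_pairs(genes_a, loops_a)

    def _map(pair: frozenset[str]) -> frozenset[str] | None:
        mapped = [ortholog_map.get(g) for g in pair]
        return frozenset(mapped) if all(mapped) else None

    def _conserved(pairs_b: set, pairs_a: set) -> tuple[int, float]:
        mapped = [(_map(p)) for p in pairs_b]
        n = len(mapped)
        hit = sum(1 for m in mapped if m is not None and m in pairs_a)
        return n, (hit / n if n else float("nan"))

    n_tad, f_tad = _conserved(tad_b, tad_a)
    n_loop, f_loop = _conserved(loop_b, loop_a)
    return ConservationSummary(n_tad, f_tad, n_loop, f_loop)
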