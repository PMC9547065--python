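"""Topological classification of eQTL variant-eGene pairs.

Each record is classified on five axes: position relative to the eGene TSS
(promoter within +/-2.5 kb, else distal), A/B compartment of the variant,
TAD co-residence with the eGene TSS (compared against random-TAD nulls),
the promoter-interaction loop taxonomy (eGene pieQTL / non-eGene pieQTL /
eQTL-only / not on a loop), and regulatory-element context (SE takes
precedence over CRE) with local H3K27Ac coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomeBuild,
    GenomicInterval,
    GeneRecord,
    IntervalIndex,
    Loop,
    SignalTrack,
    coverage_in_window,
    promoter_window,
)
from .matrix import CompartmentCall
from .nulls import EnrichmentResult, RandomRegionSet, enrichment_t

__all__ = [
    "EQTLAnnotation",
    "classify_position",
    "compartment_of_variants",
    "same_tad_analysis",
    "pieqtl_classify",
    "regulatory_overlap",
    "h3k27ac_context",
    "annotate_eqtls",
]

LOOP_CLASS_ORDER = ["not_on_loop", "eqtl_only", "non_egene_pieqtl", "egene_pieqtl"]


@dataclass
class EQTLAnnotation:
    variant_id: str
    egene_id: str
    position_class: str      # promoter / distal
    trans: bool
    compartment: str         # A / B / none
    same_tad: bool
    loop_class: str
    regulatory_class: str    # none / CRE / SE
    region_overlaps_egene: bool
    h3k27ac: float | None = None


def _point(chrom: str, pos: int) -> GenomicInterval:
    return GenomicInterval(chrom, pos, pos + 1)


def _gene_lookup(genes: list[GeneRecord]) -> dict[str, GeneRecord]:
    return {g.gene_id: g for g in genes}


def classify_position(
    eqtls: pd.DataFrame,
    genes: list[GeneRecord],
    promoter_halfwidth: int = 2500,
) -> pd.Series:
    """promoter iff |variant - eGene TSS| <= halfwidth on the same
    chromosome (boundary inclusive); else distal. Trans pairs are distal.
    """
    lookup = _gene_lookup(genes)
    out = []
    for row in eqtls.itertuples():
        gene = lookup[row.egene_id]
        if row.chrom != gene.chrom:
            out.append("distal")
        else:
            out.append("promoter" if abs(row.pos - gene.tss) <= promoter_halfwidth else "distal")
    return pd.Series(out, index=eqtls.index, name="position_class")


def compartment_of_variants(
    eqtls: pd.DataFrame,
    compartments: CompartmentCall | dict[str, CompartmentCall],
) -> tuple[pd.Series, dict[str, float]]:
    """Compartment label per pair and A/B/none proportions over pairs."""
    if isinstance(compartments, CompartmentCall):
        compartments = {compartments.chrom: compartments}
    labels = []
    for row in eqtls.itertuples():
        call = compartments.get(row.chrom)
        lab = call.label_at(row.chrom, row.pos) if call is not None else ""
        labels.append(lab if lab else "none")
    s = pd.Series(labels, index=eqtls.index, name="compartment")
    n = len(s)
    props = {k: float((s == k).sum()) / n if n else float("nan") for k in ("A", "B", "none")}
    return s, props


def same_tad_analysis(
    eqtls: pd.DataFrame,
    genes: list[GeneRecord],
    tads: list[GenomicInterval],
    random_tad_sets: list[RandomRegionSet] | None = None,
) -> tuple[pd.Series, EnrichmentResult | None]:
    """Per-pair flag: one TAD contains both the variant and the eGene TSS.

    With random-TAD sets the observed same-TAD proportion is compared to
    the 100 per-set proportions via the enrichment t-test. Trans pairs are
    excluded from proportions (never same-TAD).
    """
    lookup = _gene_lookup(genes)

    def _proportion(tad_list: list[GenomicInterval]) -> tuple[pd.Series, float]:
        index = IntervalIndex(tad_list)
        flags, n_cis, n_same = [], 0, 0
        for row in eqtls.itertuples():
            gene = lookup[row.egene_id]
            if row.chrom != gene.chrom:
                flags.append(False)
                continue
            n_cis += 1
            hit = any(
                index.intervals[j].contains_point(gene.tss)
                for j in index.overlapping(_point(row.chrom, row.pos))
            )
            flags.append(hit)
            n_same += hit
        prop = n_same / n_cis if n_cis else float("nan")
        return pd.Series(flags, index=eqtls.index, name="same_tad"), prop

    flags, observed = _proportion(tads)
    result = None
    if random_tad_sets is not None:
        randoms = [_proportion(rs.intervals)[1] for rs in random_tad_sets]
        result = enrichment_t(observed, randoms, name="same_tad_proportion")
    return flags, result


def pieqtl_classify(
    eqtls: pd.DataFrame,
    loops: list[Loop],
    genes: list[GeneRecord],
    promoter_halfwidth: int = 2500,
    build: GenomeBuild | None = None,
) -> pd.Series:
    """Promoter-interaction taxonomy per variant-eGene pair.

    All loops with a foot covering the variant are collected; each opposite
    foot is tested against the promoter windows (TSS +/- halfwidth) of all
    genes. The record takes the best-supported class across loops:
    egene_pieqtl > non_egene_pieqtl > eqtl_only > not_on_loop.
    """
    promoters = IntervalIndex([promoter_window(g, promoter_halfwidth, build) for g in genes])
    gene_ids = [g.gene_id for g in genes]
    feet = IntervalIndex(
        [lp.footA for lp in loops] + [lp.footB for lp in loops]
    )
    n_loops = len(loops)
    out = []
    for row in eqtls.itertuples():
        probe = _point(row.chrom, row.pos)
        foot_hits = feet.overlapping(probe)
        if not foot_hits:
            out.append("not_on_loop")
            continue
        best = "eqtl_only"
        for fh in foot_hits:
            lp = loops[fh % n_loops]
            opposite = lp.footB if fh < n_loops else lp.footA
            for j in promoters.overlapping(opposite):
                if gene_ids[j] == row.egene_id:
                    best = "egene_pieqtl"
                    break
                best = max(best, "non_egene_pieqtl", key=LOOP_CLASS_ORDER.index)
            if best == "egene_pieqtl":
                break
        out.append(best)
    return pd.Series(out, index=eqtls.index, name="loop_class")


def regulatory_overlap(
    eqtls: pd.DataFrame,
    cres: list[GenomicInterval],
    ses: list[GenomicInterval],
    genes: list[GeneRecord],
) -> pd.DataFrame:
    """Variant-in-SE (precedence) / variant-in-CRE / none, and whether the
    containing region overlaps the eGene body."""
    lookup = _gene_lookup(genes)
    cre_index = IntervalIndex(cres)
    se_index = IntervalIndex(ses)
    classes, overlaps_egene = [], []
    for row in eqtls.itertuples():
        probe = _point(row.chrom, row.pos)
        region = None
        hits = se_index.overlapping(probe)
        if hits:
            classes.append("SE")
            region = se_index.intervals[hits[0]]
        else:
            hits = cre_index.overlapping(probe)
            if hits:
                classes.append("CRE")
                region = cre_index.intervals[hits[0]]
            else:
                classes.append("none")
        if region is None:
            overlaps_egene.append(False)
        else:
            overlaps_egene.append(region.overlaps(lookup[row.egene_id].body))
    return pd.DataFrame(
        {"regulatory_class": classes, "region_overlaps_egene": overlaps_egene},
        index=eqtls.index,
    )


def h3k27ac_context(
    eqtls: pd.DataFrame,
    track: SignalTrack,
    position_class: pd.Series,
    halfwidth: int = 100,
) -> tuple[pd.Series, dict]:
    """Local H3K27Ac coverage (+/- halfwidth bp, inclusive) per variant and
    a Welch two-sample t between distal and promoter classes.

    The t statistic is computed with the distal group first, so it is
    negative when promoter variants carry more signal. Satterthwaite
    degrees of freedom are reported.
    """
    cov = pd.Series(
        [coverage_in_window(track, row.chrom, int(row.pos), halfwidth) for row in eqtls.itertuples()],
        index=eqtls.index,
        name="h3k27ac",
    )
    distal = cov[position_class == "distal"].to_numpy()
    promoter = cov[position_class == "promoter"].to_numpy()
    test: dict = {"t": None, "df": None, "p": None, "skipped": False}
    if len(distal) < 2 or len(promoter) < 2 or (np.var(distal) == 0 and np.var(promoter) == 0):
        test["skipped"] = True
    else:
        res = stats.ttest_ind(distal, promoter, equal_var=False)
        test.update(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
    return cov, test


def annotate_eqtls(
    eqtls: pd.DataFrame,
    genes: list[GeneRecord],
    tads: list[GenomicInterval],
    loops: list[Loop],
    cres: list[GenomicInterval],
    ses: list[GenomicInterval],
    compartments: CompartmentCall | dict[str, CompartmentCall] | None = None,
    track: SignalTrack | None = None,
    random_tad_sets: list[RandomRegionSet] | None = None,
    promoter_halfwidth: int = 2500,
    build: GenomeBuild | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full per-pair annotation and return (table, summary)."""
    out = eqtls.copy()
    out["position_class"] = classify_position(out, genes, promoter_halfwidth)
    lookup = _gene_lookup(genes)
    out["trans"] = [row.chrom != lookup[row.egene_id].chrom for row in out.itertuples()]
    summary: dict = {}
    if compartments is not None:
        out["compartment"], summary["compartment_proportions"] = compartment_of_variants(out, compartments)
    out["same_tad"], tad_enrichment = same_tad_analysis(out, genes, tads, random_tad_sets)
    if tad_enrichment is not None:
        summary["same_tad_enrichment"] = tad_enrichment
    out["loop_class"] = pieqtl_classify(out, loops, genes, promoter_halfwidth, build)
    out = pd.concat([out, regulatory_overlap(out, cres, ses, genes)], axis=1)
    if track is not None:
        out["h3k27ac"], summary["h3k27ac_welch"] = h3k27ac_context(
            out, track, out["position_class"]
        )
    summary["loop_class_counts"] = out["loop_class"].value_counts().to_dict()
    summary["position_class_counts"] = out["position_class"].value_counts().to_dict()
    summary["regulatory_class_counts"] = out["regulatory_class"].value_counts().to_dict()
    return out, summary
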