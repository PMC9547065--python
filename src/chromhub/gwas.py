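"""GWAS lead/LD variant filtering and target-gene assignment.

LD variants are filtered on minor allele frequency and r-squared with
their lead (both bounds inclusive). Candidate target genes come from three
mechanisms: a chromatin loop with one foot on the variant and the other on
a gene body or TSS; co-residence of variant and gene body/TSS in the same
CRE or SE; and the nearest gene as a fallback annotation. Summaries
deduplicate variants per category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import (
    GenomicInterval,
    GeneRecord,
    IntervalIndex,
    Loop,
    closest_feature,
)

__all__ = [
    "TargetGeneLink",
    "filter_ld",
    "loop_targets",
    "regulatory_targets",
    "closest_targets",
    "locus_summary",
    "verify_links",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("loop_to_body", "loop_to_tss", "cre_shared", "se_shared", "closest")


@dataclass(frozen=True)
class TargetGeneLink:
    rsid: str
    variant_class: str  # lead / filtered_LD
    gene_id: str
    mechanism: str
    evidence: str  # loop/region identifier or distance for `closest`

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def filter_ld(
    ld: pd.DataFrame,
    maf_min: float = 0.01,
    r2_min: float = 0.7,
    on_missing: str = "drop",
) -> pd.DataFrame:
    """Keep LD variants with MAF >= maf_min and r2 >= r2_min (inclusive).

    Rows with missing MAF or r2 are dropped with a warning (or raise with
    ``on_missing='error'``). Input order is preserved.
    """
    missing = ld["maf"].isna() | ld["r2"].isna()
    if missing.any():
        if on_missing == "error":
            raise ValueError(f"{int(missing.sum())} LD records missing MAF or r2")
        logger.warning("dropping %d LD records missing MAF or r2", int(missing.sum()))
        ld = ld[~missing]
    return ld[(ld["maf"] >= maf_min) & (ld["r2"] >= r2_min)].copy()


def _variant_rows(variants: pd.DataFrame) -> list[tuple[str, str, str, int]]:
    """(rsid, variant_class, chrom, pos) per row; class from the table shape."""
    cls = "filtered_LD" if "lead_rsid" in variants.columns else "lead"
    return [(str(r.rsid), cls, str(r.chrom), int(r.pos)) for r in variants.itertuples()]


def loop_targets(
    variants: pd.DataFrame, loops: list[Loop], genes: list[GeneRecord]
) -> list[TargetGeneLink]:
    """Links through loops: variant on one foot, gene body or TSS on the other.

    One link per (variant, gene, mechanism, loop); a gene reachable through
    several loops yields several links and is deduplicated in summaries.
    """
    bodies = IntervalIndex([g.body for g in genes])
    feet = IntervalIndex([lp.footA for lp in loops] + [lp.footB for lp in loops])
    n_loops = len(loops)
    tss_index = IntervalIndex(
        [GenomicInterval(g.chrom, g.tss, g.tss + 1) for g in genes]
    )
    links = []
    for rsid, vclass, chrom, pos in _variant_rows(variants):
        probe = GenomicInterval(chrom, pos, pos + 1)
        for fh in feet.overlapping(probe):
            lp = loops[fh % n_loops]
            opposite = lp.footB if fh < n_loops else lp.footA
            loop_id = f"loop_{fh % n_loops}"
            for j in bodies.overlapping(opposite):
                links.append(TargetGeneLink(rsid, vclass, genes[j].gene_id, "loop_to_body", loop_id))
            for j in tss_index.overlapping(opposite):
                links.append(TargetGeneLink(rsid, vclass, genes[j].gene_id, "loop_to_tss", loop_id))
    return links


def regulatory_targets(
    variants: pd.DataFrame,
    cres: list[GenomicInterval],
    ses: list[GenomicInterval],
    genes: list[GeneRecord],
) -> list[TargetGeneLink]:
    """Links through shared regulatory regions: the variant and the gene
    body (or TSS) overlap the same CRE / SE."""
    links = []
    for regions, mechanism in ((cres, "cre_shared"), (ses, "se_shared")):
        index = IntervalIndex(regions)
        for rsid, vclass, chrom, pos in _variant_rows(variants):
            probe = GenomicInterval(chrom, pos, pos + 1)
            for j in index.overlapping(probe):
                region = index.intervals[j]
                region_id = f"{mechanism.split('_')[0]}_{j}"
                for g in genes:
                    if g.chrom != region.chrom:
                        continue
                    if region.overlaps(g.body) or region.contains_point(g.tss):
                        links.append(TargetGeneLink(rsid, vclass, g.gene_id, mechanism, region_id))
    return links


def closest_targets(
    variants: pd.DataFrame, genes: list[GeneRecord]
) -> list[TargetGeneLink]:
    """Nearest gene body per variant (ties to the smaller start)."""
    bodies = IntervalIndex([g.body for g in genes])
    by_body = {id(iv): g for iv, g in zip(bodies.intervals, genes)}
    links = []
    for rsid, vclass, chrom, pos in _variant_rows(variants):
        hit = closest_feature(GenomicInterval(chrom, pos, pos + 1), bodies)
        if hit is None:
            continue
        iv, dist = hit
        links.append(TargetGeneLink(rsid, vclass, by_body[id(iv)].gene_id, "closest", f"d={dist}"))
    return links


def locus_summary(
    links: list[TargetGeneLink],
    leads: pd.DataFrame,
    ld: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-disease deduplicated variant counts by evidence category.

    A variant counts once per category regardless of how many links
    support it. Categories: on a loop foot with a gene contact
    (loop_contact), in a CRE (cre), in an SE (se), any of the above
    (linked).
    """
    disease_of: dict[str, str] = {str(r.rsid): str(r.disease) for r in leads.itertuples()}
    if ld is not None:
        lead_disease = dict(disease_of)
        for r in ld.itertuples():
            disease_of[str(r.rsid)] = lead_disease.get(str(r.lead_rsid), "other")

    cat_of_mech = {
        "loop_to_body": "loop_contact",
        "loop_to_tss": "loop_contact",
        "cre_shared": "cre",
        "se_shared": "se",
    }
    rows: dict[tuple[str, str, str], set[str]] = {}
    for link in links:
        cat = cat_of_mech.get(link.mechanism)
        if cat is None:
            continue
        disease = disease_of.get(link.rsid, "other")
        for c in (cat, "linked"):
            rows.setdefault((disease, link.variant_class, c), set()).add(link.rsid)
    records = [
        {"disease": d, "variant_class": vc, "category": cat, "n_variants": len(rsids)}
        for (d, vc, cat), rsids in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["disease", "variant_class", "category", "n_variants"])


def verify_links(
    links: list[TargetGeneLink],
    variants: pd.DataFrame,
    loops: list[Loop],
    cres: list[GenomicInterval],
    ses: list[GenomicInterval],
    genes: list[GeneRecord],
) -> bool:
    """Re-check every link's cited evidence against its mechanism predicate."""
    pos_of = {str(r.rsid): (str(r.chrom), int(r.pos)) for r in variants.itertuples()}
    gene_of = {g.gene_id: g for g in genes}
    regions = {"cre": cres, "se": ses}
    for link in links:
        chrom, pos = pos_of[link.rsid]
        probe = GenomicInterval(chrom, pos, pos + 1)
        gene = gene_of[link.gene_id]
        if link.mechanism.startswith("loop_to"):
            lp = loops[int(link.evidence.split("_")[1])]
            on_a = lp.footA.overlaps(probe)
            on_b = lp.footB.overlaps(probe)
            if not (on_a or on_b):
                return False
            target_ok = False
            for on_near, far in ((on_a, lp.footB), (on_b, lp.footA)):
                if not on_near:
                    continue
                if link.mechanism == "loop_to_body" and far.overlaps(gene.body):
                    target_ok = True
                if link.mechanism == "loop_to_tss" and far.chrom == gene.chrom and far.contains_point(gene.tss):
                    target_ok = True
            if not target_ok:
                return False
        elif link.mechanism in ("cre_shared", "se_shared"):
            kind, idx = link.evidence.split("_")
            region = regions[kind][int(idx)]
            if not region.overlaps(probe):
                return False
            if not (region.overlaps(gene.body) or (region.chrom == gene.chrom and region.contains_point(gene.tss))):
                return False
    return True
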