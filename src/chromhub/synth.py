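"""Synthetic genome generator with planted, machine-verifiable truth.

Emulates the derived products of a tissue Hi-C / chromatin study on a toy
genome (default 2 x 10 Mb): a binned contact matrix with power-law distance
decay, planted TADs, compartment blocks and loop anchors; an H3K27Ac
case/control track pair with clustered high-signal enhancer constituents
forming super-enhancers; a chromatin-state segmentation consistent with the
signal; genes with log-normal expression boosted near SEs; eQTLs planted in
every topological class; and GWAS lead variants with LD blocks, a fraction
of which sit on loop feet opposite gene bodies.

Layout discipline: each TAD is divided into 40 kb slots and every planted
element (gene, SE cluster, typical enhancer, variant anchor) occupies its
own slot, guaranteeing >12.5 kb spacing between distinct elements so the
stitching stage cannot chain unrelated elements, and >2.5 kb between
variants and unintended TSSs. Loop feet and variant positions are booked in
a per-bin registry so no planted class is contaminated by another element's
loop. After assembly the generator re-derives every planted label with the
package's own predicates and refuses to emit an inconsistent bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as chio
from .core import GenomeBuild, GenomicInterval, GeneRecord, Loop, SignalTrack
from .matrix import ContactMatrix
from .se import ChromatinStateSegment

__all__ = [
    "SyntheticConfig",
    "TruthSet",
    "SimulationResult",
    "simulate",
    "null_variant_shuffle",
    "conserved_genome_pair",
]

SLOT = 40_000


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle (defaults are the
    conditions every recovery test runs under)."""

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    bin_size: int = 5000
    # topology
    tad_length_range: tuple = (500_000, 1_100_000)   # mean 800 kb
    compartment_block_tads: tuple = (2, 3)           # TADs per A/B block
    # contact matrix
    distance_decay: float = 1.0
    base_contacts: float = 100.0
    tad_factor: float = 3.0
    compartment_factor: float = 1.5
    loop_strength: float = 4.0
    noise: str = "poisson"                           # poisson / none
    # H3K27Ac signal
    signal_bin: int = 100
    lambda_background: float = 1.0
    lambda_se: float = 20.0
    lambda_typical: float = 4.0
    lambda_promoter: float = 6.0
    # regulatory landscape
    n_se: int = 16
    se_edge_fraction: float = 0.5
    n_typical: int = 30
    # genes / expression
    genes_per_tad: int = 3
    gene_length_range: tuple = (5000, 20_000)
    expression_log_mean: float = math.log(10.0)
    expression_log_sd: float = 0.25
    se_boost: float = 2.0
    # eQTLs
    eqtl_per_class: int = 25
    same_tad_fraction: float = 0.7
    compartment_a_fraction: float = 0.8
    # GWAS
    diseases: tuple = ("AMD", "glaucoma")
    leads_per_disease: int = 4
    ld_per_lead: int = 30
    ld_pass_fraction: float = 0.6
    linked_locus_fraction: float = 0.5
    # extra structure
    n_background_loops: int = 20
    make_matrix: bool = True   # skip contact matrices for signal-only runs
    seed: int = 1


@dataclass
class TruthSet:
    """Planted labels for every entity the pipeline should recover."""

    tads: list = field(default_factory=list)            # (chrom, start, end)
    compartments: list = field(default_factory=list)    # (chrom, start, end, label)
    ses: list = field(default_factory=list)             # dicts: interval, position_class, target_gene
    typical: list = field(default_factory=list)
    loops: list = field(default_factory=list)           # (chrom, binA, binB, role)
    boosted_genes: list = field(default_factory=list)
    gwas_links: list = field(default_factory=list)      # (rsid, gene_id, loop_index)
    control_leads: list = field(default_factory=list)
    tad_groups: dict = field(default_factory=dict)      # "chrom:start-end" -> group

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class SimulationResult:
    config: SyntheticConfig
    build: GenomeBuild
    tads: list
    compartment_segments: list      # (GenomicInterval, label)
    segments: list                  # ChromatinStateSegment
    case_track: SignalTrack
    control_track: SignalTrack
    genes: list
    loops: list
    matrices: dict                  # chrom -> ContactMatrix
    eqtls: pd.DataFrame             # includes truth_* columns
    leads: pd.DataFrame
    ld: pd.DataFrame
    truth: TruthSet


class _Layout:
    """Slot bookkeeping for one genome."""

    def __init__(self, build: GenomeBuild, tads: list, rng: np.random.Generator):
        self.build = build
        self.tads = tads
        self.rng = rng
        self.slots: dict[int, list[int]] = {}   # tad index -> free slot starts
        self.edge_free: dict[int, bool] = {}
        for ti, tad in enumerate(tads):
            starts = []
            s = tad.start + SLOT
            while s + SLOT <= tad.end - 10_000:
                starts.append(s)
                s += SLOT
            starts = [starts[i] for i in rng.permutation(len(starts))]
            self.slots[ti] = starts
            self.edge_free[ti] = True
        self.used_bins: set[tuple[str, int]] = set()

    def pop_slot(self, tad_index: int) -> int:
        if not self.slots[tad_index]:
            raise GenerationError(
                f"TAD {tad_index} ran out of 40 kb slots; enlarge the genome "
                "or reduce planted element counts"
            )
        return self.slots[tad_index].pop()

    def pop_slot_any(self, tad_indices: list[int]) -> tuple[int, int]:
        order = [tad_indices[i] for i in self.rng.permutation(len(tad_indices))]
        for ti in order:
            if self.slots[ti]:
                return ti, self.slots[ti].pop()
        raise GenerationError("no free slots left in the requested TAD set")

    def pop_slot_pair(self, tad_indices: list[int]) -> tuple[int, int, int]:
        """Two slots in one TAD (for intra-TAD loop anchors)."""
        order = [tad_indices[i] for i in self.rng.permutation(len(tad_indices))]
        for ti in order:
            if len(self.slots[ti]) >= 2:
                return ti, self.slots[ti].pop(), self.slots[ti].pop()
        raise GenerationError("no TAD with two free slots left")

    def book_bin(self, chrom: str, pos: int, bin_size: int) -> int:
        b = pos // bin_size
        key = (chrom, b)
        if key in self.used_bins:
            raise GenerationError(f"bin collision at {chrom}:{b * bin_size}")
        self.used_bins.add(key)
        return b

    def bin_free(self, chrom: str, pos: int, bin_size: int) -> bool:
        return (chrom, pos // bin_size) not in self.used_bins


def _plant_tads(build: GenomeBuild, cfg: SyntheticConfig, rng) -> list:
    tads = []
    lo, hi = cfg.tad_length_range
    bs = cfg.bin_size
    for chrom, size in build.items():
        pos = 0
        while pos < size:
            length = int(rng.integers(lo // bs, hi // bs + 1)) * bs
            end = min(pos + length, size)
            if size - end < lo:       # absorb the remainder into the last TAD
                end = size
            tads.append(GenomicInterval(chrom, pos, end))
            pos = end
    return tads


def _plant_compartments(tads: list, cfg: SyntheticConfig, rng) -> list:
    """Group consecutive TADs into alternating A/B blocks tiling each chrom."""
    blocks = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    lo, hi = cfg.compartment_block_tads
    for chrom, ts in by_chrom.items():
        label = "A"
        i = 0
        while i < len(ts):
            k = int(rng.integers(lo, hi + 1))
            group = ts[i : i + k]
            blocks.append((GenomicInterval(chrom, group[0].start, group[-1].end), label))
            label = "B" if label == "A" else "A"
            i += k
    return blocks


def _tad_labels(tads: list, blocks: list) -> list[str]:
    labels = []
    for t in tads:
        lab = ""
        for seg, seg_label in blocks:
            if seg.chrom == t.chrom and seg.start <= t.start and t.end <= seg.end:
                lab = seg_label
                break
        labels.append(lab)
    return labels


def simulate(config: SyntheticConfig | None = None, out_dir=None) -> SimulationResult:
    """Generate the full bundle; optionally write it to `out_dir`.

    Deterministic under ``config.seed``: independent child seeds drive the
    layout, signal, matrix, expression, eQTL and GWAS components.
    """
    cfg = config or SyntheticConfig()
    ss = np.random.SeedSequence(cfg.seed)
    (rng_layout, rng_signal, rng_matrix, rng_expr, rng_eqtl, rng_gwas) = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    build = GenomeBuild(cfg.chrom_sizes)
    truth = TruthSet()

    tads = _plant_tads(build, cfg, rng_layout)
    blocks = _plant_compartments(tads, cfg, rng_layout)
    tad_comp = _tad_labels(tads, blocks)
    truth.tads = [(t.chrom, t.start, t.end) for t in tads]
    truth.compartments = [(s.chrom, s.start, s.end, lab) for s, lab in blocks]

    layout = _Layout(build, tads, rng_layout)
    a_tads = [i for i, lab in enumerate(tad_comp) if lab == "A"]
    b_tads = [i for i, lab in enumerate(tad_comp) if lab == "B"]
    if len(a_tads) < 2 or len(b_tads) < 1:
        raise GenerationError("degenerate compartment layout; reseed or resize")

    # ----- genes ----------------------------------------------------------
    genes: list[GeneRecord] = []
    genes_by_tad: dict[int, list[int]] = {i: [] for i in range(len(tads))}
    glo, ghi = cfg.gene_length_range
    for ti, tad in enumerate(tads):
        for _ in range(cfg.genes_per_tad):
            if not layout.slots[ti]:
                break
            s = layout.pop_slot(ti)
            length = int(rng_layout.integers(glo, ghi + 1))
            strand = "+" if rng_layout.random() < 0.5 else "-"
            body = GenomicInterval(tad.chrom, s + 8000, s + 8000 + length)
            g = GeneRecord(f"G{len(genes):04d}", f"G{len(genes):04d}", strand, body)
            genes_by_tad[ti].append(len(genes))
            genes.append(g)
            layout.book_bin(g.chrom, g.tss, cfg.bin_size)

    # ----- super-enhancers and typical enhancers --------------------------
    segments: list[ChromatinStateSegment] = []
    ses: list[dict] = []
    n_edge = round(cfg.n_se * cfg.se_edge_fraction)
    se_host = [a_tads[i % len(a_tads)] for i in range(cfg.n_se)]
    for si in range(cfg.n_se):
        ti = se_host[si]
        tad = tads[ti]
        if si < n_edge and layout.edge_free[ti]:
            start = tad.start + 2000
            layout.edge_free[ti] = False
            planted_class = "edge"
        else:
            ti, s = layout.pop_slot_any(a_tads)
            tad = tads[ti]
            start = s + 4000
            planted_class = "non_edge"
        consts = []
        pos = start
        n_c = int(rng_layout.integers(3, 5))
        for ci in range(n_c):
            width = int(rng_layout.integers(1500, 2501))
            consts.append(GenomicInterval(tad.chrom, pos, pos + width))
            pos += width + int(rng_layout.integers(3000, 6001))
        for c in consts:
            segments.append(ChromatinStateSegment(c, "enhancer_1"))
        # target gene: TSS at the 2nd constituent's start, inside the SE span
        tg_body = GenomicInterval(tad.chrom, consts[1].start, consts[1].start + 20_000)
        tg = GeneRecord(f"G{len(genes):04d}", f"G{len(genes):04d}", "+", tg_body)
        genes_by_tad[ti].append(len(genes))
        truth.boosted_genes.append(tg.gene_id)
        genes.append(tg)
        ses.append({
            "chrom": tad.chrom,
            "start": consts[0].start,
            "end": consts[-1].end,
            "position_class": planted_class,
            "target_gene": tg.gene_id,
            "host_tad": ti,
            "constituents": [(c.start, c.end) for c in consts],
        })
    truth.ses = ses

    typical: list[GenomicInterval] = []
    all_tads = list(range(len(tads)))
    for _ in range(cfg.n_typical):
        ti, s = layout.pop_slot_any(all_tads)
        iv = GenomicInterval(tads[ti].chrom, s + 8000, s + 9500)
        typical.append(iv)
        segments.append(ChromatinStateSegment(iv, "enhancer_2"))
    truth.typical = [(t.chrom, t.start, t.end) for t in typical]

    # promoter-state segments for ordinary genes (SE target genes sit on
    # enhancer constituents already, which would overlap)
    boosted = set(truth.boosted_genes)
    for g in genes:
        if g.gene_id not in boosted:
            segments.append(ChromatinStateSegment(
                GenomicInterval(g.chrom, g.tss - 1000, g.tss + 1000), "promoter"
            ))

    # ----- loops ----------------------------------------------------------
    bs = cfg.bin_size
    loops: list[Loop] = []
    loop_roles: list[str] = []
    loop_target_genes: set[str] = set()

    def _foot(chrom: str, b: int) -> GenomicInterval:
        return GenomicInterval(chrom, b * bs, (b + 1) * bs)

    def _add_loop(chrom: str, pos_a: int, pos_b: int, role: str, book=(True, True)) -> int:
        ba = layout.book_bin(chrom, pos_a, bs) if book[0] else pos_a // bs
        bb = layout.book_bin(chrom, pos_b, bs) if book[1] else pos_b // bs
        loops.append(Loop(_foot(chrom, ba), _foot(chrom, bb), qvalue=0.001))
        loop_roles.append(role)
        return len(loops) - 1

    # SE loops: SE anchor -> an ordinary-gene promoter in the same TAD
    for se in ses:
        ti = se["host_tad"]
        candidates = [gi for gi in genes_by_tad[ti]
                      if genes[gi].gene_id not in boosted
                      and genes[gi].gene_id not in loop_target_genes]
        if not candidates:
            continue
        gi = candidates[0]
        anchor = se["constituents"][0][0]
        if not layout.bin_free(se["chrom"], anchor, bs):
            continue
        _add_loop(se["chrom"], anchor, genes[gi].tss, "se_loop", book=(True, False))
        loop_target_genes.add(genes[gi].gene_id)

    # background intra-TAD loops between otherwise-empty slots
    for _ in range(cfg.n_background_loops):
        ti, s1 = layout.pop_slot_any(all_tads)
        if not layout.slots[ti]:
            continue
        s2 = layout.pop_slot(ti)
        _add_loop(tads[ti].chrom, s1 + 20_000, s2 + 20_000, "background")

    # ----- eQTLs ----------------------------------------------------------
    eqtl_rows: list[dict] = []
    n = cfg.eqtl_per_class
    n_same = round(cfg.same_tad_fraction * n)
    n_in_a = round(cfg.compartment_a_fraction * n)

    def _host_pool(k: int) -> list[int]:
        return a_tads if k < n_in_a else b_tads

    def _pick_gene(ti: int, same: bool, exclude_loop_targets=False) -> int:
        if same:
            pool = genes_by_tad[ti]
        else:
            chrom = tads[ti].chrom
            pool = [gi for tj, gl in genes_by_tad.items() for gi in gl
                    if tj != ti and tads[tj].chrom == chrom]
        if exclude_loop_targets:
            pool = [gi for gi in pool if genes[gi].gene_id not in loop_target_genes]
        pool = [gi for gi in pool if genes[gi].gene_id not in boosted]
        if not pool:
            raise GenerationError("no eligible eGene for planted eQTL")
        return pool[int(rng_eqtl.integers(0, len(pool)))]

    def _emit(variant_id, chrom, pos, egene_idx, loop_class, position_class, reg_class, same):
        eqtl_rows.append({
            "variant_id": variant_id, "chrom": chrom, "pos": pos,
            "egene_id": genes[egene_idx].gene_id, "tags": "",
            "truth_loop_class": loop_class, "truth_position_class": position_class,
            "truth_regulatory_class": reg_class, "truth_same_tad": same,
        })

    vc = 0
    # egene_pieqtl: loop from variant bin to the eGene promoter bin
    for k in range(n):
        ti, s = layout.pop_slot_any(_host_pool(k))
        same = k < n_same
        gi = _pick_gene(ti, same)
        pos = s + 20_000 + 2500
        _add_loop(tads[ti].chrom, pos, genes[gi].tss, "eqtl_egene", book=(True, False))
        loop_target_genes.add(genes[gi].gene_id)
        _emit(f"veg{vc}", tads[ti].chrom, pos, gi, "egene_pieqtl", "distal", "none", same)
        vc += 1
    # non_egene_pieqtl: loop to another gene's promoter; eGene elsewhere
    for k in range(n):
        ti, s = layout.pop_slot_any(_host_pool(k))
        same = k < n_same
        hi_ = _pick_gene(ti, True)                      # promoter contacted
        gi = _pick_gene(ti, same)
        tries = 0
        while genes[gi].gene_id == genes[hi_].gene_id:
            gi = _pick_gene(ti, same)
            tries += 1
            if tries > 50:
                raise GenerationError("cannot separate eGene from contacted gene")
        pos = s + 20_000 + 2500
        _add_loop(tads[ti].chrom, pos, genes[hi_].tss, "eqtl_nonegene", book=(True, False))
        loop_target_genes.add(genes[hi_].gene_id)
        _emit(f"vne{vc}", tads[ti].chrom, pos, gi, "non_egene_pieqtl", "distal", "none", same)
        vc += 1
    # eqtl_only: loops between paired empty slots; a variant on each foot
    k = 0
    while k < n:
        ti, s1, s2 = layout.pop_slot_pair(_host_pool(k))
        p1, p2 = s1 + 20_000 + 2500, s2 + 20_000 + 2500
        _add_loop(tads[ti].chrom, p1, p2, "eqtl_only")
        for pos in (p1, p2):
            if k >= n:
                break
            same = k < n_same
            gi = _pick_gene(ti, same)
            _emit(f"vo{vc}", tads[ti].chrom, pos, gi, "eqtl_only", "distal", "none", same)
            vc += 1
            k += 1
    # not_on_loop: empty slot, no loop
    for k in range(n):
        ti, s = layout.pop_slot_any(_host_pool(k))
        same = k < n_same
        gi = _pick_gene(ti, same)
        pos = s + 20_000 + 2500
        layout.book_bin(tads[ti].chrom, pos, bs)
        _emit(f"vnl{vc}", tads[ti].chrom, pos, gi, "not_on_loop", "distal", "none", same)
        vc += 1
    # promoter eQTLs: 1.05-2 kb from an un-looped gene's TSS (outside the
    # promoter-state segment so the regulatory class stays "none")
    promoter_reserved: set[str] = set()
    promoter_pool = [gi for gi in range(len(genes))
                     if genes[gi].gene_id not in loop_target_genes
                     and genes[gi].gene_id not in boosted]
    promoter_pool = [promoter_pool[i] for i in rng_eqtl.permutation(len(promoter_pool))]
    if len(promoter_pool) < n:
        raise GenerationError("not enough un-looped genes for promoter eQTLs")
    for k in range(n):
        gi = promoter_pool[k]
        offset = int(rng_eqtl.integers(1050, 2001)) * (1 if k % 2 == 0 else -1)
        pos = genes[gi].tss + offset
        # reserve the gene so later stages cannot anchor a loop on its body
        promoter_reserved.add(genes[gi].gene_id)
        _emit(f"vp{vc}", genes[gi].chrom, pos, gi, "not_on_loop", "promoter", "none", True)
        vc += 1
    # regulatory SE: variant inside an SE constituent whose bin carries no foot
    for k in range(n):
        se = ses[k % len(ses)]
        pos = None
        for c_start, c_end in reversed(se["constituents"]):
            cand = c_start + (c_end - c_start) // 2
            if layout.bin_free(se["chrom"], cand, bs):
                pos = cand
                break
        if pos is None:
            raise GenerationError("no foot-free constituent for SE eQTL")
        same = k < n_same
        ti = se["host_tad"]
        gi = (genes.index(next(g for g in genes if g.gene_id == se["target_gene"]))
              if same else _pick_gene(ti, False))
        _emit(f"vse{vc}", se["chrom"], pos, gi, "not_on_loop", "distal", "SE", same)
        vc += 1
    # regulatory CRE: variant inside a typical enhancer
    for k in range(n):
        te = typical[k % len(typical)]
        pos = te.start + 750
        if not layout.bin_free(te.chrom, pos, bs):
            raise GenerationError("typical enhancer bin unexpectedly booked")
        ti = next(i for i, t in enumerate(tads) if t.contains(te))
        same = k < n_same
        gi = _pick_gene(ti, same)
        _emit(f"vcre{vc}", te.chrom, pos, gi, "not_on_loop", "distal", "CRE", same)
        vc += 1

    eqtls = pd.DataFrame(eqtl_rows)

    # ----- GWAS -----------------------------------------------------------
    lead_rows, ld_rows = [], []
    n_linked = round(cfg.leads_per_disease * cfg.linked_locus_fraction)
    for disease in cfg.diseases:
        for li in range(cfg.leads_per_disease):
            linked = li < n_linked
            ti, s = layout.pop_slot_any(all_tads)
            chrom = tads[ti].chrom
            lead_pos = s + 20_000 + 1000
            rsid = f"rs{disease[:3]}{li}"
            lead_rows.append({"rsid": rsid, "chrom": chrom, "pos": lead_pos,
                              "locus": f"{disease}_locus_{li}", "disease": disease})
            foot_bin = lead_pos // bs
            loop_idx = None
            if linked:
                # target an ordinary gene body in another TAD on this chrom,
                # in a bin not already carrying a foot or TSS
                target = None
                for _ in range(50):
                    gi = _pick_gene(ti, False)
                    if genes[gi].gene_id in promoter_reserved:
                        continue
                    body = genes[gi].body
                    for b in range(body.start // bs, (body.end - 1) // bs + 1):
                        cand = b * bs + bs // 2
                        if body.contains_point(cand) and layout.bin_free(chrom, cand, bs):
                            target = cand
                            break
                    if target is not None:
                        break
                if target is None:
                    raise GenerationError("no free gene-body bin for GWAS loop")
                loop_idx = _add_loop(chrom, lead_pos, target, "gwas", book=(True, True))
                truth.gwas_links.append((rsid, genes[gi].gene_id, loop_idx))
            else:
                layout.book_bin(chrom, lead_pos, bs)
                truth.control_leads.append(rsid)
            n_pass = round(cfg.ld_per_lead * cfg.ld_pass_fraction)
            for vi in range(cfg.ld_per_lead):
                passes = vi < n_pass
                on_foot = linked and passes and vi % 2 == 0
                if on_foot:
                    pos = foot_bin * bs + 100 + vi * 30
                else:
                    # off-foot: a neighbouring bin of the same slot
                    pos = s + 4_000 + (vi % 3) * 3000 + vi * 7
                maf = float(rng_gwas.uniform(0.05, 0.5)) if passes else float(rng_gwas.uniform(0.001, 0.009))
                r2 = float(rng_gwas.uniform(0.7, 1.0)) if passes else float(rng_gwas.uniform(0.1, 0.69))
                ld_rsid = f"{rsid}_ld{vi}"
                ld_rows.append({"rsid": ld_rsid, "chrom": chrom, "pos": pos,
                                "lead_rsid": rsid, "r2": r2, "maf": maf})
                if on_foot and loop_idx is not None:
                    gene_id = next(g for r, g, l in truth.gwas_links if r == rsid and l == loop_idx)
                    truth.gwas_links.append((ld_rsid, gene_id, loop_idx))
    leads = pd.DataFrame(lead_rows)
    ld = pd.DataFrame(ld_rows)

    truth.loops = [(lp.chrom, lp.footA.start // bs, lp.footB.start // bs, role)
                   for lp, role in zip(loops, loop_roles)]

    # ----- expression -----------------------------------------------------
    for g in genes:
        base = float(rng_expr.lognormal(cfg.expression_log_mean, cfg.expression_log_sd))
        g.expression = base * (cfg.se_boost if g.gene_id in boosted else 1.0)
        if g.gene_id in boosted:
            g.set_labels = ["retina-enriched"]

    # ----- signal tracks --------------------------------------------------
    case_track, control_track = _make_tracks(build, cfg, segments, rng_signal)

    # low-signal filler states between planted segments (annotation tiling)
    segments = _fill_low_states(build, segments)

    # ----- contact matrices -----------------------------------------------
    matrices = (_make_matrices(build, cfg, tads, blocks, loops, rng_matrix)
                if cfg.make_matrix else {})

    # ----- TAD group truth -------------------------------------------------
    se_classes_by_tad: dict[int, list[str]] = {}
    for se in ses:
        se_classes_by_tad.setdefault(se["host_tad"], []).append(se["position_class"])
    for ti, tad in enumerate(tads):
        lab = tad_comp[ti]
        if lab == "B":
            group = "B_compartment"
        elif lab == "A":
            classes = se_classes_by_tad.get(ti, [])
            group = ("A_edge_SE" if "edge" in classes
                     else "A_nonedge_SE" if classes else "A_no_SE")
        else:
            group = "unassigned"
        truth.tad_groups[f"{tad.chrom}:{tad.start}-{tad.end}"] = group

    result = SimulationResult(
        cfg, build, tads, blocks, segments, case_track, control_track,
        genes, loops, matrices, eqtls, leads, ld, truth,
    )
    _verify_truth(result)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _make_tracks(build, cfg, segments, rng) -> tuple[SignalTrack, SignalTrack]:
    sb = cfg.signal_bin
    rate = {"enhancer_1": cfg.lambda_se, "enhancer_2": cfg.lambda_typical,
            "promoter": cfg.lambda_promoter}
    case_vals, ctrl_vals = {}, {}
    for chrom, size in build.items():
        nb = math.ceil(size / sb)
        lam = np.full(nb, cfg.lambda_background)
        for seg in segments:
            if seg.interval.chrom != chrom or seg.state not in rate:
                continue
            b0 = seg.interval.start // sb
            b1 = (seg.interval.end - 1) // sb
            lam[b0 : b1 + 1] = rate[seg.state]
        if cfg.noise == "poisson":
            case = rng.poisson(lam * sb).astype(float) / sb
            ctrl = rng.poisson(np.full(nb, cfg.lambda_background) * sb).astype(float) / sb
        else:
            case = lam.copy()
            ctrl = np.full(nb, cfg.lambda_background)
        case_vals[chrom] = case
        ctrl_vals[chrom] = ctrl
    return (SignalTrack(build, sb, case_vals), SignalTrack(build, sb, ctrl_vals))


def _fill_low_states(build, segments) -> list:
    out = list(segments)
    by_chrom: dict[str, list] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s.interval)
    for chrom, size in build.items():
        ivs = sorted(by_chrom.get(chrom, []), key=lambda x: x.start)
        pos = 0
        for iv in ivs:
            if iv.start > pos:
                out.append(ChromatinStateSegment(GenomicInterval(chrom, pos, iv.start), "low_1"))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(ChromatinStateSegment(GenomicInterval(chrom, pos, size), "low_1"))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return out


def _make_matrices(build, cfg, tads, blocks, loops, rng) -> dict:
    bs = cfg.bin_size
    matrices = {}
    for chrom, size in build.items():
        n = size // bs
        idx = np.arange(n)
        tad_id = np.full(n, -1)
        for ti, t in enumerate(tads):
            if t.chrom == chrom:
                tad_id[t.start // bs : t.end // bs] = ti
        comp = np.zeros(n, dtype=int)
        for seg, lab in blocks:
            if seg.chrom == chrom:
                comp[seg.start // bs : seg.end // bs] = 1 if lab == "A" else 2

        d = np.abs(np.subtract.outer(idx, idx))
        expected = cfg.base_contacts * (d + 1.0) ** (-cfg.distance_decay)
        expected *= np.where(np.equal.outer(tad_id, tad_id) & (tad_id >= 0)[:, None],
                             cfg.tad_factor, 1.0)
        expected *= np.where(np.equal.outer(comp, comp) & (comp > 0)[:, None],
                             cfg.compartment_factor, 1.0)
        for lp in loops:
            if lp.chrom != chrom:
                continue
            ba, bb = lp.footA.start // bs, lp.footB.start // bs
            expected[ba, bb] *= cfg.loop_strength
            expected[bb, ba] *= cfg.loop_strength
        if cfg.noise == "poisson":
            upper = np.triu(rng.poisson(expected)).astype(float)
            mat = upper + np.triu(upper, 1).T
        else:
            mat = (expected + expected.T) / 2
        matrices[chrom] = ContactMatrix(chrom, bs, mat)
    return matrices


def _verify_truth(result: SimulationResult) -> None:
    """Re-derive planted eQTL labels with the package's own predicates."""
    from .eqtl import classify_position, pieqtl_classify, regulatory_overlap, same_tad_analysis

    eq = result.eqtls
    pos_cls = classify_position(eq, result.genes)
    if not (pos_cls == eq["truth_position_class"]).all():
        raise GenerationError("planted position classes not realized")
    loop_cls = pieqtl_classify(eq, result.loops, result.genes, build=result.build)
    if not (loop_cls == eq["truth_loop_class"]).all():
        bad = eq.loc[loop_cls != eq["truth_loop_class"], "variant_id"].tolist()
        raise GenerationError(f"planted loop classes not realized: {bad[:5]}")
    se_ivs = [GenomicInterval(s["chrom"], s["start"], s["end"]) for s in result.truth.ses]
    cre_like = se_ivs + [GenomicInterval(*t) for t in result.truth.typical]
    reg = regulatory_overlap(eq, cre_like, se_ivs, result.genes)
    if not (reg["regulatory_class"] == eq["truth_regulatory_class"]).all():
        raise GenerationError("planted regulatory classes not realized")
    flags, _ = same_tad_analysis(eq, result.genes, result.tads)
    if not (flags == eq["truth_same_tad"]).all():
        raise GenerationError("planted same-TAD flags not realized")


def null_variant_shuffle(eqtls: pd.DataFrame, build: GenomeBuild, seed: int) -> pd.DataFrame:
    """Uniformly re-sample each variant's position on its chromosome,
    keeping the eGene assignments (supports calibration tests)."""
    rng = np.random.default_rng(seed)
    out = eqtls.copy()
    out["pos"] = [int(rng.integers(0, build[c])) for c in out["chrom"]]
    return out


def conserved_genome_pair(
    n_pairs: int = 20,
    tad_fraction: float = 0.4,
    loop_fraction: float = 0.4,
    seed: int = 0,
):
    """Two-genome fixture with an exactly planted conservation fraction.

    Species B has `n_pairs` TADs, each holding one gene pair connected by a
    loop. In species A, round(tad_fraction*n) ortholog pairs keep a shared
    TAD and round(loop_fraction*n) keep their loop; the rest are separated.
    Returns (tads_a, loops_a, genes_a, tads_b, loops_b, genes_b, ortholog_map).
    """
    rng = np.random.default_rng(seed)
    tad_len, gene_len = 400_000, 20_000

    def _make(n_tads, pair_in_tad):
        tads, genes, loops = [], [], []
        pos = 0
        for i in range(n_tads):
            tads.append(GenomicInterval("chr1", pos, pos + tad_len))
            pos += tad_len
        return tads

    # species B: each TAD holds genes 2i, 2i+1 with a loop between them
    tads_b = _make(n_pairs, True)
    genes_b, loops_b = [], []
    for i, tad in enumerate(tads_b):
        g1 = GeneRecord(f"b{2*i}", f"b{2*i}", "+",
                        GenomicInterval("chr1", tad.start + 50_000, tad.start + 50_000 + gene_len))
        g2 = GeneRecord(f"b{2*i+1}", f"b{2*i+1}", "+",
                        GenomicInterval("chr1", tad.start + 200_000, tad.start + 200_000 + gene_len))
        genes_b += [g1, g2]
        loops_b.append(Loop(
            GenomicInterval("chr1", g1.body.start, g1.body.start + 5000),
            GenomicInterval("chr1", g2.body.start, g2.body.start + 5000),
        ))
    n_keep_tad = round(tad_fraction * n_pairs)
    n_keep_loop = round(loop_fraction * n_pairs)
    keep_tad = set(rng.choice(n_pairs, size=n_keep_tad, replace=False).tolist())
    keep_loop = set(rng.choice(sorted(keep_tad), size=min(n_keep_loop, n_keep_tad),
                               replace=False).tolist())
    if n_keep_loop > n_keep_tad:  # loops can also survive across split TADs
        extra = [i for i in range(n_pairs) if i not in keep_tad]
        keep_loop |= set(extra[: n_keep_loop - n_keep_tad])

    # species A: preserved pairs share a TAD; split pairs go to separate TADs
    genes_a, loops_a, tads_a = [], [], []
    pos = 0
    ortholog_map = {}
    for i in range(n_pairs):
        if i in keep_tad:
            tads_a.append(GenomicInterval("chr1", pos, pos + tad_len))
            s1, s2 = pos + 50_000, pos + 200_000
            pos += tad_len
        else:
            tads_a.append(GenomicInterval("chr1", pos, pos + tad_len))
            tads_a.append(GenomicInterval("chr1", pos + tad_len, pos + 2 * tad_len))
            s1, s2 = pos + 50_000, pos + tad_len + 50_000
            pos += 2 * tad_len
        g1 = GeneRecord(f"a{2*i}", f"a{2*i}", "+", GenomicInterval("chr1", s1, s1 + gene_len))
        g2 = GeneRecord(f"a{2*i+1}", f"a{2*i+1}", "+", GenomicInterval("chr1", s2, s2 + gene_len))
        genes_a += [g1, g2]
        ortholog_map[f"b{2*i}"] = f"a{2*i}"
        ortholog_map[f"b{2*i+1}"] = f"a{2*i+1}"
        if i in keep_loop:
            loops_a.append(Loop(
                GenomicInterval("chr1", s1, s1 + 5000),
                GenomicInterval("chr1", s2, s2 + 5000),
            ))
    return tads_a, loops_a, genes_a, tads_b, loops_b, genes_b, ortholog_map


def _write_bundle(result: SimulationResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    chio.write_bed(out_dir / "tads.bed", result.tads)
    chio.write_bed(out_dir / "compartments.bed", [
        GenomicInterval(seg.chrom, seg.start, seg.end, name=lab)
        for seg, lab in result.compartment_segments
    ])
    chio.write_bed(out_dir / "states.bed", [
        GenomicInterval(s.interval.chrom, s.interval.start, s.interval.end, name=s.state)
        for s in result.segments
    ])
    chio.write_bedpe(out_dir / "loops.bedpe", result.loops)
    chio.write_bedgraph(out_dir / "h3k27ac_case.bedgraph", result.case_track)
    chio.write_bedgraph(out_dir / "h3k27ac_control.bedgraph", result.control_track)
    chio.write_genes(out_dir / "genes.tsv", result.genes)
    chio.write_eqtls(out_dir / "eqtls.tsv", result.eqtls)
    chio.write_variants(out_dir / "gwas_leads.tsv", result.leads)
    chio.write_variants(out_dir / "gwas_ld.tsv", result.ld)
    for chrom, cm in result.matrices.items():
        chio.write_matrix_triplet(out_dir / f"matrix_{chrom}.txt", cm.matrix)
        with open(out_dir / f"matrix_{chrom}.json", "w") as fh:
            json.dump({"chrom": chrom, "bin_size": cm.bin_size, "n_bins": cm.n_bins}, fh)
    result.truth.to_json(out_dir / "truth.json")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)
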