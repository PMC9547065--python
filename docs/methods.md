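# Methods

`chromhub` implements an integrative 3D-genome analysis pipeline of the kind
used in tissue Hi-C studies of gene regulation: it combines chromatin loops
and topologically associating domains (TADs) with chromatin-state–derived
cis-regulatory elements (CREs), H3K27Ac-defined super-enhancers (SEs),
expression, eQTLs and GWAS variants. This note records the models and
procedures, the parameters that matter, what the synthetic data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Coordinate model

All internal coordinates are 0-based, half-open `[start, end)` (the BED
convention). Variant tables are 1-based on disk and converted at the I/O
boundary, in both directions. Two intervals overlap iff
`a.start < b.end and b.start < a.end` on the same chromosome; a variant is a
1-bp interval `[pos, pos+1)`. The interval engine (overlap join, closest
feature with deterministic tie-breaks, containment) is written to be
verifiable against brute-force all-pairs scans, and the test suite holds it
to exact agreement on ≥1,000 randomized cases. `closest` ties break to the
smaller feature start, then input order — a deliberate single-answer rule
where bedtools would report all ties.

A chromatin loop is a pair of anchor intervals ("feet", 5 kb bins from the
loop caller) on one chromosome, stored in canonical order. Loop *size* is
the distance between foot midpoints, which is insensitive to foot width.

## Contact-matrix topology

**Expected-by-distance and compartments.** The observed/expected (O/E)
matrix divides each pixel by the mean of its diagonal over valid bins.
Compartments are the canonical first-principal-component call: Pearson
correlation of O/E rows, leading eigenvector of the correlation matrix,
positive bins labelled A. Because the eigenvector sign is arbitrary, it is
oriented against an activity reference track (H3K27Ac coverage or gene
density): the sign is flipped when the eigenvector covaries negatively with
the reference. Covariance is used rather than an above-median rule because
the reference may be binary (more than half the bins "active" leaves the
above-median set empty). Degenerate inputs — uniform matrices, fewer than
10 informative bins, rank-0 correlation — raise an error rather than
emitting an arbitrary labelling. The call is invariant under uniform
scaling of the matrix, which the tests assert.

**Diamond insulation.** For bin *i* and window *w* bins, the raw score is
the mean contact over the off-diagonal square `{i−w…i−1} × {i+1…i+w}`
restricted to valid pixels; the reported value is
`log2(raw / chromosome-wide mean raw)`. The first and last *w* bins are
undefined. This is the "contacts crossing the locus" convention; it
deliberately does **not** normalize by contacts in the adjacent regions,
a choice that matters for loci rich in local loops (such as SE-containing
TADs) where adjacent-region normalization biases boundary scores. Default
window 100 kb on 5 kb bins (w = 20). Per-TAD boundary insulation is the
mean of the insulation values at the two bins containing the TAD's start
and end coordinates; a TAD with one invalid boundary bin keeps the valid
value and is flagged. A single containing bin per boundary (rather than a
small window) keeps the statistic local and is the simplest defensible
reading of a per-boundary score.

## CREs and super-enhancer calling

CREs are the interval union of the active chromatin states (the promoter
state plus five enhancer states, by default), merging overlapping or
touching segments. CREs fully contained in a promoter window
(TSS ± 2.5 kb) are removed before SE calling, so that promoter-only loci do
not enter the enhancer ranking; CREs merely overlapping a promoter window
are kept.

SE calling follows the ROSE recipe: CREs whose gap is < 12.5 kb
(the classic stitching distance, configurable) are chained into stitched
regions; each region's signal is case coverage minus input coverage summed
over **constituent CREs only** (gaps between constituents do not count),
floored at zero. Regions are ranked ascending; with rank and signal both
min–max scaled to [0, 1], the cutoff is the discrete tangent-slope-1 elbow
`argmin(y − x)`, taking the largest index on ties (conservative: fewer
SEs). Regions strictly above the cutoff signal are super-enhancers. The
rule is invariant under affine rescaling of the signals; all-equal or
perfectly linear rank curves yield zero SEs by the tie rule, with a
warning for the former.

## Resampling nulls and the enrichment statistic

Two nulls mirror the standard tool semantics:

* **Random regions** (bedtools-random-like): *n* sets of `count` regions of
  fixed `length` (observed count and median length of the SE set), with
  chromosome chosen proportionally to placeable length and starts uniform;
  regions within a set may overlap.
* **Random TADs** (regioneR-like): each set reuses the observed TAD length
  multiset — so count and mean length are preserved exactly — placed
  without within-set overlap. Placement is per chromosome: the
  chromosome's lengths are shuffled and laid out left-to-right with the
  free space split uniformly at random among the gaps (a uniform integer
  composition). This one-pass construction samples a random
  non-overlapping arrangement at *any* domain density, including
  chromosomes the observed TADs tile completely, where naive rejection
  sampling jams.

Seeds are mandatory; every generator is a pure function of (build,
parameters, seed).

**Enrichment statistic.** `enrichment_t(observed, random_values)` is the
one-sample t of the *n* null values against the observed value treated as
a constant: `t = (mean(r) − observed)/(sd(r)/√n)`, df = n − 1, two-sided
p. With 100 null sets this yields the familiar df = 99. The sign
convention is fixed: negative t means the observed value exceeds the null
mean. Two caveats are intrinsic to this statistic and documented rather
than hidden:

* Its type-I error is calibrated for the hypothesis it actually tests —
  that the null distribution's mean equals the observed constant. The
  calibration tests therefore fix the observed value at the null mean and
  verify ~5% rejections at α = 0.05 over 2,000 simulations.
* When the observed quantity itself fluctuates as much as one null draw,
  the statistic is strongly anti-conservative (its denominator is the
  standard error of a mean of 100 sets, not of one set). That is why
  observed-vs-null comparisons of whole-set statistics produce very large
  |t| even for modest effects. For exchangeable-null questions the result
  also carries `p_empirical`, the plus-one–corrected empirical two-sided
  quantile of the observed value in the null distribution, which is
  calibrated under exchangeability; the shuffled-variant calibration test
  uses it.

## Topology statistics

* **SE placement**: a region hosted by a TAD (fully contained) is `edge`
  when `min(start − tad.start, tad.end − end) < 5 kb`, else `non_edge`;
  regions overlapping a TAD without containment are `spanning_boundary`;
  regions touching no TAD are `outside_tad`. The classification is
  exhaustive and mutually exclusive.
* **TAD grouping**: a TAD joins `A`/`B` only when every bp is covered by
  segments of one compartment label; otherwise it is `unassigned`.
  A-compartment TADs split into `A_no_SE`, `A_nonedge_SE` and `A_edge_SE`
  (an edge SE dominates). Spanning-boundary SEs count as edge SEs for
  every TAD they overlap (configurable off): their boundary distance is
  below any threshold by construction.
* **Loop/TAD and loop/region statistics**: a loop is "in contact" with a
  TAD or region when ≥1 foot overlaps it (counted once per TAD it
  touches); it "crosses" a TAD boundary when exactly one foot overlaps.
  A region-touching loop crosses TADs when no single TAD overlaps both
  feet and at least one foot lies in some TAD; loops entirely outside the
  TAD layout count as non-crossing. Contacted-feature counts follow loops
  with exactly one foot in a region and count unique CREs, TSSs and other
  regions hit by the distal foot.
* **Expression**: a gene belongs to a region class when ≥1 TSS lies inside
  a region, counted once regardless of multiplicity; fold-changes are
  ratios of class means.
* **Gene-pair conservation** (two-genome comparison): species-B unordered
  gene pairs share a TAD when both TSSs fall in one TAD and are
  loop-connected when some loop joins the two gene bodies; the conserved
  fraction is the share of species-B pairs whose one-to-one mapped
  orthologs satisfy the same predicate in species A. Gene bodies (not
  promoters) define loop connection at this gene-level granularity.

## eQTL classification

Each variant–eGene pair is classified on five axes:

1. **Position**: `promoter` iff |variant − eGene TSS| ≤ 2.5 kb on the same
   chromosome (boundary inclusive), else `distal`; trans pairs are distal
   and flagged.
2. **Compartment**: label of the compartment segment containing the
   variant; `none` in gaps.
3. **Same-TAD**: one TAD contains both the variant and the eGene TSS;
   the observed proportion is compared to 100 random-TAD proportions with
   the enrichment t.
4. **Loop taxonomy**: over all loops with a foot covering the variant, the
   opposite feet are tested against promoter windows (TSS ± 2.5 kb) of all
   genes: `egene_pieqtl` if any hits the eGene promoter, else
   `non_egene_pieqtl` if any promoter is hit, else `eqtl_only`;
   `not_on_loop` without any foot. A variant on several loops takes the
   best-supported class — the taxonomy is monotone in the loop set.
5. **Regulatory context**: variant-in-SE takes precedence over
   variant-in-CRE; the containing region is then tested for overlap with
   the eGene body. Local H3K27Ac is summed in the inclusive ±100 bp window
   around the variant; promoter-vs-distal contrasts use Welch's t with
   Satterthwaite df, computed distal-first so higher promoter signal gives
   negative t.

## GWAS variant-to-gene linking

LD variants are kept when `MAF ≥ 0.01` **and** `r² ≥ 0.7`, both bounds
inclusive; records missing either value are dropped with a warning
(configurable to error). Target-gene mechanisms, each carrying re-checkable
evidence: `loop_to_body` / `loop_to_tss` (variant on one foot, gene body or
TSS on the other), `cre_shared` / `se_shared` (variant and gene body or TSS
inside the same region), and `closest` (nearest gene body, deterministic
tie-break) as a fallback annotation. Summaries deduplicate variants per
category; a gene reachable through several loops yields several links but
one counted variant.

## Synthetic data generator

The generator emulates the *derived products* of such a study — not reads
or fragments — on a toy genome, with machine-readable planted truth for
every entity.

**Defaults (the study conditions of every recovery test).** Genome
2 × 10 Mb; matrix bins 5 kb. TAD lengths uniform 0.5–1.1 Mb (mean 800 kb)
tiling each chromosome; consecutive runs of 2–3 TADs form alternating A/B
compartment blocks, so every TAD lies wholly in one compartment. Contact
expectation at bin separation *d*: `100·(d+1)^(−1)`, ×3 when both bins
share a TAD, ×1.5 when they share a compartment label, ×4 at planted loop
anchor pairs, then Poisson-sampled (upper triangle, mirrored). The base
level of 100 contacts at the diagonal reflects a deeply sequenced
experiment resolved at ~5 kb; decay exponent 1.0 is the generic power law.
H3K27Ac case coverage is Poisson with per-bp rate 1 (background), 20 (SE
constituents), 4 (typical enhancers), 6 (promoters) in 100 bp track bins;
the input/control track is background-only. 16 SEs (half planted < 5 kb
from a TAD boundary, half central) of 3–4 constituents (1.5–2.5 kb wide,
gaps 3–6 kb, all < 12.5 kb so stitching reassembles them); 30 isolated
typical enhancers. ~3 genes per TAD plus one target gene per SE with its
TSS inside the SE span. Expression is log-normal (median 10, log-sd 0.25)
×2.0 for SE target genes; the modest dispersion keeps the planted 2×
effect identifiable at ~100 genes, which is what the parameter-recovery
check exercises. 25 eQTLs per planted class (four loop classes, promoter
class, SE- and CRE-resident classes) with 70% of each class sharing a TAD
with its eGene and 80% hosted in A-compartment TADs. Two diseases × 4 GWAS
leads × 30 LD variants (60% passing the MAF/r² filter); half the loci are
"linked" (lead and half of their passing LD variants sit on a loop foot
whose other foot lies in a gene body), the other half are loop-free
controls.

**Layout discipline.** Each TAD is divided into 40 kb slots; every planted
element (gene, SE cluster, typical enhancer, variant anchor) gets its own
slot. This guarantees >12.5 kb between unrelated elements (stitching
cannot chain them) and >2.5 kb between variants and unintended TSSs. Loop
feet and variant positions are booked in a per-5kb-bin registry so no
planted class is contaminated by another element's loop. After assembly
the generator re-derives every planted eQTL label with the package's own
classification predicates and *refuses to emit* an inconsistent bundle —
planting bugs surface as generation errors, not as silently wrong truth.

**What it does not emulate.** Read-level noise and mappability, matrix
balancing artefacts, overlapping or nested regulatory elements, genes with
multiple TSSs, trans contacts, LD structure beyond a flat block around the
lead, and hg38 scale. Passing recovery tests therefore demonstrate
correctness of the *computations* under clean planted structure, not
robustness to every pathology of real data. TADs and loops are emitted as
truth rather than re-called — loop and TAD calling are upstream of this
pipeline — but the contact matrix is generated consistently with that
truth so the insulation and compartment stages have a real input.

## Problem sizes in the validation suite

The default bundle (2 × 2,000-bin matrices, ~100 genes, ~100 loops, 175
eQTL pairs, 240 LD variants) runs the full pipeline in seconds, so the
test suite and the acceptance script regenerate everything from scratch:
interval oracles on 1,000 randomized cases, type-I calibration over 2,000
simulated nulls, expression-boost recovery across 10 seeds, and a
byte-level determinism check over the whole emitted bundle.

## Known limitations

* Compartment calling on raw (unbalanced) synthetic matrices is adequate
  because the generator has no coverage biases; real matrices should be
  balanced upstream (balancing is accepted as input, not implemented).
* The insulation minimum localizes boundaries to ±1 bin only when window
  and TAD sizes are well separated; very short TADs (< window) blur.
* The enrichment t inherits the anti-conservatism described above
  whenever the observed statistic has set-level sampling noise; use
  `p_empirical` for exchangeable-null questions.
* `closest` reports a single deterministic neighbor; consumers needing
  all ties should query `IntervalIndex.overlapping` at an expanded range.
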