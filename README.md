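# chromhub

Integrative 3D-genome analysis for regulatory genomics: who is a
super-enhancer, where does it sit in the TAD landscape, and which variants
reach which genes through chromatin loops.

Tissue Hi-C studies produce a layered set of derived objects — chromatin
loops and TADs from a contact matrix, A/B compartments, chromatin-state
segments merged into cis-regulatory elements (CREs), H3K27Ac-ranked
super-enhancers (SEs) — and then ask integrative questions: do SEs sit at
TAD edges, do eQTL variants share a TAD with their eGene, which GWAS risk
variants physically contact a gene. `chromhub` implements that integration
layer as a tested, reusable library for analysts working with loop calls
(BEDPE), TAD/compartment/state intervals (BED), coverage (bedGraph), gene
and variant tables (TSV), and binned contact matrices, together with a
synthetic-data generator that plants known truth through every stage so
the whole pipeline can be validated end to end without any external data.

## What it computes

* **Interval engine** — overlap joins, closest-feature with deterministic
  tie-breaks, coverage sums; 0-based half-open everywhere; exact against
  brute-force oracles.
* **Matrix topology** — observed/expected normalization, A/B compartments
  as the leading eigenvector of the O/E correlation matrix (PC1, sign
  oriented by an activity track, positive = A), and the diamond insulation
  score: for bin *i* and window *w*, `log2` of the mean contact over
  `{i−w…i−1}×{i+1…i+w}` relative to the chromosome-wide mean; minima mark
  TAD boundaries.
* **SE calling (ROSE-style)** — active states → merged CREs → removal of
  CREs inside TSS ± 2.5 kb windows → stitching at < 12.5 kb → case-minus-
  input signal over constituents → ascending rank curve, min–max scaled,
  cutoff at the discrete tangent-slope-1 elbow `argmin(y − x)`.
* **Resampling nulls** — 100 sets of random SE-sized regions and 100 sets
  of random TADs preserving the observed length multiset; enrichment via
  the one-sample statistic `t = (mean(null) − observed)/(sd(null)/√n)`,
  df = n − 1 (negative t ⇒ observed exceeds the null mean).
* **SE topology** — edge (< 5 kb from a TAD boundary) vs non-edge
  placement, TAD grouping by compartment and SE content, loop-contact and
  boundary-crossing statistics, expression fold-changes, and a two-genome
  gene-pair conservation metric.
* **eQTL classification** — promoter (± 2.5 kb of the eGene TSS) vs
  distal, compartment, variant–eGene TAD co-residence vs random TADs, the
  promoter-interaction loop taxonomy (eGene pieQTL / non-eGene pieQTL /
  eQTL-only / not-on-loop), CRE/SE context and local H3K27Ac (±100 bp)
  with Welch tests.
* **GWAS linking** — MAF ≥ 1% and r² ≥ 0.7 LD filtering (inclusive), then
  variant→gene links through loops (`loop_to_body`, `loop_to_tss`), shared
  CREs/SEs, and nearest-gene fallback, with per-locus deduplicated counts.
* **Synthetic data** — a 2 × 10 Mb genome with planted TADs, compartment
  blocks, loops (Poisson contact matrix with power-law decay), SE
  constituent clusters, boosted expression, eQTLs in every topological
  class and GWAS LD blocks, plus a machine-readable truth set the
  generator itself re-verifies with the package's own predicates.

## Worked example

```python
from chromhub import SyntheticConfig, simulate, call_super_enhancers
from chromhub.eqtl import pieqtl_classify, same_tad_analysis
from chromhub.nulls import sample_random_tads

res = simulate(SyntheticConfig(seed=1))
cres, call = call_super_enhancers(res.segments, res.genes, res.case_track,
                                  res.control_track, build=res.build)
print(f"{len(cres)} CREs -> {len(call.regions)} stitched regions -> "
      f"{call.n_se} super-enhancers")

classes = pieqtl_classify(res.eqtls, res.loops, res.genes, build=res.build)
print("pieQTL classes:", classes.value_counts().to_dict())

random_tads = sample_random_tads(res.build, res.tads, n_sets=100, seed=1)
flags, enr = same_tad_analysis(res.eqtls, res.genes, res.tads, random_tads)
print(f"same-TAD proportion: {flags.mean():.3f}  "
      f"(t_{enr.df} = {enr.t:.2f}, p = {enr.p:.2e}, {enr.direction})")
```

prints

```
168 CREs -> 50 stitched regions -> 20 super-enhancers
pieQTL classes: {'not_on_loop': 100, 'egene_pieqtl': 25, 'non_egene_pieqtl': 25, 'eqtl_only': 25}
same-TAD proportion: 0.760  (t_99 = -43.07, p = 6.31e-66, observed_higher)
```

The 50 stitched regions are the 16 planted SE constituent clusters, the 30
isolated typical enhancers and a few promoter-adjacent composites; the
elbow cutoff flags 20 regions, every planted SE among them. The 175
planted eQTLs recover their loop taxonomy exactly (100 of them were
planted off any loop foot: 25 per non-loop class across the promoter,
SE-resident, CRE-resident and not-on-loop groups). The same-TAD proportion
is the planted 0.76, and the negative t against 100 random-TAD sets says
the observed co-residence far exceeds the null.

The same stages are scriptable from the shell:

```bash
chromhub simulate --seed 1 --out bundle/
chromhub call-se --bundle bundle/ --out out/
chromhub eqtl-annotate --bundle bundle/ --out out/ --seed 1
chromhub gwas-link --bundle bundle/ --se-bed out/super_enhancers.bed \
    --cre-bed out/cres.bed --out out/
```

Each stage appends its counts to `out/report.json`.

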