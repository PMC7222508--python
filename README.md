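# clonaltraj

Multi-omic "dynamic alteration" analysis for serially passaged
patient-derived xenograft (PDX) cohorts.

When a PDX tumor is transplanted through successive mouse passages under
continuous drug treatment (here: anti-EGFR cetuximab in a KRAS-mutant
colorectal model), acquired resistance emerges over a handful of
generations. `clonaltraj` implements the analyses that track that
process across a 5-generation × 3-replicate design:

- **Allele-frequency trajectories.** For each exome variant, the
  alternate-allele frequency per generation g1–g5 is the exact fraction
  of alternate alleles over the callable chromosomes of that passage
  (≤ 6 with three diploid mice; missing calls shrink the denominator).
  The **trajectory filter** keeps loci that sweep monotonically
  (non-strict) from f(g1) ≤ 1/3 up to f(g5) ≥ 2/3, or the mirrored
  decrease — the signature of clones expanding or collapsing under
  selection. Comparisons use exact rational arithmetic.
- **Sample geometry.** Classical (Torgerson) multidimensional scaling of
  pairwise Hamming proportions between genotype columns, with a
  silhouette score quantifying how cleanly the resistant passage
  separates in the leading MDS plane.
- **Expression dynamics.** Genes are "expressed" when FPKM > 5 in all
  three replicates of at least one generation; differential expression
  across generations is a fixed-effects one-way ANOVA on
  log2(FPKM + 1) at unadjusted thresholds (P < 0.05, P < 0.001);
  samples are clustered hierarchically on the DEG set; temporal trends
  are Spearman correlations against the passage index. miRNAs run
  through the same machinery.
- **Integration.** Filter-passing loci map to the genes containing them;
  each (locus, gene) pair is tested by additive linear regression of
  log2 expression on allele dosage (eQTL-style, P < 0.01); candidate
  genes intersect an immune gene list; miRNA→target pairs are scored
  for concordant trends.
- **In-vivo efficacy.** Tumor volume V = (L × W²)/2 from caliper
  measurements, and per passage
  T/C (%) = (Tt_i − Tt_0)/(Vc_i − Vc_0) × 100,
  TGI (%) = 100 − T/C,
  with a configurable TGI ≥ 30% convention for the responsive call.
- **Synthetic cohorts.** `clonaltraj.simgen` generates complete cohorts
  (VCF, expression TSVs, BED annotation, miRNA target pairs, immune
  list, growth CSV) with planted sweeps, DEGs, eQTL links, concordant
  miRNA pairs and a responsive-then-resistant growth profile, all
  recorded in truth tables so every stage can be scored for recovery.

## Worked example

`examples/` holds one short script per capability. The core worked
example (`examples/02_trajectory_filter.py`) builds a locus whose
per-generation alternate-allele counts are 0, 1, 2, 2, 4 over six
chromosomes:

```
generation   alt alleles / chromosomes   frequency
        g1   0 / 6                       0.000000
        g2   1 / 6                       0.166667
        g3   2 / 6                       0.333333
        g4   2 / 6                       0.333333
        g5   4 / 6                       0.666667

filter verdict: passes=True, direction=increasing
```

The allele rises from absent to two-thirds of the cohort's chromosomes
with an internal tie — monotonicity is non-strict — so the locus passes
as `increasing`: a candidate resistance allele sweeping through the
tumor. The full pipeline (`examples/06_full_pipeline.py`) prints the
stage-by-stage report of a simulated cohort:

```
variants: 2000 in, 40 passing the trajectory filter
genes: 495 expressed, 33 DEGs, 30 strict DEGs
candidates: 15 loci on 15 genes; 10 immune; 16 concordant miRNA pairs
passage P2: TGI 44.62% (responsive)
passage P3: TGI 43.93% (responsive)
passage P4: TGI -44.04% (resistant)
passage P5: TGI 7.42% (resistant)
```

A negative TGI means treated tumors grew faster than vehicle — the
hallmark of the resistant passages.

## Command line

A thin CLI wraps the library: `clonaltraj simulate | growth | vartraj |
exprdyn | integrate | run`. `clonaltraj run --config run.yaml` executes
the whole pipeline and writes `report.json` plus per-stage TSVs.

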