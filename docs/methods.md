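# Methods

## Study design and data model

The pipeline assumes a serial-passage PDX design: five generations
(g1–g5) with three replicate mice sequenced per generation, 15 samples
in total. A `SampleSheet` assigns every sample to its generation and
replicate and is threaded through all containers (`GenotypeMatrix`,
`ExpressionMatrix`), so all statistics are invariant to the on-disk
sample order. VCF coordinates are 1-based; gene annotation intervals are
0-based half-open, converted exactly once at read time. Diploid GT
fields become alternate-allele dosages 0/1/2 (phase ignored), `./.`
becomes missing; multi-allelic records are split per alternate allele so
dosage is well defined.

## Allele-frequency trajectories and the sweep filter

For locus *l* and generation *g* the tracked frequency is

f(l, g) = (sum of dosages over non-missing samples of g) / (2 × number
of non-missing samples of g).

This is the alternate-allele frequency, deliberately not folded to a
minor-allele frequency: trajectories of interest cross 0.5 (the worked
sweep ends at 2/3). Missing genotypes are excluded from numerator and
denominator rather than imputed; a generation with no callable sample
leaves the trajectory undefined and the locus is excluded from
filtering (with a reported count).

The filter keeps a locus when its five frequencies are monotone
non-decreasing with f(g1) ≤ 1/3 and f(g5) ≥ 2/3 (direction
"increasing"), or monotone non-increasing with the mirrored bounds
("decreasing"). Monotonicity is non-strict: the canonical passing
trajectory contains the internal tie 2/6, 2/6, which forces that
reading. Frequencies are exact `Fraction`s (denominator ≤ 6 here), and
the 1/3 and 2/3 bounds are exact rationals compared with ≤/≥, so grid
points such as 2/6 = 1/3 can never be lost to floating-point rounding.
The filter is verified against a brute-force evaluation of the two rules
over all 7⁵ trajectories on the {0, 1/6, …, 1} grid.

## Genotype distances and classical MDS

Pairwise sample distance is the Hamming proportion: the fraction of
mutually callable loci at which dosages differ (loci missing in either
sample are skipped pairwise; a pair with no mutually callable locus is
an error naming the pair). MDS is classical/Torgerson: double-center the
squared distance matrix, eigendecompose, scale the top-k eigenvectors by
√λ. Axes with non-positive eigenvalues get zero coordinates; the
largest-magnitude entry of each axis is made positive so the embedding
is deterministic. Eigenvalues are returned for scree inspection. The
generation-5 separation score is the silhouette of the declared split on
the first two coordinates (scikit-learn), 0 for coincident points.

## Expression dynamics

Presence: a feature is kept iff some generation has all replicates
strictly above the threshold (default 5 FPKM for genes; miRNAs default
to 1 because the FPKM > 5 convention is gene-specific — both
configurable). ANOVA is the classical fixed-effects decomposition
F = (SSB/df_b)/(SSW/df_w), P from the F(4, 10) upper tail for the full
design, computed on log2(value + 1) by default (the log stabilizes
FPKM variance; a raw mode exists for sensitivity checks). DEG selection
uses strict unadjusted thresholds (P < 0.05 and P < 0.001), sorted by P
with feature-id tiebreaks; no multiple-testing correction is applied, by
design, and users should treat the resulting lists as ranked candidates,
not inference-grade discoveries. Clustering is average-linkage
hierarchical clustering of samples on Euclidean distances of
feature-standardized log values, cut at k = 2; degenerate cuts (all-zero
distances, or fewer clusters than requested) are flagged rather than
hidden. Trends are Spearman correlations of expression against the
generation index, called up/down by sign when the correlation P < 0.05,
"none" otherwise or for constant input.

Degenerate fits: zero within-group variance with unequal means is a
perfect fit; P is reported as the smallest positive double (5e-324) and
flagged, keeping P inside (0, 1] while still passing any α cut.
Exactly-constant input is detected before the sums of squares are
formed, because one-ulp differences between the grand mean and group
means can otherwise fabricate an infinite F from a flat row. The
analogous guard applies to regression residuals at the rounding floor
(relative SS below 1e-20).

## Integration

Locus→gene mapping is positional containment only (a locus inside two
overlapping genes maps to both; strand is ignored; loci in no gene are
dropped with a count). Association is simple linear regression of
log2(expression + 1) on additive dosage over all non-missing samples,
F-test P value; monomorphic loci or pairs with < 3 usable samples are
skipped with a reason. A genotype-as-factor ANOVA mode is available.
Candidates are loci with P < 0.01; the gene list is de-duplicated, so it
is never longer than the locus list. The immune overlap is a plain set
intersection, lexically sorted. miRNA–target concordance classifies both
members' trends; the default mode is "same" (both up or both down), with
an "inverse" mode available because canonical miRNA repression predicts
opposite trends — the same-trend default mirrors how such candidate
lists are reported in practice, and both modes are exposed rather than
guessing intent.

## Efficacy metrics

V = (L × W²)/2; T/C = (Tt_i − Tt_0)/(Vc_i − Vc_0) × 100 on group means
(unpaired cohorts of three animals; baseline is the first treatment
day); TGI = 100 − T/C, so the two are exact complements by
construction — in IEEE doubles the literal sum T/C + TGI can drift by
one ulp, which is a representation artifact, not a property of the
metric. A flat vehicle arm (Vc_i = Vc_0) leaves both undefined and is an
error. SD uses the n − 1 denominator; a single-animal group reports
SD 0 with n = 1 as the flag. The responsive/resistant call uses a
configurable TGI ≥ 30% convention (boundary counts as responsive); the
threshold is a community default, not a measured quantity.

## Synthetic cohorts

The generator reproduces the study conditions: 5 × 3 design; neutral
loci with constant latent frequency drawn uniform(0, 1); selected loci
with monotone latent paths on the 6-chromosome grid from ≤ 1/3 to ≥ 2/3
(or mirrored) — the grid matches the granularity of observed frequencies
in a three-mouse passage. `noise_sd` is the log2-scale expression noise
SD (default 0.1) and doubles as the sampling switch for genotypes: when
positive, each mouse's dosage is Binomial(2, latent frequency); at zero,
per-generation counts are allocated deterministically so trajectories
are exact and constant loci can never pass the filter. Expression is
log2(FPKM + 1) = baseline + planted effects + Gaussian noise, baselines
log-normal around 2⁵ FPKM; planted DEGs get a monotone gradient of
`deg_effect_sd_units` noise-SDs **per generation step** (at noise 0 a
reference SD of 0.5 log2-units applies) — the per-step convention is
what makes a "2 SD" effect recoverable at P < 0.001 with df (4, 10);
planted eQTL genes add `eqtl_slope` log2-units per alternate allele of
their linked selected locus. Genes are tiled non-overlapping on one
synthetic chromosome and a BED annotation is emitted; eQTL loci are
placed inside their linked gene, and other loci are kept out of eQTL
and DEG gene intervals so the candidate truth set is exact (a second
sweeping locus inside such a gene would be a real, but unplanted,
association). Growth curves put vehicle animals on exponential paths
from baselines uniform in [100, 300] mm³ to a common endpoint volume;
treatment endpoints are constructed so group-mean TGI equals the
configured profile (default 44.62, 43.93, −44.04, 7.42 for P2–P5)
exactly at noise 0, with multiplicative lognormal measurement noise
otherwise. All randomness derives from one mandatory seed through named
independent streams.

What the generator does **not** emulate: linkage disequilibrium and
clonal phylogenies (loci are independent), mapping/quantification noise
structure of real FPKM, batch effects, copy-number variation, germline
vs somatic status, and realistic miRNA–target regulatory coupling.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted signal under the stated noise model — not
performance on real tumor data.

## Default problem sizes

Simulated cohorts default to 2,000 loci, 500 genes and 50 miRNAs, which
keeps a full pipeline run under a second while leaving every planted
class (40 sweeping loci, 30 DEGs, 15 eQTL links, 16 concordant pairs,
10 immune candidates) large enough to score recall and precision.
Paper-scale inputs (10⁶ loci) are supported by the same code paths; only
the per-pair Hamming loop is quadratic in samples, which is trivial at
n = 15.

## Known limitations

- The trajectory filter is a deterministic rule, not a test: it has no
  error model, and with binomial sampling noise a genuinely selected
  locus can fail monotonicity (recall < 1 away from noise 0).
- Raw-P DEG selection inflates the family-wise error rate by design
  fidelity; a correction layer is deliberately out of scope.
- Association uses all 15 samples jointly and ignores the generation
  structure (no kinship/relatedness correction), so sweeping loci and
  generation-dependent genes can associate without a causal link; the
  generator avoids planting such coincidences, real data will not.
- The efficacy metrics use group means of three animals; no
  mixed-effects growth modeling is attempted.
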