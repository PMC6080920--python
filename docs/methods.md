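# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `mammomics`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and annotation model

All coordinates are 0-based half-open (BED convention) internally; the
per-CpG count table is 1-based on disk and converted at the parser
boundary. Overlap between two intervals means ≥ 1 shared base pair; under
half-open semantics, adjacent intervals ([100,200) and [200,300)) do not
overlap. The package is assembly-agnostic: coordinates are opaque labels,
no liftover is performed, and the synthetic generator uses a single
coordinate space for every layer.

A gene's TSS is its strand-aware 5′ end (body start on `+`, body end − 1 on
`-`). The promoter is the `upstream` bp window ending at the TSS (default
2,500 bp); the "gene window" used for peak and DMC assignment is the gene
body extended 2,500 bp upstream of the TSS only — not both ends — matching
the convention that promoter methylation lies upstream of the TSS.

## Differential methylation

Replicate counts are pooled within each cell type and each CpG is tested
with a two-sided Fisher exact test on the 2×2 (cell type × methylated /
unmethylated) table; BH adjustment runs over all testable sites (covered in
both groups). Thresholds: |Δβ| ≥ 0.15 (inclusive) and adjusted p < 0.01
(strict). Pooling assumes replicates are exchangeable draws of the same
underlying methylation state; the test is exact for binomial counts but
anticonservative under strong between-replicate overdispersion (see the
generator section — this constrains how much dispersion the emulation can
plant while the pipeline stays calibrated).

Feature annotation uses precedence promoter > exon > intron > intergenic
for the genic label and island > shore (≤ 2 kb from an island edge) > shelf
(2–4 kb) > open sea for the CpG-island context; precedence resolves sites
covered by several classes (e.g. a promoter overlapping another gene's
exon). Sites on chromosomes absent from the annotation fall back to
intergenic/open-sea and are counted in a warning.

The permutation null draws |DMC| sites uniformly without replacement from
the background CpG set, 1,000 times by default, unconstrained by chromosome
of origin. The tail p-value is computed from `norm.logsf` / `norm.logcdf`
in natural-log space; `log_p` is always finite and `p` is floored at the
smallest positive double (≈ 5e−324) so downstream code never sees an exact
zero. With a degenerate null (permutation SD = 0), p is 1 at the mean and
the log-space floor otherwise, with a flag. Fold changes below 1 are
reported as negative reciprocals (+fold = enrichment, −fold = depletion),
so |fold| ≥ 1 always.

## Open chromatin

A peak is shared iff it overlaps ≥ 1 bp of any peak from the other cell
type (symmetric by construction); otherwise it is lineage-restricted. No
merging of same-type peaks is performed before counting. Peaks overlapping
several gene windows count toward every such gene — membership, not a
nearest-gene tie-break — and peaks assigned to no gene are retained under a
null key so totals are conserved.

## Motif scanning and TFBS enrichment

PWM matrices are probabilities per position over ACGT; count matrices read
from JASPAR-style text are converted with a +0.25 pseudocount per cell
(avoiding −∞ log-odds). Scores are Σ log2(p_base/background_base) per
window, both strands, reverse-strand hits reported on forward coordinates.
The default hit threshold is 80% of a motif's maximum achievable score,
overridable per motif; windows containing any non-ACGT base score −∞, and
regions more than 50% ambiguous are skipped.

Enrichment between target windows (300 bp around hypomethylated DMCs) and
background windows (an equal-size seeded draw of non-DMC CpGs) is
log2(pct_target/pct_background) on the percentage of windows containing
≥ 1 hit, with an upper hypergeometric tail p (drawing the target-set size
from the combined pool, hit-bearing windows as successes) and BH q across
motifs. When the background percentage is zero the score is reported as an
infinity sentinel with a flag; motifs hitting neither set are dropped with
a warning.

Proximal-gene integration keeps hits within 250 bp (gap between nearest
ends; 0 when overlapping) of any ATAC-seq peak, shared or restricted, maps
them to genes via the gene-window rule, and restricts to protein-coding
genes present in the expression table. Per motif it reports the gene list
with significance flags (expression q < 0.05) and the mean RNA log2 fold
change; per gene, the number of distinct motifs with a proximal
hypomethylated TFBS.

## Proteome harmonization

The ≥ 2-peptide filter runs first. Records with LFQ present in every
sample keep LFQ verbatim. All other records use iBAQ rescaled per sample
by median(LFQ)/median(iBAQ) computed over the LFQ-complete records —
a median-ratio interpretation of "median-adjusted", chosen as the standard
robust scale anchor. Intensities still missing (both measures absent) are
floored to 1; with LFQ intensities in the 10^5–10^7 range this makes
single-lineage detection appear as |log2 FC| > 15, a deliberate sentinel
behaviour rather than an artefact. Technical replicates are assumed
already averaged upstream on the raw intensity scale.

The differential test is Welch's t (unequal variances) on log2 abundance —
at n = 2 per group variance equality cannot be assessed, so the
unequal-variance form is the safer default. Detection-only proteins are
exempt from the test and flagged differential. Both raw p and BH q are
emitted; the differential-set definition uses raw p < 0.05 with ≥ 2-fold
change. Row z-scores use the sample SD (n − 1); constant rows are emitted
as zeros with a flag.

Spearman correlations (average-rank ties) between RNA and protein log2
fold changes are computed globally and within peptide-count quartiles
(boundaries at the empirical quartiles, ties to the lower bin), peptide
count serving as a proxy for protein abundance/measurement quality.

## Relationship states and layer association

The gene universe is the intersection of genes observed in all four
layers; excluded genes are counted. Ternary rules: chromatin and
methylation are up in the cell type with the strictly greater count (peaks;
hypomethylated DMCs — "up" meaning the more active, less methylated
configuration); RNA and protein are up when the linear-scale ratio strictly
exceeds 2. Ties and sub-threshold differences are neutral. Two fold-change
conventions coexist and are kept distinct: the state-map rule above
(> 2-fold both for RNA and protein) and the tabular reporting criteria
(RNA q < 0.05; protein ≥ 2-fold with p < 0.05; lineage-restricted peaks);
a config switch selects which one a report uses.

Association between layers is fitted per ordered layer pair and per
direction d: predictor x = [predictor layer is up-d], outcome restricted to
genes whose outcome layer is d or neutral, a two-category multinomial logit
against the all-neutral reference. With a single binary predictor the MLE
equals the 2×2 closed form ln[(n₁₁/n₁₀)/(n₀₁/n₀₀)]; the Haldane–Anscombe
+0.5 correction is applied to all four cells when any is zero (flagged),
Wald SE = √Σ1/n, two-sided normal p. Joint multi-predictor models are
deliberately not fitted: the pairwise design reproduces the reported
chromatin→RNA, chromatin→protein and RNA→protein associations without
inventing a joint specification. Percentages in reports round half away
from zero to integers.

The label-swap symmetry implemented (and tested) is equivariance: swapping
basal/luminal everywhere maps the up-basal fit onto the up-luminal fit and
vice versa. For the signed fold changes of feature enrichment, swapping
enriched and depleted site sets flips the sign.

## Limiting-dilution analysis

Single-hit model: P(positive | dose d) = 1 − e^(−f·d). The MLE maximizes
the binomial log-likelihood over θ = ln f (bounded scalar optimization,
tolerance 1e−12, bounds f ∈ [1e−12, ~1]); `log1p(-exp(-λ))` keeps the
likelihood stable at small doses. The 95% CI is the profile likelihood at
the χ²₁ 95% cutoff (3.841), found by bracketed root-finding on each side —
more robust than a Wald interval on ln f when the estimate sits near a data
boundary. All-positive or all-negative experiments return one-sided
intervals with flags. Two groups are compared by a likelihood-ratio test
(separate vs. pooled fits) against χ²₁. Goodness-of-fit extras and
frailty/overdispersion variants are out of scope.

## Synthetic study generator

The generator emulates the structure of a two-lineage mammary multi-omics
study so that every pipeline stage has a recorded ground truth: three
chromosomes of 3.2 Mb; 360 genes (2–20 kb, 3–8 exons, both strands, 90%
protein-coding); CpG islands at 30% of promoters plus random islands;
20,000 background CpGs (40% inside islands); 2 bisulfite and 2 proteome
replicates and 4 expression replicates per cell type; ~1,200 ATAC peaks
per type; limiting-dilution schedules of 500/2,000/10,000 cells × 12 fat
pads. These sizes keep a full run in tens of seconds while leaving every
statistic non-trivially powered.

Key planted parameters (all recorded in `ground_truth.json`):

- **DMCs** at rate 0.05 of CpGs, with a group-β shift of 0.3 and direction
  hypo-in-basal with probability 0.55. Promoter placement is stratified so
  the promoter overlap count equals `promoter_enrichment_fold` (default 3)
  times the uniform expectation — the permutation fold-change estimand is
  then exactly 3 by construction.
- **Methylation counts** are beta-binomial with dispersion ρ = 0.01 around
  the group β, coverage ~ Poisson(40) + 5 per replicate. ρ was chosen as
  the largest "modest overdispersion" compatible with the pooled Fisher
  test remaining calibrated: the suite checks that a null generator
  (dmc_rate = 0) yields ≤ 0.5% spurious calls, and at ρ = 0.05 that check
  fails by a wide margin (pooled exact tests assume binomial sampling).
- **Motifs**: three sharp 10-bp PWMs (0.91/0.03 columns) whose consensus is
  embedded into the genome around hypomethylated-in-basal DMCs at rates
  0.6/0.5/0.4 and around a recorded draw of background CpGs at rate 0.2.
  The background draw excludes CpGs within 450 bp of any target DMC;
  without that exclusion, island CpG clustering lets plants leak between
  the overlapping 300-bp windows of the two sets and biases the recovered
  contrast. Window-level rate recovery (±0.3 of log2 3) is asserted on
  independent windows; on the bundle, where target windows overlap each
  other inside islands, region-level percentages sit above the per-window
  plant rates and only clear, significant enrichment is asserted.
- **Layer dependence**: per-gene ternary directions are drawn with
  chromatin up-rates 0.2/0.2 and base RNA/protein up-rates 0.15/0.15, with
  multinomial odds multiplied by exp(β) when the upstream layer points the
  same way (β = 1.5 chromatin→RNA, 2.0 RNA→protein). This makes β exactly
  the estimand of the pairwise association fit. Peak counts, expression
  fold changes (|log2 FC| > 1.2 for "up" genes, |log2 FC| < 0.9 for
  neutral) and protein intensities are then realized consistently with
  those directions. Methylation directions are left independent.
- **Proteome**: LFQ missing at rate 0.15 with iBAQ retained (iBAQ = LFQ
  divided by a per-protein factor ~ U(5,50), standing in for the
  theoretical peptide count); 5% of detected proteins are zeroed in one
  lineage to create detection-only records; peptide counts 2 + NB(2,0.15).
- **LDA**: Bernoulli(1 − e^(−f·d)) outcomes at f = 1/2,000 (vehicle) and
  1/8,000 (treated).

A separate lightweight generator draws RNA/protein fold-change pairs with
per-peptide-count-quantile Spearman correlations (0.2/0.35/0.45/0.6),
using the bivariate-normal relation ρ_pearson = 2 sin(π ρ_spearman/6).

Everything is deterministic given the seed (one `numpy` Generator, fixed
operation order); the suite asserts byte-identical bundles across repeated
runs.

### What the generator does not emulate

Read-level data (FASTQ, alignments), chromosome-scale CpG density and
genuine CpG-island biology, GC/repeat structure of real genomes, batch and
array normalization artefacts in expression data, peptide-level missingness
structure in proteomics, and between-replicate biological variance beyond
the planted dispersions. Passing tests therefore demonstrate correctness
of the statistics and the pipeline plumbing under a faithful structural
emulation — not performance claims on real RRBS/ATAC/MS data.

## Problem sizes used by the default runs

The test suite runs the generator at 120 genes / 4,000 CpGs / 400 peaks
per type (one shared session bundle), and the acceptance script at the full
default conditions above. Property checks use 200 replicates at n = 3,000
genes for association recovery, 500 replicates for limiting-dilution
interval coverage, and dense-grid or enumeration oracles at small n for
exactness checks — sizes chosen so each statistic is tested at meaningful
power.

## Known limitations

- The pooled Fisher DMC test ignores replicate structure; with more than
  ~2 replicates per group or strong biological variability, a
  dispersion-aware test (e.g. beta-binomial regression) would be
  preferable.
- The permutation null is unconstrained by chromosome or CpG density, so
  strongly clustered backgrounds can make the normal approximation of the
  permutation distribution slightly heavy in the tails at small |DMC|.
- PWM hit thresholds (80% of maximum score) are a pragmatic default;
  motif-specific calibrated thresholds would change absolute hit counts,
  though the target/background contrast is robust to the shared threshold.
- The LDA model fixes the single-hit assumption; heterogeneity in
  repopulating-unit activity (frailty) would widen true intervals relative
  to the profile CI.
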