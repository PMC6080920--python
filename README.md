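# mammomics

Integrative chromatin–DNA–RNA–protein analysis of basal and luminal mammary
epithelial cells.

The adult mammary epithelium contains two principal lineages — basal
(myoepithelial, CD24^lo CD49f^hi) and luminal (CD24^hi CD49f^lo) — each
maintained by its own stem/progenitor activity. `mammomics` links four
successive layers of gene regulation measured on these two cell types into a
single per-gene picture:

1. **DNA methylation** — per-CpG bisulfite counts (RRBS-style), compared
   between lineages to call differentially methylated cytosines (DMCs),
2. **open chromatin** — ATAC-seq peak sets per lineage, classified as
   lineage-restricted or shared,
3. **RNA abundance** — per-gene expression with log2 fold changes and
   q-values,
4. **protein abundance** — label-free shotgun proteomics (MaxQuant-style
   LFQ/iBAQ intensities).

It is written for computational biologists who want a tested, reusable,
fully scriptable version of this style of multi-omics integration, with a
synthetic-study generator so every stage can be exercised and validated
without any external download.

## The statistics at the core

**DMC calling.** For each CpG, replicate-pooled methylated/unmethylated
counts form a 2×2 table tested by Fisher's exact test; p-values are
Benjamini–Hochberg adjusted. A DMC requires |Δβ| ≥ 0.15 (β = methylated
fraction; Δβ = β_basal − β_luminal) and adjusted p < 0.01. The lineage with
the lower β is *hypomethylated* there.

**Permutation feature enrichment.** For each genomic feature class
(promoter / exon / intron / intergenic; CpG island / shore / shelf / open
sea), the observed DMC overlap count is compared with 1,000 draws of
equally many sites from the background CpG set. With permutation mean μ and
SD σ, the p-value is the normal tail Φ̄((obs − μ)/σ) (lower tail when obs
< μ), evaluated in natural-log space so it never underflows to zero. The
fold change is obs/μ, reported as its negative reciprocal when below 1, so
+2 means twofold enrichment and −2 twofold depletion.

**TFBS enrichment.** PWMs are scanned over both strands of 300-bp windows
centred on hypomethylated DMCs (log2-odds scores against the background
base composition). The enrichment score is
log2(% target windows with a hit / % background windows with a hit), with a
hypergeometric tail p-value and BH q-values across motifs.

**Proteome harmonization.** Protein groups with < 2 peptides are dropped.
LFQ intensities are used when present in every sample; otherwise iBAQ
values are rescaled per sample by median(LFQ)/median(iBAQ) over
LFQ-complete records. Remaining missing values become 1, so proteins
detected in only one lineage show |log2 FC| > 15. Differential proteins
require ≥ 2-fold change with Welch-t p < 0.05, or detection in one lineage
only.

**Relationship states.** Every gene observed in all four layers gets a
ternary label per layer (up-in-basal / up-in-luminal / neutral): strictly
more peaks, strictly more hypomethylated DMCs, or a > 2-fold RNA/protein
ratio. Associations between layers are multinomial logits of each "up"
direction against the all-neutral reference; with one binary predictor the
maximum-likelihood log-odds equals the contingency closed form
ln[(n₁₁/n₁₀)/(n₀₁/n₀₀)] (Haldane–Anscombe +0.5 when a cell is empty), with
Wald standard errors.

**Limiting-dilution analysis.** Transplant take rates follow the single-hit
Poisson model P(outgrowth | dose d) = 1 − e^(−f·d), where f is the mammary
repopulating unit (MRU) frequency. f is estimated by maximum likelihood on
ln f, with a 95% profile-likelihood confidence interval (χ²₁ cutoff) and a
likelihood-ratio test for comparing two groups.

## Worked example

Generate a small synthetic study and run the methylome and stem-cell
stages:

```python
from pathlib import Path
from mammomics.synthetic import SimulationConfig, simulate_study
from mammomics import genome_io, methylome
from mammomics.lda import read_lda_table, fit_single_hit, compare_groups

outdir = Path("bundle")
cfg = SimulationConfig(seed=7, n_genes=120, n_cpg_background=4000,
                       n_peaks=400, chrom_length=1_500_000)
simulate_study(cfg, outdir)

samples, sites = genome_io.read_beta_table(outdir / "methylation.tsv")
groups = ["basal" if s.startswith("basal") else "luminal" for s in samples]
dmcs = methylome.call_dmcs(sites, groups, delta_min=0.15, q_max=0.01)
print(f"{len(dmcs)} DMCs called from {len(sites)} CpGs")

ann = genome_io.load_annotation(outdir / "genes.tsv", outdir / "cgi.bed")
enr = methylome.permutation_feature_enrichment(
    [(d.site.chrom, d.site.pos) for d in dmcs],
    [(s.chrom, s.pos) for s in sites],
    ann, n_perm=1000, seed=7,
)
for e in enr:
    if e.feature in ("promoter", "open_sea"):
        print(f"{e.feature}: observed={e.observed} expected={e.expected_mean:.1f} "
              f"fold={e.fold_change:+.2f} ln(p)={e.log_p:.1f}")

exps = read_lda_table(outdir / "lda.tsv")
fit = fit_single_hit(exps["vehicle"])
print(f"vehicle MRU frequency: 1 in {fit.one_in:.0f} "
      f"(95% CI 1 in {1/fit.ci_low:.0f} - 1 in {1/fit.ci_high:.0f})")
print(f"vehicle vs treated: p = {compare_groups(exps['vehicle'], exps['treated'])['p']:.4f}")
```

Output:

```
161 DMCs called from 4000 CpGs
promoter: observed=78 expected=25.6 fold=+3.05 ln(p)=-73.3
open_sea: observed=61 expected=81.8 fold=-1.34 ln(p)=-8.0
vehicle MRU frequency: 1 in 1943 (95% CI 1 in 3541 - 1 in 1110)
vehicle vs treated: p = 0.0033
```

Reading this: 161 CpGs pass the |Δβ| ≥ 0.15, q < 0.01 thresholds. DMCs land
in promoters about three times as often as a random draw of CpGs would
(the generator plants exactly that bias, fold +3.05), and are depleted from
open-sea regions. The limiting-dilution fit estimates one repopulating unit
per ~1,900 cells in the vehicle group (truth: 1 in 2,000), and the
likelihood-ratio test flags the 4-fold lower frequency planted in the
treated group.

The same pipeline is available from the shell:

```sh
mammomics simulate --seed 7 --outdir bundle
mammomics all --bundle bundle --outdir results --seed 7
```

which writes, per stage: `dmcs.tsv`, `dmc_beta_top_variance.tsv`,
`feature_enrichment.tsv`, `peaks_classified.bed`, `gene_peak_counts.tsv`,
`motif_enrichment.tsv`, `proteins_differential.tsv`, `protein_zscores.tsv`,
`rna_protein_correlation.json`, `states.tsv`, `state_frequencies.tsv`,
`associations.tsv`, `marker_report.json`, `lda_fits.json`, plus a resolved
config and run log.

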