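# wacna

Weighted analyte correlation network analysis: joint module detection across
transcriptomic and metabolomic abundance matrices, together with the upstream
untargeted-metabolomics feature QC/statistics stage and a synthetic-cohort
generator with planted, verifiable module structure.

## What it does

The pipeline integrates one transcript matrix (genes × samples) with one or
more metabolite feature matrices (m/z–retention-time features × samples,
peak areas with missing values and pooled-QC replicate columns):

1. **QC filtering** — remove features with pooled-QC relative standard
   deviation > 20% or detected in < 70% of biological samples (two
   independent criteria; a conjunctive mode is available).
2. **Imputation** — analyte-space k-nearest-neighbour imputation (k = 3).
3. **Differential statistics** — two-sided Wilcoxon–Mann–Whitney tests
   (exact for small tie-free groups), Benjamini–Hochberg FDR, signed fold
   changes with percentile-bootstrap 95% confidence limits, and per-class
   rollups of significant features.
4. **Network construction** — per-dataset top-20%-by-variance selection,
   row concatenation with per-analyte z-scaling, soft-thresholded Pearson
   adjacency (`|cor|^beta`, unsigned by default; beta fixed or chosen by the
   scale-free-fit criterion), topological overlap.
5. **Module detection** — average-linkage clustering of `1 − TOM` with an
   adaptive branch cut, minimum module size, eigengene-correlation module
   merging and a module-membership (kME) purge; modules named by the
   conventional colour sequence, unassigned analytes grey.
6. **Module–design association** — module eigengenes (first principal
   component, sign-oriented), correlation with the diet/exercise design
   indicators, two-factor interaction test, BH across modules, and flagging
   of modules of interest.
7. **Enrichment / evaluation** — hypergeometric over-representation against
   GMT gene sets, and recovery scoring (adjusted Rand index, purity,
   eigengene fidelity, background rejection) against simulated ground truth.

The `simulate` module generates paired cohorts with a 2×2 diet × exercise
design, lognormal intensities, pooled-QC technical replicates,
detection-limit plus random missingness, and latent co-regulated analyte
blocks spanning all datasets — so every stage is testable without any
external download.

## Command-line usage

```sh
# generate a synthetic cohort (TSV matrices + metadata + ground-truth sidecar)
wacna simulate --out data/ --seed 7

# full pipeline from a YAML config
wacna run --config pipeline.yaml --seed 7 --out results/

# individual stages
wacna qc       --matrix data/metabolome_pos.tsv --tag metabolome_pos \
               --metadata data/metadata.tsv --out qc/
wacna impute   --matrix qc/metabolome_pos.filtered.tsv --tag metabolome_pos \
               --k 3 --out mp.imputed.tsv
wacna diffstat --matrix mp.imputed.tsv --tag metabolome_pos \
               --metadata data/metadata.tsv --factor diet \
               --group-a CON --group-b HFD --n-boot 2000 --seed 7 \
               --out diff.tsv
wacna network  --matrix transcriptome=data/transcriptome.tsv \
               --matrix metabolome_pos=mp.imputed.tsv \
               --metadata data/metadata.tsv --beta auto --out net/
wacna associate --combined net/combined_matrix.tsv \
               --partition net/module_partition.tsv \
               --metadata data/metadata.tsv --out assoc/
wacna enrich   --partition net/module_partition.tsv --module turquoise \
               --gmt sets.gmt --out enrichment.tsv
wacna evaluate --truth data/ground_truth.tsv \
               --partition net/module_partition.tsv --out recovery.json
```

A pipeline config lists input paths and stage parameters; every run writes a
`resolved_config.yaml` and a `manifest.json` of artifact SHA-256 checksums
next to its outputs, and replaying a resolved config reproduces the
checksums bit-identically.

```yaml
# pipeline.yaml
matrices:
  transcriptome: data/transcriptome.tsv
  metabolome_pos: data/metabolome_pos.tsv
  metabolome_neg: data/metabolome_neg.tsv
metadata: data/metadata.tsv
out_dir: results
seed: 7
beta: 6            # or "auto" for the scale-free criterion
min_module_size: 20
ground_truth: data/ground_truth.tsv   # optional: enables recovery scoring
```

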