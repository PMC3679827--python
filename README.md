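# hybridexpress

Analysis pipeline for transcript-level inheritance in F1 interspecific
hybrids from bulk RNA-seq read counts. Given a contig × sample count matrix
for two parental accessions (A, P) and their F1 offspring, plus a site-level
pileup table with strand-resolved allele depths (dp4), the package:

- normalizes libraries with median-of-ratios size factors and estimates
  per-contig negative-binomial dispersions (method-of-moments gene-wise
  estimates, a robust `a1/m + a0` mean–dispersion trend, conservative
  max-sharing);
- tests pairwise differential accumulation (A vs P, A vs F1, P vs F1) with a
  conditional NB exact test on group count sums, Benjamini–Hochberg adjusted
  per comparison (default q < 0.01);
- fits the midparent additivity model (OLS of mean F1 on midparent counts,
  single-pass Cook's D > 1 pruning, 99% new-observation prediction bands) and
  labels non-additive contigs;
- calls transgressive contigs (significant vs both parents, F1 mean outside
  the parental range) and high-variance contigs (CV of log F1 counts > 2);
- discovers fixed inter-parental SNPs from parental pileups (site quality
  >= 80, per-sample depth >= 5, one allele per accession, accessions differ),
  counts parental alleles in F1 libraries with a one-strand artifact filter,
  tests per-SNP allelic bias, aggregates to contigs, and summarizes
  cis/trans overlap with the parental comparison;
- runs everything on the full sample set and a reduced set (outlier samples
  dropped via the sample sheet) and merges flags with per-flag provenance
  (BOTH / FULL / REDUCED) into one classification table;
- ships a synthetic-data generator (`hybridexpress.synthetic_data`) that
  plants parental differences, cis and trans effects, transgressive and
  high-variance contigs, fixed SNPs, filter-violating decoy sites and
  one-strand artifacts with a full ground-truth table, so every stage is
  testable at desk scale.

## CLI

Simulate a dataset with known ground truth:

```sh
hybridexpress simulate --out-dir sim --seed 1 --n-contigs 2000
# writes counts.tsv, samples.tsv, pileup.tsv, truth.tsv, truth_sites.tsv
```

Run the full + reduced analyses end to end:

```sh
hybridexpress run --counts sim/counts.tsv --samples sim/samples.tsv \
    --pileup sim/pileup.tsv --out results
# writes per-comparison da_*.tsv, nonadditive_*.tsv, bias_by_snp_*.tsv,
# bias_by_contig_*.tsv, outlier_screen.tsv, classification.tsv, summary.txt
```

Options: `--q` (FDR threshold, default 0.01), `--ci` (prediction level,
default 0.99), `--cv-threshold` (default 2), `--cv-formula`
(`lognormal_standard` | `literal`), `--min-qual` (default 80), `--min-depth`
(default 5), `--no-reduced`. A YAML file with the same keys can be passed via
`--config`.

Summarize a written classification table:

```sh
hybridexpress report results/classification.tsv
```

## File formats

All inputs and outputs are TSV with a header row:

- **count matrix** — `contig_id` column, then one integer column per sample
  (optional `length` column);
- **sample sheet** — `sample_id`, `group` (one of `A`, `P`, `F1`),
  `excluded_in_reduced` (`true`/`false`);
- **pileup table** — `contig  pos  ref  alt  qual`, then four columns per
  sample (`<sample>_rf`, `_rr`, `_af`, `_ar`: ref/alt depth on forward and
  reverse strands), samples in sample-sheet order; positions 1-based;
- **classification table** — per-contig flags encoded as ASCII tokens
  (documented in the file's `#` header) with per-flag provenance columns.

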