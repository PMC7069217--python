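# mtcn

Relative mitochondrial DNA copy-number estimation and cohort statistics,
with a synthetic three-generation cohort generator so the whole pipeline is
testable without external data.

The package covers two quantification routes and the statistical layer that
consumes them:

- **qPCR (ΔΔCT)** — run-level QC (NTC and sample CT thresholds),
  plate-referenced ΔΔCT against a constant reference sample, linear
  correction for CT-threshold / batch / DNA-concentration effects with a
  sequential variance decomposition, and rank-based inverse-normal scoring.
- **WGS coverage ratio** — SAM-flag-filtered per-base depth, mean-coverage
  ratio of mtDNA over an autosomal reference region, cohort normalization.
- **Population-genetic checks** — group-private variant detection, an
  equal-weight haploid genetic relatedness matrix (observed p(1−p)
  standardization, every SNP contributing equally), PCA, and one-vs-rest
  haplogroup association with copy number.
- **Cohort statistics** — 17-item PCL-C scoring with an inclusive cutoff,
  OLS group/age/sex models with optional interactions, Fisher exact
  enrichment with exact two-sided p, blood-count screens with Bonferroni
  control, hierarchical clustering, parent–child and maternal-lineage
  inheritance models, and minimal-detectable-effect (Cohen's f) power
  computation via a noncentral-F root solve.
- **Synthetic cohort** — pedigree-structured participants, latent
  log-normal copy numbers with configurable group/age/sex/maternal-
  transmission effects, qPCR plates with controlled effect-variance shares,
  Poisson depth profiles, haplogroup-structured haploid genotypes with
  exact private-variant counts, PCL-C responses and blood counts.

## Command-line interface

All functionality is behind one entry point:

```sh
mtcn simulate --seed 1 --out sim/                 # synthetic raw data
mtcn qpcr --plates sim/plates.csv --samples sim/participants.csv --out cn.csv
mtcn wgscn --depth depth.tsv --mt-name MT --nuc-name chr20 --out cov.csv
mtcn popgen --vcf sim/genotypes.vcf --haplogroups sim/haplogroups.csv \
            --cn cn.csv --pcs 10 --out popgen/
mtcn assoc --cn cn.csv --samples sim/participants.csv \
           --pclc sim/pclc.csv --blood sim/blood.csv --out assoc/
mtcn run --seed 1 --out run/                      # everything end to end
```

Configuration is a YAML file (`--config`) of `CohortConfig` fields with
`--set key=value` overrides; `--seed` wins over the file. Identical
config+seed produces byte-identical outputs. Exit codes: 0 success, 1 user
error, 2 internal error.

## File formats

Plate tables, participant/pedigree tables, haplogroup labels, PCL-C items
and blood counts are plain CSV; per-base depth is TSV (`chrom`, 1-based
`pos`, `depth`, optionally prefixed by `sample_id`); genotypes are
uncompressed haploid VCF (read via pysam); minimal SAM text is supported
for depth accumulation. Coordinates are 1-based inclusive everywhere at
the interfaces.

## Notes and limitations

- Quantification is relative: no amplification-efficiency modelling, no
  absolute copies per cell.
- The depth accumulator counts a read across its whole aligned span (no
  CIGAR gap handling in the minimal text reader).
- Association models are plain OLS; relatedness between participants is
  reported but not modelled.
- Haplogroup assignment is consumed as input labels, never computed.
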