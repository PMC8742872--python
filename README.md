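# cageshift

Analysis toolkit for CAGE (Cap Analysis of Gene Expression) promoter usage
between two inbred strains and their F1 hybrids:

- **CTSS extraction** — unique R1 5' ends from SAM/BAM (MAPQ-255 unique
  mappers, primary, non-duplicate), with a cross-sample support filter
  (>= 1 read in >= 3 samples).
- **Tag clustering** — single-linkage merge of CTSSs within 20 bp, TPM
  normalisation, the 1-TPM-in-one-sample filter, and grouping of clusters
  within 100 bp into promoter regions.
- **Annotation** — strand-aware assignment of promoters to gene regions
  (longest transcript + 1 kb upstream), P1/P2/... ranking by mean TPM,
  TSS-distance classes (exact / within 100 bp / within 1 kb / unannotated),
  and CpG-island / TATA-box (TATAWAWR) architecture classes.
- **Alternative promoter usage** — two-group negative-binomial Wald test per
  promoter (median-of-ratios size factors, moment dispersion, BH adjustment),
  the >= 20 % activity gate, and the opposite-direction rule requiring the P1
  promoter in the evidence pair.
- **Promoter shifts** — count-weighted two-sample Kolmogorov–Smirnov statistic
  per tag cluster between strains, significant when D > 0.3 and D exceeds the
  large-sample critical value at alpha = 0.05.
- **Allelic imbalance** — coverage/variability filters (>= 10 reads in all 12
  parental replicates, variable between parents, >= 10 reads in >= 9/12 F1s),
  pooled exact binomial test at p0 = 1/2, promoter-class comparison (Fisher +
  Mann–Whitney), and the RI-strain genotype–phenotype Mann–Whitney
  association.
- **Pseudo-genome construction** — SNV substitution into the reference
  (indels skipped to preserve coordinates) for allele-aware mapping setups.
- **Synthetic data** — a fully self-contained simulator (genome, GTF, CpG
  BED, CTSS matrix, optional SAM reads, F1 VCF, RI tables) with planted
  alternative-usage genes, TSS shifts, allelic imbalance and phenotype
  effects, recorded in a truth object for parameter-recovery testing.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: the Insr worked
example (346 / 414 bp upstream distances), brute-force clustering and KS
oracles, type-I-error calibration of both tests, planted-effect recovery on
the simulator, and conservation invariants.

## Command line

```bash
# generate a synthetic fixture set with planted effects
cageshift simulate --seed 1 --outdir fixtures/

# per-sample CTSS extraction and merging
cageshift ctss --bam s1.bam --sample s1 --out s1.ctss.tsv
cageshift ctss-merge *.ctss.tsv --samplesheet samples.tsv --min-samples 3 --out ctss.matrix.tsv

# clustering and annotation
cageshift cluster --ctss ctss.matrix.tsv --gap 20 --promoter-gap 100 --min-tpm 1 \
    --out clusters.tsv --bed clusters.bed
cageshift annotate --ctss ctss.matrix.tsv --gtf genes.gtf --cpg cpg.bed \
    --fasta genome.fa --out promoters.annotated.tsv

# strain comparisons
cageshift altprom --ctss ctss.matrix.tsv --samplesheet samples.tsv --gtf genes.gtf --out alt_usage.tsv
cageshift shift --ctss ctss.matrix.tsv --samplesheet samples.tsv --group-a A --group-b B --out shifts.tsv
cageshift assoc --genotypes ri_geno.tsv --phenotypes ri_pheno.tsv --out assoc.tsv

# pseudo-genome for allele-aware mapping
cageshift pseudogenome --fasta ref.fa --vcf snvs.vcf --out pseudo.fa

# everything at once, with summary + manifest
cageshift run --ctss ctss.matrix.tsv --samplesheet samples.all.tsv --gtf genes.gtf \
    --cpg cpg.bed --fasta genome.fa --vcf f1.vcf --outdir run/
```

Sample sheets are TSV with columns `sample_id`, `strain` (`A`, `B` or `F1`),
and optional `sex`, `replicate`, `group`. Coordinates are 1-based inclusive
internally (GTF/VCF convention); BED input/output converts at the boundary.
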