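# ctrich

Targeted long-read genotyping and association toolkit for the polymorphic
CT-rich repeat in intron 4 of *SNCA*.

## The problem

Intron 4 of *SNCA* — the gene encoding alpha-synuclein — harbours a
polymorphic CT-rich structural variant that segregates as four length-defined
haplotypes (H1–H4, with H4 the largest). The region cannot be resolved by
short reads, so it is characterised by targeted amplicon long-read (HiFi)
sequencing: a ~520 bp amplicon is PCR-amplified with primers flanking the
repeat, reads are demultiplexed and cleaned of chimeras, the repeat is
genotyped per sample from flank-anchored reads, alleles are binned into the
four haplotypes by length, and the haplotype dosages are taken into
association, linkage-disequilibrium and expression/CAGE cis-QTL analyses.

`ctrich` implements that entire workflow as a tested, simulation-backed
pipeline for method development: every input a real study would provide
(reads, cohort genotypes, phenotypes, covariates, expression matrices) can be
generated synthetically with known ground truth, so each stage's accuracy is
measurable.

## What it computes

* **Primer QC** — reads are classified `forward-pass` / `reverse-pass` /
  `chimeric` / `unmatched` from the placement of the forward
  (`GTTGGAAACTCTCCCAGACACT`) and reverse (`CAAGCATACCCTTGCCCTGA`) PCR
  primers; a primer occurrence in the read interior, or the same primer at
  both termini, marks a chimera.
* **Repeat genotyping** — the repeat segment strictly between two flank
  sequences is extracted per read (edit distance ≤ 2 per flank), segments are
  clustered into ≤ 2 alleles at the largest length gap, the per-allele
  consensus is the medoid under Levenshtein distance, and samples with mean
  depth < 10 fail QC.
* **Haplotype classification** — alleles are binned into H1–H4 by length and
  validated by Levenshtein distance against the reference sequences
  (distance > 1 flags the call without reassigning it); per-sample dosages
  are coded 0/1/2 per haplotype.
* **Association statistics** — OLS of haplotype dosage on SNV dosage with
  sex, age and PC1–5 covariates (t, P, SE, R²); binomial GLM of case/control
  status with OR = e^β and 95 % CI; D′ from unphased genotypes via EM over the
  four two-locus haplotype frequencies (D′ = |D|/D_max, D = p_AB − p_A p_B);
  homozygote-carrier percentages per haplotype × SNV.
* **cis-QTL** — TPM / CAGE-TSS count filtering, per-feature rank
  inverse-normal transform Φ⁻¹((rank − ½)/n), UMAP sample-embedding
  covariates, a ±1 Mb per-pair linear scan, and Benjamini–Hochberg FDR.

## Worked example

```bash
ctrich all --seed 1 --n-samples 300 --outdir demo_run
```

runs simulate → preprocess → genotype → classify → assoc → qtl. With seed 1
and 300 samples the run log reports 9000 simulated reads of which 8578 are
kept (160 chimeric, 262 unmatched), and `04_classify/frequencies.tsv`
contains

```
haplotype  allele_count  allele_frequency  n_samples
H1         156           0.260             300
H2         204           0.340             300
H3         44            0.073             300
H4         196           0.327             300
```

— the called allele frequencies of the four haplotypes, to be compared with
the configured truth (0.26, 0.29, 0.08, 0.37; a 300-sample cohort carries
binomial noise of about ±0.02). The association table
(`05_assoc/haplotype_snv_assoc.tsv`) shows the planted tagging structure,
e.g. H3 × rs2298728: t = 14.14, P = 6.4e-35, SE = 0.036, R² = 0.42,
D′ = 0.84 — a strong positive association of the H3 dosage with its linked
SNV under incomplete LD. In the CAGE cis-QTL stage the feature carrying the
planted per-allele effect (β = −0.8 on `ctss_0030`) is the top hit:
β̂ = −1.16 (on the rank-normalised scale), P = 1.3e-72, smallest FDR in the
scan.

Every stage is also importable directly (`ctrich.simulate_cohort`,
`ctrich.orient_and_filter`, `ctrich.genotype_cohort`, `ctrich.cohort_dosages`,
`ctrich.dprime_em`, `ctrich.cis_scan`, ...); see `docs/methods.md` for the
models behind each stage.

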