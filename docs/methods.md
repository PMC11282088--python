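# Methods

This note documents the models, defaults and design choices behind each
stage of the `ctrich` pipeline, what the synthetic data does and does not
emulate, and the numerical conventions used throughout.

## Synthetic data model

### Reference haplotypes

The four CT-rich alleles are synthesized, not copied from any published
sequence set: each is `(CT)×30 + (CTTT)×k + (CT)×6` with k chosen to reach
the configured lengths (defaults 120/144/168/240 bp, H4 longest). This keeps
every invariant the downstream logic relies on — pairwise-distinct lengths
(so length binning is well defined), ≥ 100 bp, ≥ 70 % C/T — while remaining
a pure function of the config, hence byte-reproducible. All classification
logic reads references from FASTA, so real allele sequences can be dropped
in without code changes.

### Amplicon reads

A read is `forward primer + left flank + allele + right flank +
revcomp(reverse primer)`. The primers are the published PCR pair for the
region; the two flanks are synthetic mixed-base sequences that cannot occur
inside the pyrimidine-only repeat, standing in for the genomic context that
a real aligner would use. Per sample, `read_depth` (default 30) reads are
split between the two true alleles as Binomial(0.5). Errors are injected
per base as independent substitution / insertion / deletion events
(defaults 0.2 % / 0.05 % / 0.05 %, a deliberately simple HiFi-like noise
level; there is no instrument error model, no homopolymer-length bias, no
quality-score variation). A configured fraction of reads (default 50 %) is
emitted reverse-complemented and a configured fraction (default 2 %)
replaced by chimeras.

The chimera model is a partial template fused to a second full template, so
the junction carries a primer occurrence in the read interior. A plain
half+half splice of two forward templates would carry primers only at its
termini and be undetectable by *any* primer-placement rule; the fused form
is the minimal model that exercises the chimera filter.

### Cohort, LD and phenotype

Each sample draws two gametes i.i.d. from the haplotype frequencies
(defaults 0.26/0.29/0.08/0.37, the study-scale allele frequencies of the
four haplotypes). Each SNV is simulated in LD with one haplotype by
collapsing that haplotype vs. the rest into a biallelic locus and
constructing the four two-locus gamete frequencies in closed form:

    D = D' · D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B)  for D' ≥ 0
                     D_max = min(p_A p_B, (1−p_A)(1−p_B))  for D' < 0
    p_AB = p_A p_B + D, etc.

With the sign-dependent bound, every D′ in [−1, 1] is feasible for
non-degenerate allele frequencies; the constructor rejects anything outside
that range (or monomorphic marginals) with a message naming the feasible
range. The recomputed D′ of the constructed table equals the target to
1e-12 (tested). Default SNV settings: rs356182 (AF 0.356, D′ 0.40 with H4),
rs5019538 (0.294, 0.55, H4), rs2298728 (0.113, 0.76, H3), rs7680557
(0.519, 0.71, H2) — the allele frequencies come from the CAGE-cohort
reporting and each SNV is linked to the haplotype it tags most strongly.

Phenotype is Bernoulli with logit = intercept + Σ β_j · dosage_j (default:
intercept 0.3, per-allele log-OR ln(1.05) on rs356182, giving a cohort
about 57 % cases). Covariates are sex ~ Bernoulli(0.5), age ~ N(65, 10²)
truncated to (30, 100), PC1–5 ~ N(0, 1); their exact distributions are
immaterial to the mechanics, only their presence in the design matrices
matters.

### Expression / CAGE counts

Counts are negative binomial with log μ = baseline + β · dosage +
log(library factor); baseline ~ N(4, 0.5²), NB size 10, library factors
log-normal (σ = 0.2). Features receive coordinates evenly spread over
chr4:88.3–91.3 Mb so a ±1 Mb window around the repeat locus
(chr4:89,821,175) includes some features and excludes others. TPM matrices
are derived from counts by column normalisation to 1e6. None of this
emulates real expression covariance structure, batch effects or annotation
— passing tests demonstrate that the estimators recover planted effects
under a well-specified generative model, not that they are robust to the
pathologies of real RNA-seq/CAGE data.

## Pipeline stages

### Primer marking and chimera removal

Matching is Hamming distance at each offset (no indels) with
`max_mismatches = 3` inside a terminal window of primer length + 10 bp; an
indel-tolerant (edit-distance) mode is available by config
(`allow_indels=True`) and rescues the ~3 % of reads that carry an indel
inside a primer under default error rates. Classification: forward-pass if
the forward primer sits in the 5′ window and the reverse-complemented
reverse primer in the 3′ window; reverse-pass for the mirror image;
chimeric if any primer occurs in the interior beyond the terminal windows
or the same primer is readable at both termini; unmatched otherwise. The
mismatch tolerance is a declared default, not inferred from any published
demultiplexer's internals.

### Repeat genotyping

Flank matching uses edit distance ≤ 2 (edlib infix alignment) rather than
Hamming, so an indel sequencing error inside a flank does not void the
read; the extracted allele is the subsequence *strictly between* the flank
matches — flank bases are never counted in the allele length. Allele
clustering is 1-D on segment length: split at the largest gap if the two
group centers are ≥ `min_allele_gap` (6 bp) apart and each side has ≥
`min_support` (3) reads, else call a homozygote. The defaults reflect that
the four haplotypes differ by ≥ 24 bp while indel noise perturbs lengths by
~1 bp. Consensus is the medoid — the member sequence minimizing summed
Levenshtein distance to its group, ties broken by (shorter length, then
lexicographic order) to keep results order-invariant. Mean depth is the
count of reads spanning both flanks; the QC cutoff of 10 is the standard
minimum-depth rule for this assay and is configurable.

Length clustering (not sequence clustering) is primary because all
downstream analysis is keyed on allele length; sequence content enters only
through the consensus and its edit-distance validation.

### Haplotype classification

Default bins are the reference lengths ± half the minimum inter-haplotype
gap (±12 bp at the default lengths); explicit bins can be injected for real
data. Edit distance against the bin's reference validates the assignment:
calls above `max_edit_distance = 1` keep their length-based label and carry
a flag — distance is a validation statistic, not a classifier. Samples with
any out-of-bin (UNASSIGNED) allele are excluded from allele-frequency
denominators and reported.

### Association statistics

Per-haplotype tests treat the haplotype as a biallelic locus (0/1/2 dosage
of that haplotype vs. all others). The haplotype × SNV table regresses
*haplotype dosage on SNV dosage* (plus sex, age, PC1–5); the mirrored
direction is available by flag since either orientation is defensible for a
tagging analysis. The case-control model is a binomial GLM with logit link;
the 95 % interval is reported on both the log-odds and OR scales. No
multiple-testing correction is applied to these tables; raw p-values are
reported. Rank-deficient designs raise an error naming the collinear
columns; missing covariates are handled by complete-case analysis.

D′ is estimated from unphased genotypes by EM on the four gamete
frequencies: all genotype pairs contribute unambiguous gametes except the
double heterozygote, which splits between coupling and repulsion phase by
the current expectation p_AB p_ab / (p_AB p_ab + p_Ab p_aB). Convergence:
max frequency change < 1e-10 or 1000 iterations. A phased counting mode
(`dprime_phased`) exists for phased inputs; on data free of double
heterozygotes the EM estimate equals direct counting exactly, which is how
the two routes are cross-checked (with double heterozygotes present the EM
MLE and the plug-in phased count differ in finite samples, as expected).
The bootstrap SE resamples individuals with 200 replicates.

### cis-QTL

Filters follow the assay-appropriate rules: TPM features are dropped when
TPM < 1 in more than one third of subjects; CAGE-TSS features are kept when
they have > 5 reads in > 10 samples *and* are detected in ≥ 90 % of
samples; samples aged ≤ 15 are removed first. All comparisons are strict
where the rule is phrased strictly ("more than", "larger than"). The bulk
RNA "missingness" filter is implemented as *detected in fewer than 33 % of
samples* — the alternative literal reading (exclude low-missingness
features) is self-contradictory — and a low-variance quantile filter is
available; both are off unless configured. Every dropped feature/sample is
listed in the audit with its reason, and kept + dropped = input.

"Quantile normalisation" is a per-feature rank inverse-normal transform
value → Φ⁻¹((rank − ½)/n) with average ranks on ties, i.e. each feature's
marginal is mapped onto a standard normal; constant features become zeros
and are flagged. UMAP covariates default to 2 components with a fixed
`random_state` (deterministic given the seed); with fewer than 10 samples
the stage is skipped with a warning. Whether to include UMAP components and
genetic PCs simultaneously is left open in the source material; both are
included by default and each is individually toggleable.

The scan itself is an OLS of the transformed feature on variant dosage for
every pair whose variant position lies within [feature start − 1 Mb,
feature end + 1 Mb); haplotype dosages enter as pseudo-variants positioned
at the repeat locus. Covariates are projected out once per scan
(Frisch–Waugh), which is numerically identical to the full per-pair OLS
(verified to 1e-10 against the reference implementation) and keeps the scan
linear in the number of pairs. FDR is Benjamini–Hochberg across all emitted
pairs — permutation-based empirical p-values are out of scope.

Coordinates are BED-style 0-based half-open internally; printed 1-based
labels (e.g. the repeat region label) are carried as display strings only.

## Reproducibility and problem sizes

A single master seed drives every stage through spawned generator
substreams, making full pipeline runs byte-identical (tested). The test
suite runs the read-level pipeline at 200 samples × depth 30 (genotype
recovery), 1842 samples × depth 30 (frequency recovery, ~55k reads), D′
recovery at n = 1601, the GLM at n = 100,000 (cohort only, no reads), and
2000-replicate null calibrations for the OLS and GLM p-values; these sizes
were chosen to match the cohort scales the pipeline models while keeping a
full run in well under an hour on one CPU.

## Known limitations

* The error model is i.i.d. per base; real HiFi errors concentrate in
  homopolymers, which is exactly where a CT-repeat assay is most fragile.
  Genotype-recovery results here are therefore optimistic upper bounds.
* Demultiplexing is bypassed: synthetic reads carry their sample of origin.
  A barcode mode exists only as configuration surface.
* The repeat genotyper handles at most two alleles per sample and does no
  phasing beyond the two-allele split; somatic mosaicism and allele dropout
  are not modelled.
* The four reference sequences are synthetic; analyses that depend on real
  sub-haplotype sequence structure (motif interruptions, methylation) are
  out of scope.
* BH FDR across pairs is a cruder error control than per-feature
  permutation schemes used by dedicated QTL mappers; ranks of top hits are
  comparable, absolute FDR values are not.
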