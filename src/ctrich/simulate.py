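"""Synthetic data generation for the CT-rich repeat pipeline.

Everything the downstream stages consume can be generated here with known
ground truth: the four reference repeat haplotypes, a diploid cohort with
linked SNV genotypes and a binary phenotype, HiFi-like amplicon reads over
the repeat, and expression / CAGE TSS count matrices with planted
per-dosage effects.

The defaults encode the study conditions of the targeted SNCA intron-4
experiment this package models: four haplotypes at allele frequencies
(0.26, 0.29, 0.08, 0.37), a ~520 bp amplicon flanked by the published PCR
primers, per-sample HiFi depth around 30, and risk SNVs in incomplete LD
(D' 0.40-0.76) with individual haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import BASES, _BASE_INDEX, array_to_seq, revcomp, seq_to_array

HAPLOTYPE_NAMES = ("H1", "H2", "H3", "H4")

# Published amplicon PCR primers for the SNCA intron-4 CT-rich region.
FORWARD_PRIMER = "GTTGGAAACTCTCCCAGACACT"
REVERSE_PRIMER = "CAAGCATACCCTTGCCCTGA"

# Synthetic unique flanks separating the primers from the repeat segment.
# Mixed-base by construction so they can never occur inside the pure-CT repeat.
LEFT_FLANK = "ACCAGGACTTACGGAAGACAGTC"
RIGHT_FLANK = "TGGACGTTAGGAAGCAGGAATCA"

#: hg38 coordinates of the repeat flank region, carried as a label only.
REGION_LABEL = "chr4:89821175-89821400"
REPEAT_POS = 89_821_175
REPEAT_CHROM = "chr4"


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named reference allele of the CT-rich repeat."""

    name: str
    sequence: str

    def __post_init__(self):
        if self.name not in HAPLOTYPE_NAMES:
            raise ConfigError(f"haplotype name must be one of {HAPLOTYPE_NAMES}, got {self.name!r}")
        if len(self.sequence) < 100:
            raise ConfigError(f"{self.name}: repeat sequence must be >=100 bp")
        ct = (self.sequence.count("C") + self.sequence.count("T")) / len(self.sequence)
        if ct < 0.70:
            raise ConfigError(f"{self.name}: sequence must be >=70% C/T (got {ct:.2f})")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnvSpec:
    """A biallelic SNV simulated in LD with one haplotype (vs. the rest)."""

    id: str
    allele_freq: float
    target_dprime: float
    linked_haplotype: str
    position: int = REPEAT_POS  # genomic position label, defaults to the repeat locus


@dataclass(frozen=True)
class PhenotypeModel:
    """Logistic disease model: logit P(case) = intercept + sum_j beta_j * dosage_j.

    ``log_odds`` maps predictor names (haplotype names or SNV ids) to
    per-allele log odds ratios.
    """

    intercept: float = 0.3
    log_odds: dict = field(default_factory=lambda: {"rs356182": math.log(1.05)})


@dataclass(frozen=True)
class ExpressionSpec:
    """Negative-binomial count model for CTSS / gene features.

    log mean = baseline + beta * dosage(effect predictor) + log(library size
    factor); ``dispersion`` is the NB size parameter (variance = mu + mu^2/size).
    ``planted_betas`` maps feature index -> (predictor name, beta).
    """

    n_features: int = 100
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 0.5
    dispersion: float = 10.0
    planted_betas: dict = field(default_factory=dict)
    chrom: str = REPEAT_CHROM
    span: tuple = (88_300_000, 91_300_000)  # features spread around the repeat locus
    libsize_log_sd: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 1842
    haplotype_freqs: tuple = (0.26, 0.29, 0.08, 0.37)
    haplotype_lengths: tuple = (120, 144, 168, 240)
    snv_specs: tuple = (
        SnvSpec("rs356182", 0.356, 0.40, "H4"),
        SnvSpec("rs5019538", 0.294, 0.55, "H4"),
        SnvSpec("rs2298728", 0.113, 0.76, "H3"),
        SnvSpec("rs7680557", 0.519, 0.71, "H2"),
    )
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    read_depth: int = 30
    error_rates: tuple = (0.002, 0.0005, 0.0005)  # substitution, insertion, deletion
    reverse_fraction: float = 0.5
    chimera_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if freqs.shape != (4,):
            raise ConfigError("haplotype_freqs must have exactly four entries")
        if (freqs < 0).any() or (freqs > 1).any():
            raise ConfigError("haplotype_freqs entries must lie in [0, 1]")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"haplotype_freqs must sum to 1 (got {freqs.sum()!r})")
        lengths = tuple(self.haplotype_lengths)
        if len(set(lengths)) != 4:
            raise ConfigError("haplotype_lengths must be pairwise distinct so length binning is well defined")
        if max(lengths) != lengths[3]:
            raise ConfigError("H4 must be the longest haplotype")
        if any(l < 100 for l in lengths):
            raise ConfigError("haplotype lengths must be >=100 bp")
        for r in self.error_rates:
            if not 0.0 <= r <= 0.05:
                raise ConfigError("error rates must lie in [0, 0.05]")
        for spec in self.snv_specs:
            if spec.linked_haplotype not in HAPLOTYPE_NAMES:
                raise ConfigError(f"{spec.id}: linked_haplotype must be one of {HAPLOTYPE_NAMES}")
            # validates feasibility of (allele_freq, target_dprime) up front
            hap_freq = freqs[HAPLOTYPE_NAMES.index(spec.linked_haplotype)]
            two_locus_frequencies(hap_freq, spec.allele_freq, spec.target_dprime)
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >=1")
        if not 0 <= self.chimera_fraction < 1 or not 0 <= self.reverse_fraction <= 1:
            raise ConfigError("chimera_fraction/reverse_fraction must be fractions")


@dataclass(frozen=True)
class AmpliconRead:
    """One simulated read plus its ground truth."""

    id: str
    sequence: str
    orientation: str  # '+' as emitted forward, '-' emitted reverse-complemented
    sample_id: str
    true_allele: str  # haplotype name, or 'chimera'
    is_chimera: bool = False


# ---------------------------------------------------------------------------
# Reference haplotypes


def make_reference_haplotypes(config: SimulationConfig | None = None) -> list[HaplotypeDefinition]:
    """Build the four CT-rich reference alleles from (CT)n / (CTTT)m blocks.

    Deterministic: the sequence is a pure function of the configured lengths
    ((CT)x30 head, (CTTT) body, (CT)x6 tail), so repeated calls are
    byte-identical.
    """
    config = config or SimulationConfig()
    refs = []
    for name, length in zip(HAPLOTYPE_NAMES, config.haplotype_lengths):
        body = length - 72  # 60 bp (CT)x30 head + 12 bp (CT)x6 tail
        if body < 0:
            raise ConfigError(f"{name}: length {length} too short for the block structure")
        k, r = divmod(body, 4)
        seq = "CT" * 30 + "CTTT" * k + "CTTT"[:r] + "CT" * 6
        refs.append(HaplotypeDefinition(name, seq))
    return refs


def amplicon_template(hap: HaplotypeDefinition) -> str:
    """Forward-strand amplicon: fwd primer + left flank + repeat + right flank + revcomp(rev primer)."""
    return FORWARD_PRIMER + LEFT_FLANK + hap.sequence + RIGHT_FLANK + revcomp(REVERSE_PRIMER)


# ---------------------------------------------------------------------------
# Two-locus LD construction


def two_locus_frequencies(p_a: float, p_b: float, dprime: float) -> np.ndarray:
    """Four two-locus haplotype frequencies (AB, Ab, aB, ab) achieving a target D'.

    A is the focal (haplotype-vs-rest) allele with frequency ``p_a``; B the SNV
    allele with frequency ``p_b``. D = D' * Dmax with the standard
    sign-dependent bound, so any D' in [-1, 1] is feasible for non-degenerate
    marginals.
    """
    if not 0.0 < p_a < 1.0 or not 0.0 < p_b < 1.0:
        raise ConfigError(
            f"both loci must be polymorphic: got allele frequencies {p_a}, {p_b}"
        )
    if not -1.0 <= dprime <= 1.0:
        raise ConfigError(
            f"target D'={dprime} is infeasible; the feasible D' range for "
            f"frequencies ({p_a}, {p_b}) is [-1, 1]"
        )
    if dprime >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d = dprime * dmax
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    # numerical guard; construction guarantees feasibility analytically
    if (freqs < -1e-12).any():
        raise ConfigError(
            f"target D'={dprime} with frequencies ({p_a}, {p_b}) produced a "
            "negative two-locus frequency"
        )
    return np.clip(freqs, 0.0, 1.0)


def dprime_from_frequencies(freqs) -> float:
    """Recompute D' from four two-locus frequencies (AB, Ab, aB, ab)."""
    p_ab, p_a_b, p_b_a, p_ab0 = np.asarray(freqs, dtype=float)
    p_a = p_ab + p_a_b
    p_b = p_ab + p_b_a
    d = p_ab - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if dmax == 0:
        return 0.0
    return abs(d) / dmax


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a diploid cohort table with haplotypes, SNVs, phenotype and covariates.

    Each sample carries two gametes; each gamete draws a haplotype i.i.d. from
    ``haplotype_freqs`` and, per SNV spec, an SNV allele from the conditional
    distribution implied by the constructed two-locus frequencies (haplotype
    vs. rest collapsed to a biallelic locus). Sex ~ Bernoulli(0.5), age ~
    Normal(65, 10) truncated to (30, 100), PCs ~ Normal(0, 1); phenotype from
    the logistic model.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    freqs = np.asarray(config.haplotype_freqs)

    gametes = rng.choice(4, size=(n, 2), p=freqs)  # haplotype index per gamete
    df = pd.DataFrame({"sample_id": [f"S{i:05d}" for i in range(n)]})
    df["hap_allele1"] = [HAPLOTYPE_NAMES[g] for g in gametes[:, 0]]
    df["hap_allele2"] = [HAPLOTYPE_NAMES[g] for g in gametes[:, 1]]
    for j, name in enumerate(HAPLOTYPE_NAMES):
        df[f"dosage_{name}"] = (gametes == j).sum(axis=1)

    for spec in config.snv_specs:
        hap_idx = HAPLOTYPE_NAMES.index(spec.linked_haplotype)
        p_a = freqs[hap_idx]
        p_ab, p_a_b, p_b_a, p_ab0 = two_locus_frequencies(p_a, spec.allele_freq, spec.target_dprime)
        p_b_given_a = p_ab / p_a
        p_b_given_not_a = p_b_a / (1 - p_a)
        on_hap = gametes == hap_idx
        u = rng.random(size=(n, 2))
        snv_alleles = np.where(on_hap, u < p_b_given_a, u < p_b_given_not_a)
        df[spec.id] = snv_alleles.sum(axis=1)

    df["sex"] = rng.integers(0, 2, size=n)
    age = rng.normal(65.0, 10.0, size=n)
    while True:  # truncate to (30, 100) by redraw
        bad = (age <= 30) | (age >= 100)
        if not bad.any():
            break
        age[bad] = rng.normal(65.0, 10.0, size=bad.sum())
    df["age"] = age
    for k in range(1, 6):
        df[f"PC{k}"] = rng.normal(0.0, 1.0, size=n)

    model = config.phenotype_model
    eta = np.full(n, model.intercept, dtype=float)
    for predictor, beta in model.log_odds.items():
        col = f"dosage_{predictor}" if predictor in HAPLOTYPE_NAMES else predictor
        if col not in df.columns:
            raise ConfigError(f"phenotype model predictor {predictor!r} not simulated")
        eta += beta * df[col].to_numpy(dtype=float)
    df["phenotype"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return df


# ---------------------------------------------------------------------------
# Read simulation


def _inject_errors(template_arr: np.ndarray, rates, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitution / insertion / deletion errors to a uint8 array."""
    p_sub, p_ins, p_del = rates
    arr = template_arr.copy()
    n = arr.size
    if p_sub > 0:
        sub_mask = rng.random(n) < p_sub
        k = int(sub_mask.sum())
        if k:
            orig_idx = _BASE_INDEX[arr[sub_mask]]
            arr[sub_mask] = BASES[(orig_idx + rng.integers(1, 4, size=k)) % 4]
    if p_ins == 0 and p_del == 0:
        return arr
    ins_mask = rng.random(n) < p_ins
    del_mask = rng.random(n) < p_del
    counts = ins_mask.astype(np.int64) + (~del_mask).astype(np.int64)
    out = np.empty(counts.sum(), dtype=np.uint8)
    starts = np.cumsum(counts) - counts
    n_ins = int(ins_mask.sum())
    if n_ins:
        out[starts[ins_mask]] = BASES[rng.integers(0, 4, size=n_ins)]
    keep = ~del_mask
    out[(starts + ins_mask)[keep]] = arr[keep]
    return out


def simulate_reads(
    cohort: pd.DataFrame,
    refs: list[HaplotypeDefinition],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AmpliconRead]:
    """Simulate HiFi-like amplicon reads for every sample in the cohort.

    Per sample, ``read_depth`` reads are split between the two true alleles
    (binomial 0.5). Each read is the forward amplicon template with errors
    injected at the configured rates; a configured fraction is emitted
    reverse-complemented and a configured fraction replaced by chimeras
    (a partial template fused to a second full template, leaving a primer
    occurrence at the interior junction).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    templates = {h.name: seq_to_array(amplicon_template(h)) for h in refs}
    reads: list[AmpliconRead] = []
    hap_cols = cohort[["hap_allele1", "hap_allele2"]].to_numpy()
    sample_ids = cohort["sample_id"].to_numpy()
    all_haps = list(templates)
    for i in range(len(cohort)):
        sid = sample_ids[i]
        a1, a2 = hap_cols[i]
        allele_pick = rng.random(config.read_depth) < 0.5
        for r in range(config.read_depth):
            hap_name = a1 if allele_pick[r] else a2
            template = templates[hap_name]
            is_chimera = rng.random() < config.chimera_fraction
            if is_chimera:
                cut = int(len(template) * rng.uniform(0.3, 0.7))
                other = templates[all_haps[rng.integers(0, 4)]]
                template = np.concatenate([template[:cut], other])
                true_allele = "chimera"
            else:
                true_allele = hap_name
            arr = _inject_errors(template, config.error_rates, rng)
            seq = array_to_seq(arr)
            orientation = "+"
            if rng.random() < config.reverse_fraction:
                seq = revcomp(seq)
                orientation = "-"
            reads.append(
                AmpliconRead(
                    id=f"{sid}/read{r:04d}",
                    sequence=seq,
                    orientation=orientation,
                    sample_id=sid,
                    true_allele=true_allele,
                    is_chimera=is_chimera,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(
    cohort: pd.DataFrame,
    spec: ExpressionSpec,
    rng: np.random.Generator | None = None,
    kind: str = "CTSS-count",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a features x samples count matrix plus feature coordinates.

    Counts are negative binomial with log mean = baseline_f + beta_f *
    dosage(predictor) + log(sample library-size factor). Feature coordinates
    are spread across ``spec.span`` on ``spec.chrom`` so a +/-1 Mb cis window
    around the repeat locus captures some features and excludes others.
    Returns ``(matrix, coords)`` where coords is BED-like (chrom, start, end,
    feature).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_samples = len(cohort)
    n_feat = spec.n_features
    baselines = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_feat)
    libsize = rng.normal(0.0, spec.libsize_log_sd, size=n_samples)

    log_mu = baselines[:, None] + libsize[None, :]
    for f_idx, (predictor, beta) in spec.planted_betas.items():
        col = f"dosage_{predictor}" if predictor in HAPLOTYPE_NAMES else predictor
        dosage = cohort[col].to_numpy(dtype=float)
        log_mu[f_idx] += beta * dosage
    mu = np.exp(log_mu)
    size = spec.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    feature_ids = [f"ctss_{i:04d}" if kind == "CTSS-count" else f"gene_{i:04d}" for i in range(n_feat)]
    matrix = pd.DataFrame(counts, index=feature_ids, columns=cohort["sample_id"].to_numpy())
    starts = np.linspace(spec.span[0], spec.span[1], n_feat).astype(int)
    coords = pd.DataFrame(
        {"chrom": spec.chrom, "start": starts, "end": starts + 100, "feature": feature_ids}
    )
    return matrix, coords


def counts_to_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a count matrix to TPM assuming unit feature length."""
    return counts / counts.sum(axis=0) * 1e6


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
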