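"""Flank-anchored repeat genotyping from oriented amplicon reads.

For each sample: locate the two flank sequences in every read, extract the
repeat segment strictly between them, cluster segments into at most two
alleles by length (largest-gap split), take the medoid as the per-allele
consensus, and apply a mean-depth QC cutoff. This is the in-repo analogue
of a tandem-repeat genotyper run against a flank region; genomic
coordinates are carried as labels only — all matching is sequence-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .simulate import LEFT_FLANK, REGION_LABEL, RIGHT_FLANK, AmpliconRead


@dataclass(frozen=True)
class FlankSpec:
    left_flank: str = LEFT_FLANK
    right_flank: str = RIGHT_FLANK
    region_label: str = REGION_LABEL
    max_mismatches: int = 2  # edit distance allowed per flank match

    def __post_init__(self):
        if len(self.left_flank) < 15 or len(self.right_flank) < 15:
            raise ValueError("flanks must be >=15 bp")


@dataclass(frozen=True)
class Thresholds:
    depth_threshold: int = 10  # samples below this mean depth fail QC
    min_allele_gap: int = 6  # bp between cluster centers to call two alleles
    min_support: int = 3  # reads per allele


@dataclass(frozen=True)
class AlleleCall:
    sample_id: str
    allele_index: int  # 1 or 2
    consensus_sequence: str
    support: int

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("allele support must be >=1")

    @property
    def length(self) -> int:
        return len(self.consensus_sequence)


@dataclass(frozen=True)
class SampleGenotype:
    sample_id: str
    allele_calls: tuple  # 1-2 AlleleCall; a single call means a homozygote
    mean_depth: int  # number of reads spanning both flanks
    qc_pass: bool

    @property
    def allele_lengths(self) -> tuple:
        """Diploid allele lengths (homozygotes report the single length twice)."""
        lengths = tuple(c.length for c in self.allele_calls)
        return lengths * 2 if len(lengths) == 1 else lengths


def extract_spanning_segment(sequence: str, flanks: FlankSpec | None = None) -> str | None:
    """Repeat segment strictly between the best left-flank and right-flank matches.

    Each flank must match with edit distance <= ``max_mismatches``; returns
    None if either flank is absent or they are out of order.
    """
    flanks = flanks or FlankSpec()
    left = edlib.align(flanks.left_flank, sequence, mode="HW", task="locations", k=flanks.max_mismatches)
    if not 0 <= left["editDistance"] <= flanks.max_mismatches:
        return None
    left_end = left["locations"][0][1] + 1  # first (leftmost) best-score hit
    rest = sequence[left_end:]
    right = edlib.align(flanks.right_flank, rest, mode="HW", task="locations", k=flanks.max_mismatches)
    if not 0 <= right["editDistance"] <= flanks.max_mismatches:
        return None
    right_start = right["locations"][0][0]
    if right_start is None:
        return None
    return rest[:right_start]


def cluster_alleles(
    segments: list[str], min_allele_gap: int = 6, min_support: int = 3
) -> list[list[int]]:
    """Split segments into 1 or 2 length clusters at the largest length gap.

    Two clusters are called only if the cluster centers are >=
    ``min_allele_gap`` bp apart and each side has >= ``min_support`` reads;
    otherwise all reads form one (homozygote) group. Returns lists of indices
    into ``segments``.
    """
    if not segments:
        raise ValueError("cluster_alleles requires at least one segment")
    lengths = np.array([len(s) for s in segments])
    order = np.argsort(lengths, kind="stable")
    sorted_lengths = lengths[order]
    if len(segments) < 2 or sorted_lengths[-1] == sorted_lengths[0]:
        return [list(range(len(segments)))]
    gaps = np.diff(sorted_lengths)
    split = int(np.argmax(gaps)) + 1  # first index of the upper group
    lower, upper = order[:split], order[split:]
    center_gap = sorted_lengths[split:].mean() - sorted_lengths[:split].mean()
    if center_gap >= min_allele_gap and len(lower) >= min_support and len(upper) >= min_support:
        return [sorted(lower.tolist()), sorted(upper.tolist())]
    return [list(range(len(segments)))]


def consensus(group: list[str]) -> str:
    """Medoid consensus: the member minimizing summed Levenshtein distance.

    Ties broken by (smaller summed distance, shorter length, lexicographic).
    """
    if not group:
        raise ValueError("consensus requires at least one sequence")
    uniq = sorted(set(group))
    if len(uniq) == 1:
        return uniq[0]
    counts = {s: 0 for s in uniq}
    for s in group:
        counts[s] += 1
    best = None
    for cand in uniq:
        total = 0
        for other in uniq:
            if other == cand:
                continue
            total += counts[other] * edlib.align(cand, other, task="distance")["editDistance"]
        key = (total, len(cand), cand)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


def genotype_sample(
    sample_id: str,
    reads: list[AmpliconRead],
    flanks: FlankSpec | None = None,
    thresholds: Thresholds | None = None,
) -> SampleGenotype:
    """Genotype one sample from its oriented reads.

    Mean depth is the count of reads spanning both flanks; QC fails below the
    depth threshold. Zero spanning reads yields an empty genotype.
    """
    flanks = flanks or FlankSpec()
    thresholds = thresholds or Thresholds()
    segments = []
    for read in reads:
        seg = extract_spanning_segment(read.sequence, flanks)
        if seg is not None:
            segments.append(seg)
    depth = len(segments)
    if depth == 0:
        return SampleGenotype(sample_id, (), 0, False)
    groups = cluster_alleles(segments, thresholds.min_allele_gap, thresholds.min_support)
    calls = []
    for idx, grp in enumerate(groups, start=1):
        seqs = [segments[i] for i in grp]
        calls.append(AlleleCall(sample_id, idx, consensus(seqs), support=len(grp)))
    calls.sort(key=lambda c: (c.length, c.consensus_sequence))
    calls = tuple(
        AlleleCall(c.sample_id, i + 1, c.consensus_sequence, c.support) for i, c in enumerate(calls)
    )
    return SampleGenotype(sample_id, calls, depth, depth >= thresholds.depth_threshold)


def genotype_cohort(
    reads: list[AmpliconRead],
    flanks: FlankSpec | None = None,
    thresholds: Thresholds | None = None,
) -> list[SampleGenotype]:
    """Group oriented reads by sample id and genotype each sample."""
    by_sample: dict[str, list[AmpliconRead]] = {}
    for read in reads:
        by_sample.setdefault(read.sample_id, []).append(read)
    return [
        genotype_sample(sid, sample_reads, flanks, thresholds)
        for sid, sample_reads in sorted(by_sample.items())
    ]


def genotypes_to_table(genotypes: list[SampleGenotype]) -> pd.DataFrame:
    """Flatten genotypes into the cohort TSV schema."""
    rows = []
    for g in genotypes:
        calls = g.allele_calls
        if len(calls) == 1:
            calls = (calls[0], calls[0])
        row = {"sample_id": g.sample_id, "mean_depth": g.mean_depth, "qc_pass": g.qc_pass}
        for i, c in enumerate(calls, start=1):
            row[f"allele{i}_length"] = c.length
            row[f"allele{i}_seq"] = c.consensus_sequence
            row[f"allele{i}_support"] = c.support
        if not calls:
            row.update(
                allele1_length=pd.NA, allele1_seq="", allele1_support=0,
                allele2_length=pd.NA, allele2_seq="", allele2_support=0,
            )
        rows.append(row)
    return pd.DataFrame(rows)
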