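"""Length-bin haplotype classification with edit-distance validation.

Called alleles are binned into the four haplotypes by allele length alone
(the downstream analyses are all length-based); the consensus sequence is
then compared to the reference sequence of the assigned bin by Levenshtein
distance as a validation step. Alleles whose edit distance exceeds the
configured bound keep their length-based label but carry a flag — edit
distance validates the binning, it does not reassign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import pandas as pd

from .genotype import SampleGenotype
from .simulate import HAPLOTYPE_NAMES, HaplotypeDefinition

UNASSIGNED = "UNASSIGNED"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two sequences."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class LengthBins:
    """Four half-open integer length intervals [lo, hi) mapping to H1..H4."""

    bins: dict  # name -> (lo, hi)

    def __post_init__(self):
        intervals = sorted(self.bins.values())
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            if hi1 > lo2:
                raise ValueError(f"length bins overlap: [{lo1},{hi1}) and [{lo2},{hi2})")
        for lo, hi in intervals:
            if hi <= lo:
                raise ValueError(f"empty bin [{lo},{hi})")

    @classmethod
    def from_references(cls, refs: list[HaplotypeDefinition], half_gap: int | None = None) -> "LengthBins":
        """Bins centered on the reference lengths, +/- half the minimum inter-haplotype gap."""
        lengths = sorted(r.length for r in refs)
        if half_gap is None:
            min_gap = min(b - a for a, b in zip(lengths, lengths[1:]))
            half_gap = min_gap // 2
        return cls({r.name: (r.length - half_gap, r.length + half_gap) for r in refs})

    def assign(self, length: int) -> str:
        for name, (lo, hi) in self.bins.items():
            if lo <= length < hi:
                return name
        return UNASSIGNED


def classify_allele(
    consensus_sequence: str,
    bins: LengthBins,
    refs: list[HaplotypeDefinition],
    max_edit_distance: int = 1,
) -> tuple[str, int | None, bool]:
    """Assign a called allele to a haplotype bin and validate by edit distance.

    Returns ``(haplotype, edit_distance, flagged)``. Out-of-bin lengths yield
    (UNASSIGNED, None, True); edit distance above ``max_edit_distance`` flags
    the call without reassigning it.
    """
    hap = bins.assign(len(consensus_sequence))
    if hap == UNASSIGNED:
        return UNASSIGNED, None, True
    ref = next(r for r in refs if r.name == hap)
    dist = levenshtein(consensus_sequence, ref.sequence)
    return hap, dist, dist > max_edit_distance


def cohort_dosages(
    genotypes: list[SampleGenotype],
    bins: LengthBins,
    refs: list[HaplotypeDefinition],
    max_edit_distance: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample haplotype assignments/dosages plus a cohort allele-frequency summary.

    Only QC-passed samples are classified. Samples with any UNASSIGNED allele
    are excluded from the frequency denominators (and reported via the
    ``excluded`` column). Raises if every sample ends up excluded.
    """
    qc_passed = [g for g in genotypes if g.qc_pass and g.allele_calls]
    if not qc_passed:
        raise ValueError("no QC-passed samples to classify")
    rows = []
    for g in qc_passed:
        calls = g.allele_calls
        if len(calls) == 1:
            calls = (calls[0], calls[0])
        haps, dists, flags = [], [], []
        for c in calls:
            hap, dist, flag = classify_allele(c.consensus_sequence, bins, refs, max_edit_distance)
            haps.append(hap)
            dists.append(dist)
            flags.append(flag)
        dosage = {name: haps.count(name) for name in HAPLOTYPE_NAMES}
        rows.append(
            {
                "sample_id": g.sample_id,
                "allele1_hap": haps[0],
                "allele2_hap": haps[1],
                "edit_distance1": dists[0],
                "edit_distance2": dists[1],
                "flagged": any(flags),
                "excluded": UNASSIGNED in haps,
                **{f"dosage_{name}": dosage[name] for name in HAPLOTYPE_NAMES},
            }
        )
    assignments = pd.DataFrame(rows).sort_values("sample_id", ignore_index=True)
    usable = assignments[~assignments["excluded"]]
    if usable.empty:
        raise ValueError("all samples carry unassigned alleles; check the length bins")
    n_excluded = int(assignments["excluded"].sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} samples excluded from allele frequencies (unassigned alleles)", stacklevel=2)
    denom = 2 * len(usable)
    freq = pd.DataFrame(
        {
            "haplotype": HAPLOTYPE_NAMES,
            "allele_count": [int(usable[f"dosage_{n}"].sum()) for n in HAPLOTYPE_NAMES],
        }
    )
    freq["allele_frequency"] = freq["allele_count"] / denom
    freq["n_samples"] = len(usable)
    return assignments, freq
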