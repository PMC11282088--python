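"""Primer marking, orientation and chimera removal for amplicon reads.

Emulates the LIMA / IsoSeq-Refine stage of a targeted amplicon experiment:
each read is classified by the placement of the forward and reverse PCR
primers, reverse-strand reads are flipped to the forward orientation, and
reads with anomalous primer placement (a primer in the read interior, or
the same primer at both termini) are flagged as chimeric and removed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from ._util import mismatch_profile, revcomp, seq_to_array
from .simulate import FORWARD_PRIMER, REVERSE_PRIMER, AmpliconRead


class ReadClass(str, enum.Enum):
    FORWARD = "forward-pass"
    REVERSE = "reverse-pass"
    CHIMERIC = "chimeric"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class PrimerSpec:
    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER
    max_mismatches: int = 3
    window_pad: int = 10  # terminal window = primer length + pad
    allow_indels: bool = False  # edit-distance (indel-tolerant) primer matching

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primers must be nonempty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >=0")


def _terminal_ok(
    arr: np.ndarray, pat: np.ndarray, window: int, max_mm: int, end: bool, indels: bool
) -> bool:
    """Does ``pat`` occur with <= max_mm mismatches inside the 5' (or 3') terminal window?"""
    region = arr[-window:] if end else arr[:window]
    if indels:
        res = edlib.align(pat.tobytes().decode(), region.tobytes().decode(), mode="HW",
                          task="distance", k=max_mm)
        return res["editDistance"] != -1
    prof = mismatch_profile(region, pat)
    return prof.size > 0 and int(prof.min()) <= max_mm


def _interior_hit(
    arr: np.ndarray, patterns: list[np.ndarray], window: int, max_mm: int, indels: bool
) -> bool:
    """Any primer occurrence strictly between the two terminal windows?"""
    interior = arr[window:-window] if arr.size > 2 * window else arr[:0]
    for pat in patterns:
        if interior.size < pat.size:
            continue
        if indels:
            res = edlib.align(pat.tobytes().decode(), interior.tobytes().decode(), mode="HW",
                              task="distance", k=max_mm)
            if res["editDistance"] != -1:
                return True
        elif (mismatch_profile(interior, pat) <= max_mm).any():
            return True
    return False


def classify_read(sequence: str, spec: PrimerSpec) -> ReadClass:
    """Classify one read by primer placement.

    forward-pass: forward primer within the first window and the
    reverse-complemented reverse primer within the last window; reverse-pass:
    the mirror condition (i.e. the reverse complement of the read is
    forward-pass); chimeric: a primer occurs in the interior beyond the
    terminal windows, or both termini match the same primer; unmatched
    otherwise.
    """
    fwd = seq_to_array(spec.forward)
    rev = seq_to_array(spec.reverse)
    fwd_rc = seq_to_array(revcomp(spec.forward))
    rev_rc = seq_to_array(revcomp(spec.reverse))
    arr = seq_to_array(sequence)
    window = max(len(spec.forward), len(spec.reverse)) + spec.window_pad
    mm = spec.max_mismatches

    if arr.size < len(spec.forward) + len(spec.reverse):
        return ReadClass.UNMATCHED

    ind = spec.allow_indels
    fwd_at_5 = _terminal_ok(arr, fwd, window, mm, end=False, indels=ind)
    revrc_at_3 = _terminal_ok(arr, rev_rc, window, mm, end=True, indels=ind)
    rev_at_5 = _terminal_ok(arr, rev, window, mm, end=False, indels=ind)
    fwdrc_at_3 = _terminal_ok(arr, fwd_rc, window, mm, end=True, indels=ind)

    # same primer readable at both termini: palindromic chimera
    if (fwd_at_5 and fwdrc_at_3) or (rev_at_5 and revrc_at_3):
        if not (fwd_at_5 and revrc_at_3) and not (rev_at_5 and fwdrc_at_3):
            return ReadClass.CHIMERIC
    if _interior_hit(arr, [fwd, rev, fwd_rc, rev_rc], window, mm, indels=ind):
        return ReadClass.CHIMERIC
    if fwd_at_5 and revrc_at_3:
        return ReadClass.FORWARD
    if rev_at_5 and fwdrc_at_3:
        return ReadClass.REVERSE
    return ReadClass.UNMATCHED


def orient_and_filter(
    reads: list[AmpliconRead], spec: PrimerSpec | None = None
) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Keep forward-oriented non-chimeric reads; log the class of every read.

    Reverse-pass reads are reverse-complemented so the output is uniformly
    forward-oriented. Returns ``(kept_reads, log)`` where the log has one row
    per input read (read id, class, kept).
    """
    spec = spec or PrimerSpec()
    kept: list[AmpliconRead] = []
    rows = []
    for read in reads:
        cls = classify_read(read.sequence, spec)
        keep = cls in (ReadClass.FORWARD, ReadClass.REVERSE)
        rows.append((read.id, cls.value, keep))
        if not keep:
            continue
        if cls is ReadClass.REVERSE:
            read = AmpliconRead(
                id=read.id,
                sequence=revcomp(read.sequence),
                orientation="+",
                sample_id=read.sample_id,
                true_allele=read.true_allele,
                is_chimera=read.is_chimera,
            )
        kept.append(read)
    log = pd.DataFrame(rows, columns=["read_id", "class", "kept"])
    if not kept:
        warnings.warn("no reads passed primer orientation/chimera filtering", stacklevel=2)
    return kept, log
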