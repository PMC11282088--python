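"""Small sequence and RNG helpers shared across the pipeline stages."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# uint8 byte -> base index (A=0, C=1, G=2, T=3); other bytes map to 255
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 byte array (view-friendly, no copy of semantics)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def mismatch_profile(seq_arr: np.ndarray, pat_arr: np.ndarray) -> np.ndarray:
    """Hamming mismatch count of ``pat_arr`` against every offset of ``seq_arr``.

    Returns an array of length ``len(seq) - len(pat) + 1``; empty if the pattern
    does not fit.
    """
    m = pat_arr.size
    if seq_arr.size < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
    return (windows != pat_arr).sum(axis=1)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generator substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def ct_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("C") + seq.count("T")) / len(seq)
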