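"""Low-level nucleotide encoding shared across modules.

Sequences are encoded as int8 arrays with A=0, C=1, G=2, T=3; every other
IUPAC code (N, ambiguity letters) encodes as -1 and is excluded from all
composition counts downstream.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3

IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHVU")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGT"))

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (non-ACGT -> -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes < 0):
        raise ValueError("cannot decode ambiguous (-1) codes")
    return "".join(_DECODE[codes])


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N; other IUPAC codes mapped via Biopython."""
    try:
        return "".join(_COMP[b] for b in reversed(seq))
    except KeyError:
        from Bio.Seq import reverse_complement

        return str(reverse_complement(seq))


def base_counts(codes: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Counts of A,C,G,T in an encoded sequence (shape (4,)); -1 codes ignored.

    ``mask`` optionally restricts counting to a boolean subset of positions.
    """
    if mask is not None:
        codes = codes[mask]
    valid = codes[codes >= 0]
    return np.bincount(valid, minlength=4)[:4].astype(np.int64)
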