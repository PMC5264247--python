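"""Nucleotide sequence helpers: encoding, complementation, random sequences.

Internal module. Sequences are uppercase strings over {A,C,G,T,N}; the
numeric encoding maps A,C,G,T -> 0..3 and N (or anything else) -> 4, which
lets pileup and consensus code stay fully vectorised.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 decodes to ``N``."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random sequence over {A,C,G,T}."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return decode(rng.integers(0, 4, size=length))


def as_codes(row) -> np.ndarray:
    """Accept either a string or an already-encoded uint8 array."""
    if isinstance(row, str):
        return encode(row)
    return np.asarray(row, dtype=np.uint8)
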