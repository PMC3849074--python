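"""Small shared DNA utilities: alphabet, encoding, reverse complement."""

from __future__ import annotations

import numpy as np

#: Alphabet in the fixed lexicographic order used for k-tuple indexing.
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: byte -> base code (A=0, C=1, G=2, T=3); 255 marks any other character.
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i

_CODE_TO_BYTE = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to base codes 0..3 (255 for non-ACGT characters)."""
    return BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes (0..3 only)."""
    return _CODE_TO_BYTE[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")
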