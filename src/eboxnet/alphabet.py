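"""DNA alphabet helpers shared across modules.

Bases are indexed in the fixed order A, C, G, T; the index 4 is reserved for
the ambiguity code N.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_INDEX = 4
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("N")] = N_INDEX
_LUT[ord("n")] = N_INDEX

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_indices(sequence: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0, C=1, G=2, T=3, N=4).

    Any other character raises, naming the position and the character.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _LUT[arr]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"invalid base {sequence[pos]!r} at position {pos}")
    return codes


def decode_indices(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]
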