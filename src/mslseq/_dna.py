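"""Low-level DNA utilities shared across modules.

Sequences are plain Python strings over {A,C,G,T,N}; hot loops work on
uint8 code arrays (A=0, C=1, G=2, T=3, N/other=4).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to uint8 codes; any non-ACGT character becomes 4."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def gc_fraction(sequence: str) -> float:
    codes = encode(sequence)
    valid = codes < 4
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    return float(((codes == 1) | (codes == 2)).sum() / n)


def at_fraction(sequence: str) -> float:
    return 1.0 - gc_fraction(sequence)


def base_composition(sequence: str) -> np.ndarray:
    """Mononucleotide probabilities (A,C,G,T) over the non-N bases."""
    codes = encode(sequence)
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer code of every k-window plus a validity mask.

    Windows containing any non-ACGT base are flagged invalid; their code
    value is unspecified and must not be used.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.where(codes < 4, codes, 0).astype(np.int64)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        vals = vals * 4 + safe[i : i + n]
        valid &= codes[i : i + n] < 4
    return vals, valid


def code_to_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def word_to_code(word: str) -> int:
    code = 0
    for b in word:
        code = (code << 2) | BASES.index(b)
    return code
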