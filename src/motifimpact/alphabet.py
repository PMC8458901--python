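"""DNA alphabet utilities: encoding, reverse complement, packed k-mer codes.

k-mers are packed into int64 codes base-4, big-endian (A=0, C=1, G=2, T=3),
so ascending code order is lexicographic order. Because each base occupies two
bits, the Hamming distance between two equal-length words can be computed from
the XOR of their codes, which the gapped k-mer kernel exploits.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# 255 marks any character outside {A,C,G,T} (case-insensitive).
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 digits (A=0,C=1,G=2,T=3; other chars 255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def require_acgt(seq: str) -> np.ndarray:
    """Encode, raising ValueError on any non-ACGT character."""
    digits = encode(seq)
    if (digits == 255).any():
        bad = seq[int(np.argmax(digits == 255))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return digits


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def decode(digits: np.ndarray) -> str:
    return "".join(BASES[d] for d in digits)


def window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes of every length-``k`` window of ``seq``.

    Returns ``(codes, valid)`` where ``codes[i]`` is the base-4 code of
    ``seq[i:i+k]`` and ``valid[i]`` is False for windows containing non-ACGT
    characters (their code is meaningless).
    """
    digits = encode(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(digits, k)
    valid = (win != 255).all(axis=1)
    safe = np.where(win == 255, 0, win).astype(np.int64)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return safe @ pow4, valid


def kmer_to_code(kmer: str) -> int:
    digits = require_acgt(kmer.upper())
    code = 0
    for d in digits:
        code = code * 4 + int(d)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def all_codes(k: int) -> np.ndarray:
    return np.arange(4**k, dtype=np.int64)


def codes_to_digits(codes: np.ndarray, k: int) -> np.ndarray:
    """(n, k) digit matrix for an array of packed codes."""
    codes = np.asarray(codes, dtype=np.int64)
    shifts = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((codes[:, None] // shifts[None, :]) % 4).astype(np.uint8)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement on packed codes."""
    c = np.asarray(codes, dtype=np.int64).copy()
    rc = np.zeros_like(c)
    for _ in range(k):
        rc = rc * 4 + (3 - (c % 4))
        c //= 4
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """The lexicographically smaller of each code and its reverse complement."""
    return np.minimum(np.asarray(codes, dtype=np.int64), revcomp_codes(codes, k))


def hamming_codes(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """Hamming distance between packed codes (broadcasting)."""
    x = np.bitwise_xor(np.asarray(a, dtype=np.int64), np.asarray(b, dtype=np.int64))
    low_bits = np.int64(sum(1 << (2 * i) for i in range(k)))
    diff = np.bitwise_and(np.bitwise_or(x, x >> 1), low_bits)
    return np.bitwise_count(diff).astype(np.int64)
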