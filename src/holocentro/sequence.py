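"""Low-level DNA sequence utilities shared by the scanners.

Sequences are handled as uppercase strings externally and as uint8 arrays
internally (A=0, C=1, G=2, T=3, N=4). Complementary base codes sum to 3,
which the inverted-repeat finder exploits; N never matches anything.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode",
    "decode",
    "revcomp",
    "kmer_codes",
    "canonical_kmer_set",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_BASES = np.array(list("ACGTN"))

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (unknown characters become N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of an encoded sequence.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes ``arr[i:i+k]`` in
    base 4 and ``valid[i]`` is False when the window contains an N. Requires
    ``k <= 31`` so codes fit in int64.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = arr.astype(np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        codes = codes * 4 + np.minimum(a[i : n - k + 1 + i], 3)
    bad = (arr >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def canonical_kmer_set(seq: str, k: int) -> set[int]:
    """Set of canonical (min of forward / reverse-complement code) k-mers.

    Windows containing N are skipped.
    """
    arr = encode(seq)
    fwd, valid_f = kmer_codes(arr, k)
    rc = encode(revcomp(seq))
    rev, valid_r = kmer_codes(rc, k)
    if fwd.size == 0:
        return set()
    rev = rev[::-1]  # align reverse-complement k-mer to its forward window
    valid_r = valid_r[::-1]
    canon = np.minimum(fwd, rev)
    return set(canon[valid_f & valid_r].tolist())
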