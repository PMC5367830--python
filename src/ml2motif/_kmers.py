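"""Fixed-alphabet k-mer encoding utilities.

Sequences over the DNA alphabet {A, C, G, T} are represented internally as
integer code arrays (A=0, C=1, G=2, T=3).  A k-mer is indexed by its base-4
big-endian code: the first character is the most significant digit, so
``kmer_index("AC") == 1`` and ``kmer_index("CA") == 4``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array; reject other characters."""
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(
            f"sequence contains non-ACGT character {exc.args[0]!r}: {seq[:40]!r}"
        ) from None


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


def seqs_to_codes(seqs) -> np.ndarray:
    """Encode a list of equal-length sequences into an (n, L) int8 matrix."""
    if len(seqs) == 0:
        return np.empty((0, 0), dtype=np.int8)
    L = len(seqs[0])
    out = np.empty((len(seqs), L), dtype=np.int8)
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(f"ragged sequence lengths: {len(s)} != {L} at record {i}")
        out[i] = seq_to_codes(s)
    return out


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = 4 * idx + _CODE[c]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(chars))


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all length-k windows.

    ``codes`` is (n, L) or (L,); the result is (n, L-k+1) (or (L-k+1,)) with
    entry [i, j] the code of codes[i, j:j+k].
    """
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = sliding_window_view(codes, k, axis=-1)
    return win.astype(np.int64) @ powers


def digit_matrix(k: int) -> np.ndarray:
    """(4**k, k) matrix of base-4 digits of every k-mer code (big-endian)."""
    idx = np.arange(4**k)
    out = np.empty((4**k, k), dtype=np.int64)
    for pos in range(k - 1, -1, -1):
        out[:, pos] = idx % 4
        idx = idx // 4
    return out
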