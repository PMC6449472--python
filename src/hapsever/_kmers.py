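"""Vectorized 2-bit k-mer encoding shared by the profiling and masking code.

Bases map A,C,G,T -> 0..3 and anything else (N) -> 4. A k-mer is packed into
an int64 as base-4 digits, most significant base first; windows touching an
N code are invalid and dropped. k <= 31 keeps codes within 62 bits.
"""

from __future__ import annotations

from typing import Iterable, Tuple

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """ASCII DNA string -> uint8 base codes (N and friends -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int, canonical: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Pack every k-window of a base-code array into int64 k-mer codes.

    Returns (kmer_codes, valid) where valid marks windows free of N; invalid
    windows carry arbitrary values and must be filtered by the caller (the
    pair of arrays lets callers keep positional alignment with the input).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k={k} out of supported range 1..31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = (codes & 3).astype(np.int64)
    fwd = _pack(c, k, big_endian=True)
    is_n = (codes == 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cum[k:] - cum[:-k]) == 0
    if not canonical:
        return fwd, valid
    rev = _pack(3 - c, k, big_endian=False)
    return np.minimum(fwd, rev), valid


def _pack(c: np.ndarray, k: int, big_endian: bool) -> np.ndarray:
    """Pack all k-windows of base codes into int64 by binary doubling.

    big_endian: result[i] = sum_j c[i+j] * 4^(k-1-j); otherwise the exponent
    order is reversed (used for the reverse-complement strand). O(log k)
    full passes over the array instead of O(k).
    """
    res = c
    length = 1  # window length currently packed in res
    for bit in bin(k)[3:]:  # remaining bits of k, MSB first
        m = res.size - length
        if big_endian:
            res = (res[:m] << (2 * length)) + res[length:]
        else:
            res = res[:m] + (res[length:] << (2 * length))
        length *= 2
        if bit == "1":
            m = res.size - 1
            if big_endian:
                res = (res[:m] << 2) + c[length : length + m]
            else:
                res = res[:m] + (c[length : length + m] << (2 * length))
            length += 1
    return res


def valid_kmer_codes(seqs: Iterable[str], k: int, canonical: bool = True) -> np.ndarray:
    """All valid k-mer codes across sequences (windows never span records)."""
    joined = "N".join(seqs)
    codes, valid = kmer_codes(seq_to_codes(joined), k, canonical=canonical)
    return codes[valid]


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
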