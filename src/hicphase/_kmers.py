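"""Vectorised 2-bit k-mer machinery shared by the Hi-C mapper and the evaluator.

Sequences are encoded to small integer codes (A=0, C=1, G=2, T=3; N and
record separators = 4) and every window of length k is packed into a
uint64 word, so k is limited to 31 (62 bits).  The canonical form of a
window is the minimum of its forward and reverse-complement codes, which
folds the two strands together -- Hi-C reads arrive on arbitrary strands.

Windows containing a non-ACGT code are marked invalid; concatenating many
sequences with a separator byte therefore yields per-sequence windows for
free, which is how the batch helpers below process whole read sets in a
handful of numpy passes.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq) -> np.ndarray:
    """Encode a DNA string (or bytes) to uint8 codes; unknown bases -> 4."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def check_k(k: int) -> None:
    if k % 2 == 0 or k < 11 or k > MAX_K:
        raise ValueError(f"k must be odd and in [11, {MAX_K}], got {k}")


def _window_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward codes and validity of all length-k windows of code array b.

    Built by binary doubling: a window of length a+b is the length-a window
    shifted left by 2b bits ORed with the length-b window starting a later.
    """
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    codes = {1: b.astype(np.uint64)}
    valid = {1: b < 4}
    m = 1
    while m * 2 <= k:
        c, v = codes[m], valid[m]
        codes[2 * m] = (c[:-m] << np.uint64(2 * m)) | c[m:]
        valid[2 * m] = v[:-m] & v[m:]
        m *= 2
    acc_c = acc_v = None
    off = 0
    pieces = sorted((1 << i for i in range(k.bit_length()) if (k >> i) & 1),
                    reverse=True)
    for m in pieces:
        c = codes[m][off:off + n]
        v = valid[m][off:off + n]
        if acc_c is None:
            acc_c, acc_v = c, v  # never mutated in place below
        else:
            acc_c = (acc_c << np.uint64(2 * m)) | c
            acc_v = acc_v & v
        off += m
    if len(pieces) == 1:
        acc_c, acc_v = acc_c.copy(), acc_v.copy()
    return acc_c, acc_v


def canonical_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-folded) codes of all k-windows, plus validity."""
    fwd, valid = _window_codes(b, k)
    rc = _COMP[b[::-1]]
    rev, _ = _window_codes(rc, k)
    return np.minimum(fwd, rev[::-1]), valid


def batch_canonical(seqs, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes for many sequences in one pass.

    Returns (codes, owner, pos) arrays restricted to valid windows, where
    ``owner`` is the index of the originating sequence in ``seqs`` and
    ``pos`` the window start within it.
    """
    if not len(seqs):
        return (np.empty(0, np.uint64), np.empty(0, np.int64),
                np.empty(0, np.int64))
    if all(isinstance(s, str) for s in seqs):
        # one-pass encode: NUL separators map to the invalid code 4
        big = encode("\0".join(seqs) + "\0")
        lens = np.fromiter((len(s) for s in seqs), np.int64, len(seqs))
        starts = np.concatenate([[0], np.cumsum(lens[:-1] + 1)])
    else:
        sep = np.array([4], np.uint8)
        parts, starts, cur = [], np.empty(len(seqs), np.int64), 0
        for i, s in enumerate(seqs):
            e = s if isinstance(s, np.ndarray) else encode(s)
            starts[i] = cur
            parts.append(e)
            parts.append(sep)
            cur += e.size + 1
        big = np.concatenate(parts)
    codes, valid = canonical_codes(big, k)
    idx = np.nonzero(valid)[0]
    owner = np.searchsorted(starts, idx, side="right") - 1
    pos = idx - starts[owner]
    return codes[idx], owner, pos


_BASES = "ACGT"


def decode_code(code: int, k: int) -> str:
    """Decode a packed uint64 k-mer code back to its DNA string."""
    out = []
    c = int(code)
    for _ in range(k):
        out.append(_BASES[c & 3])
        c >>= 2
    return "".join(reversed(out))


def canonical_kmers_of(seq: str, k: int) -> list[int]:
    """Canonical codes of all valid k-mers of one sequence (scalar helper)."""
    codes, valid = canonical_codes(encode(seq), k)
    return [int(c) for c in codes[valid]]
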