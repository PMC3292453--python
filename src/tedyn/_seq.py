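"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain Python strings over {A,C,G,T,N}; hot paths encode them as
numpy uint8 arrays with A,C,G,T -> 0..3 and anything else -> 4.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[ord(chr(b).lower())] = i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3,other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def shannon_entropy(seq: str) -> float:
    """Mononucleotide Shannon entropy in bits per base (0..2)."""
    if not seq:
        return 0.0
    codes = encode(seq)
    counts = np.bincount(codes[codes < 4], minlength=4)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of an encoded sequence.

    Returns (values, valid) where values[i] encodes codes[i:i+k] in base 4 and
    valid[i] is False for windows containing non-ACGT bases.  Empty arrays if
    the sequence is shorter than k.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    clean = np.where(codes < 4, codes, 0).astype(np.uint64)
    for j in range(k):
        vals |= clean[j : j + n] << np.uint64(2 * (k - 1 - j))
        bad |= codes[j : j + n] == 4
    return vals, ~bad


def canonical_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of forward / reverse-complement) k-mer codes."""
    fwd, valid = kmer_codes(codes, k)
    rc_all, _ = kmer_codes(revcomp_codes(codes), k)
    rc = rc_all[::-1] if len(rc_all) else rc_all
    return np.minimum(fwd, rc), valid


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)
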