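"""Low-level DNA utilities: encoding, k-mers, GC, homopolymers, constrained
random sequence generation.

Sequences are plain uppercase ``ACGT`` strings at the API surface; the
simulators and counters use 2-bit uint8 arrays (A=0, C=1, G=2, T=3) so a
32-mer fits a uint64 code.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 array (A=0, C=1, G=2, T=3)."""
    a = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if a.max(initial=0) > 3:
        bad = set(seq) - set("ACGTacgt")
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return a


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DEC[np.asarray(arr, dtype=np.uint8)].tobytes().decode()


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def kmers(seq: str, k: int) -> Iterator[str]:
    """All overlapping k-mers of ``seq`` in order."""
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def kmer_set(seq: str, k: int) -> set[str]:
    return set(kmers(seq, k))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    out = [""]
    for _ in range(k):
        out = [p + b for p in out for b in ALPHABET]
    return out


def is_rc_palindrome(kmer: str) -> bool:
    """True when a k-mer equals its own reverse complement."""
    return kmer == revcomp(kmer)


def kmer_code(kmer: str) -> int:
    """2-bit integer code of a k-mer (k <= 32)."""
    code = 0
    for b in kmer:
        code = (code << 2) | int(_ENC[ord(b)])
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def homopolymer_runs(seq: str, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Maximal single-base runs as ``(start, length, base)``, longest first
    filter applied at ``min_len``."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def longest_homopolymer(seq: str) -> int:
    if not seq:
        return 0
    return max(length for _, length, _ in homopolymer_runs(seq))


def find_sites(seq: str, motif: str, circular: bool = False) -> list[int]:
    """Start positions of ``motif`` in ``seq``; circular search wraps the
    origin (positions reported modulo ``len(seq)``)."""
    hay = seq + (seq[: len(motif) - 1] if circular and len(motif) > 1 else "")
    hits = []
    start = 0
    while True:
        i = hay.find(motif, start)
        if i == -1:
            break
        hits.append(i % len(seq))
        start = i + 1
    return sorted(set(hits))


def contains_any(seq: str, motifs: Iterable[str]) -> str | None:
    """First motif found in ``seq`` (both strands are the caller's concern),
    else None."""
    for m in motifs:
        if m in seq:
            return m
    return None


def random_dna(
    rng: np.random.Generator,
    length: int,
    gc: float = 0.5,
    forbidden: Sequence[str] = (),
    max_homopolymer: int = 5,
    max_tries: int = 200,
) -> str:
    """Random DNA with an exact G+C count, no forbidden motif and no
    homopolymer longer than ``max_homopolymer``.

    The G+C count is ``round(gc * length)``; S bases are split as evenly as
    possible between G and C (W between A and T), so the realized GC fraction
    deviates from ``gc`` by < 1/length.  Constraint violations are repaired by
    reshuffling a window around each violation, preserving base counts.
    """
    if length == 0:
        return ""
    n_s = int(round(gc * length))
    bases = (
        ["G"] * (n_s // 2 + n_s % 2)
        + ["C"] * (n_s // 2)
        + ["A"] * ((length - n_s) // 2 + (length - n_s) % 2)
        + ["T"] * ((length - n_s) // 2)
    )
    arr = np.array(bases)
    rng.shuffle(arr)
    seq = "".join(arr)
    for _ in range(max_tries):
        bad = _first_violation(seq, forbidden, max_homopolymer)
        if bad is None:
            return seq
        lo = max(0, bad - 8)
        hi = min(length, bad + 16)
        window = np.array(list(seq[lo:hi]))
        rng.shuffle(window)
        seq = seq[:lo] + "".join(window) + seq[hi:]
    raise RuntimeError(
        f"could not satisfy sequence constraints in {max_tries} repair passes "
        f"(length={length}, gc={gc})"
    )


def _first_violation(
    seq: str, forbidden: Sequence[str], max_homopolymer: int
) -> int | None:
    pos = None
    for m in forbidden:
        i = seq.find(m)
        if i != -1 and (pos is None or i < pos):
            pos = i
    for start, run, _ in homopolymer_runs(seq, max_homopolymer + 1):
        if pos is None or start < pos:
            pos = start
    return pos
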