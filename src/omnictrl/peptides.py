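"""Tryptic peptide pools and reverse translation for protein-control genes.

A "fully tryptic" pool peptide ends in K or R, starts with a residue other
than P (so the upstream cleavage site is not suppressed), contains no
internal cleavage site, and is at least 7 residues long — guaranteeing that
trypsin digestion of a tiled concatenation regenerates exactly the tiles.

Reverse translation uses an E. coli K-12 codon-preference table and avoids
forbidden motifs (restriction sites) by synonymous-codon backtracking.
"""

from __future__ import annotations

import numpy as np

# E. coli K-12 codons, most-preferred first
CODON_TABLE: dict[str, tuple[str, ...]] = {
    "A": ("GCG", "GCC", "GCA", "GCT"),
    "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
    "N": ("AAC", "AAT"),
    "D": ("GAT", "GAC"),
    "C": ("TGC", "TGT"),
    "Q": ("CAG", "CAA"),
    "E": ("GAA", "GAG"),
    "G": ("GGC", "GGT", "GGG", "GGA"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("CTG", "TTA", "TTG", "CTC", "CTT", "CTA"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "S": ("AGC", "TCT", "TCC", "TCG", "AGT", "TCA"),
    "T": ("ACC", "ACG", "ACT", "ACA"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTG", "GTT", "GTC", "GTA"),
    "*": ("TAA", "TGA", "TAG"),
}

_THEMES = (
    "AVILFAVILFGW",  # hydrophobic, high GRAVY
    "DEDESTGAV",  # acidic, low pI
    "STNQGYASTN",  # polar
    "FYWAGSTL",  # aromatic
    "HHSTAGLV",  # His-rich, mid-high pI
    "ADEFGHILNQSTVWY",  # mixed
)


def is_fully_tryptic(peptide: str) -> bool:
    """True when the peptide is a valid fully-cleaved tryptic tile."""
    if len(peptide) < 7 or peptide[-1] not in "KR" or peptide[0] == "P":
        return False
    # internal K/R is only tolerated when followed by P (no cleavage there)
    return all(
        peptide[i] not in "KR" or peptide[i + 1] == "P"
        for i in range(len(peptide) - 1)
    )


def default_peptide_pool(n: int = 36, seed: int = 2024) -> list[str]:
    """Deterministic synthetic pool of unique fully-tryptic peptides with
    diverse composition (GRAVY and pI spread); the first peptide starts with
    Met and is intended as the shared terminal tile."""
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(pool) < n and attempts < 100 * n:
        attempts += 1
        theme = _THEMES[len(pool) % len(_THEMES)]
        length = int(rng.integers(8, 14))
        body = "".join(rng.choice(list(theme), size=length - 2))
        first = "M" if not pool else str(rng.choice(list(theme.replace("P", ""))))
        pep = first + body + str(rng.choice(["K", "R"]))
        if pep in seen or not is_fully_tryptic(pep):
            continue
        seen.add(pep)
        pool.append(pep)
    if len(pool) < n:
        raise RuntimeError("could not generate the requested peptide pool")
    return pool


def reverse_translate(
    protein: str,
    forbidden: set[str] | frozenset[str] = frozenset(),
    prefix: str = "",
) -> str:
    """Reverse-translate ``protein`` (may include ``*`` stop) into DNA using
    preferred E. coli codons, avoiding every motif in ``forbidden`` by
    synonymous-codon backtracking.  ``prefix`` is upstream context included in
    the motif check but not returned.
    """
    if not protein:
        return ""
    motif_len = max((len(m) for m in forbidden), default=0)
    choices = [CODON_TABLE[aa] for aa in protein]
    picks = [0] * len(protein)
    seq: list[str] = []  # one codon per residue
    i = 0
    while i < len(protein):
        if picks[i] >= len(choices[i]):
            picks[i] = 0
            i -= 1
            if i < 0:
                raise RuntimeError("reverse translation infeasible under motif constraints")
            picks[i] += 1
            seq.pop()
            continue
        codon = choices[i][picks[i]]
        candidate = prefix + "".join(seq) + codon
        window = candidate[-(motif_len + 2):] if motif_len else ""
        if motif_len and any(m in window for m in forbidden):
            picks[i] += 1
            continue
        seq.append(codon)
        i += 1
    return "".join(seq)
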