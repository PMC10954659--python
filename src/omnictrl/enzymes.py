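"""Restriction enzymes used by the designer and the in silico digest.

Only the top-strand double-strand cut coordinate is modeled: a site at
position ``s`` cuts the duplex between ``s + cut_offset - 1`` and
``s + cut_offset``.  All five default sites are 6 bp reverse-complement
palindromes, so one dsDNA cut per site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import revcomp


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str  # recognition sequence, top strand, 5'->3'
    cut_offset: int  # bases 5' of the cut within the site (G^AATTC -> 1)

    def __post_init__(self) -> None:
        if not set(self.site) <= set("ACGT"):
            raise ValueError(f"{self.name}: invalid recognition sequence {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside the site")

    @property
    def is_palindromic(self) -> bool:
        return self.site == revcomp(self.site)


EcoRI = Enzyme("EcoRI", "GAATTC", 1)
HindIII = Enzyme("HindIII", "AAGCTT", 1)
BamHI = Enzyme("BamHI", "GGATCC", 1)
PstI = Enzyme("PstI", "CTGCAG", 5)
SpeI = Enzyme("SpeI", "ACTAGT", 1)

DEFAULT_ENZYMES: tuple[Enzyme, ...] = (EcoRI, HindIII, BamHI, PstI, SpeI)

BY_NAME = {e.name: e for e in DEFAULT_ENZYMES}


def get_enzyme(name: str) -> Enzyme:
    try:
        return BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {sorted(BY_NAME)}"
        ) from None


def forbidden_motifs(enzymes) -> set[str]:
    """Recognition sites and their reverse complements for a list of enzymes."""
    out: set[str] = set()
    for e in enzymes:
        out.add(e.site)
        out.add(revcomp(e.site))
    return out
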