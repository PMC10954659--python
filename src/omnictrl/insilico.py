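"""In silico molecular products of a design: restriction fragments, run-off
transcripts, tryptic peptides and peptide physicochemical properties.

Digestion models only the top-strand double-strand cut coordinate; the five
default enzymes all have palindromic sites, one dsDNA cut per site.
Transcription follows the run-off convention: a phage polymerase initiates at
the promoter +1 and extends to the end of the digested fragment, or to the
first annotated terminator in between.  Trypsin follows the Keil rule (cut
C-terminal of K/R unless the next residue is P).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .designspec import PlasmidDesign
from .dna import find_sites
from .enzymes import Enzyme, get_enzyme

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Ikai aliphatic-index mole-percent coefficients
_ALIPHATIC = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}


@dataclass(frozen=True)
class Fragment:
    start: int  # 0-based on the canonical linearization
    end: int  # exclusive; > plasmid length when the fragment wraps the origin
    sequence: str
    uncut: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    promoter: str  # T7 | Sp6
    template_start: int
    template_end: int
    length: int
    has_polya: bool
    stopped_by_terminator: bool = False


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    parent_protein: str
    missed_cleavages: int
    start: int  # 0-based residue offset in parent protein
    copy_number_expected: int | None = None


@dataclass(frozen=True)
class PhysicochemProfile:
    molecular_weight: float  # Da, average masses
    isoelectric_point: float
    gravy: float  # Kyte-Doolittle mean hydropathy
    instability_index: float
    aliphatic_index: float
    extinction_coefficient: float  # M^-1 cm^-1, reduced cysteines


def _resolve_enzyme(enzyme: str | Enzyme) -> Enzyme:
    return enzyme if isinstance(enzyme, Enzyme) else get_enzyme(enzyme)


def digest(
    design: PlasmidDesign | str,
    enzyme: str | Enzyme,
    topology: str = "circular",
) -> list[Fragment]:
    """Complete restriction digest.

    Circular input with ``s`` sites yields ``s`` fragments (one flagged
    ``uncut`` full-circle fragment when s == 0); linear input yields ``s+1``.
    Fragment lengths always sum to the input length.
    """
    enz = _resolve_enzyme(enzyme)
    seq = design if isinstance(design, str) else design.sequence
    if topology not in ("circular", "linear"):
        raise ValueError("topology must be 'circular' or 'linear'")
    circular = topology == "circular"
    n = len(seq)
    sites = find_sites(seq, enz.site, circular=circular)
    cuts = sorted((s + enz.cut_offset) % n if circular else s + enz.cut_offset
                  for s in sites)
    if circular:
        if not cuts:
            return [Fragment(0, n, seq, uncut=True)]
        doubled = seq + seq
        frags = []
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            length = (nxt - c) % n or n  # single cut -> full-length fragment
            frags.append(Fragment(c, c + length, doubled[c : c + length]))
        return frags
    bounds = [0] + cuts + [n]
    return [
        Fragment(a, b, seq[a:b]) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]


def transcribe(
    design: PlasmidDesign,
    enzyme: str | Enzyme,
    promoter: str,
) -> list[TranscriptModel]:
    """Run-off transcripts after digesting ``design`` with ``enzyme``.

    One transcript per promoter instance of the requested type: from the
    promoter's +1 (the first base after the annotated promoter element) to
    the end of the fragment carrying it, or to the first terminator
    annotated in between.  Zero-length run-offs are suppressed.
    """
    if promoter not in ("T7", "Sp6"):
        raise ValueError("promoter must be 'T7' or 'Sp6'")
    n = len(design.sequence)
    promoters = [
        f for f in design.features_of("promoter") if f.name.startswith(promoter)
    ]
    if not promoters:
        return []
    terminators = design.features_of("terminator")
    polyas = design.features_of("polya")
    frags = digest(design, enzyme, topology="circular")
    out: list[TranscriptModel] = []
    for p in promoters:
        plus1 = p.end % n
        for frag in frags:
            # the intact promoter element must lie inside the fragment with
            # its +1 strictly upstream of the fragment end
            p_off = (p.start - frag.start) % n
            off = p_off + p.length
            if off >= frag.length:
                continue
            run = frag.length - off
            stopped = False
            for t in terminators:
                t_off = (t.start - frag.start) % n
                if off < t_off < off + run:
                    run = t_off - off
                    stopped = True
            if run <= 0:
                break
            has_polya = any(
                off <= (pa.start - frag.start) % n < off + run for pa in polyas
            )
            out.append(
                TranscriptModel(
                    promoter=promoter,
                    template_start=plus1,
                    template_end=(plus1 + run) % n,
                    length=run,
                    has_polya=has_polya,
                    stopped_by_terminator=stopped,
                )
            )
            break
    return sorted(out, key=lambda t: t.template_start)


def trypsin_cut_sites(protein: str) -> list[int]:
    """Cleavage positions (0-based, cut *after* this index) under the Keil
    rule: after K or R, not when followed by P."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def trypsin_digest(
    protein: str,
    parent: str = "protein",
    max_missed: int = 0,
) -> list[PeptideRecord]:
    """Tryptic peptides with up to ``max_missed`` missed cleavages.

    Fully cleaved peptides (missed_cleavages == 0) come first, ordered by
    position, followed by the 1-missed merges, and so on.
    """
    if not protein:
        return []
    bad = set(protein) - AA20
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    cuts = trypsin_cut_sites(protein)
    bounds = [0] + [c + 1 for c in cuts] + [len(protein)]
    out: list[PeptideRecord] = []
    for missed in range(max_missed + 1):
        for i in range(len(bounds) - 1 - missed):
            a, b = bounds[i], bounds[i + 1 + missed]
            out.append(PeptideRecord(protein[a:b], parent, missed, a))
    return out


def physicochem(peptide: str) -> PhysicochemProfile:
    """ProtParam-style physicochemical profile of a peptide.

    Molecular weight uses average residue masses plus one water; pI is the
    Bjellqvist-pKa isoelectric point; GRAVY the mean Kyte-Doolittle
    hydropathy; instability the Guruprasad dipeptide index; aliphatic index
    the Ikai mole-percent formula; extinction coefficient at 280 nm assumes
    reduced cysteines (5500 per Trp + 1490 per Tyr).
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - AA20
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    pa = ProteinAnalysis(peptide)
    n = len(peptide)
    aliphatic = sum(
        _ALIPHATIC.get(a, 0.0) * 100.0 * peptide.count(a) / n for a in "AVIL"
    )
    ext_reduced = pa.molar_extinction_coefficient()[0]
    return PhysicochemProfile(
        molecular_weight=pa.molecular_weight(),
        isoelectric_point=pa.isoelectric_point(),
        gravy=pa.gravy(),
        instability_index=pa.instability_index(),
        aliphatic_index=aliphatic,
        extinction_coefficient=float(ext_reduced),
    )
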