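"""Designer for synthetic multi-omic control plasmids.

The designed plasmid carries four gene modules on one circle:

* ``conu`` — a near-shortest cover of every allowed 6-mer, split into four
  family units present at 1x/2x/3x/4x copies: a read-count ladder.
* ``gece`` — six random genes at fixed GC targets (21-65%): GC-bias probes.
* ``repe`` — two genes jointly carrying all 16 homopolymer tracts
  (A/C/G/T x 6/9/12/18 nt) at ~44% overall GC: repeat-error probes.
* ``proco`` — three protein-coding genes tiling tryptic peptides at
  1x/2x/4x/8x copies: a peptide quantification ladder.

The assembler places the genes into EcoRI-delimited blocks whose sizes are
drawn from the fragment-size targets, so a complete EcoRI digest produces
exactly the intended band ladder, and positions HindIII/BamHI sites so that
T7 and Sp6 run-off transcription after digestion reproduces the transcript
product targets.  Everything is deterministic given the spec seed: one
master seed, per-component child seeds derived by stable hashing of
component names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ._version import __version__
from .designspec import DesignSpec, Feature, GeneUnit, PlasmidDesign
from .dna import (
    contains_any,
    find_sites,
    gc_fraction,
    kmer_set,
    longest_homopolymer,
    random_dna,
    revcomp,
)
from .enzymes import Enzyme, forbidden_motifs, get_enzyme
from .insilico import digest, transcribe, trypsin_digest
from .kcover import build_kmer_universe, generate_kmer_cover
from .peptides import default_peptide_pool, is_fully_tryptic, reverse_translate

T7_PROMOTER = "TAATACGACTCACTATA"  # +1 is the first base after the element
SP6_PROMOTER = "ATTTAGGTGACACTATA"
SHINE_DALGARNO = "AGGAGG"
HIS_LEADER = "MGSSHHHHHHSSGR"  # N-terminal His-tag leader, ends at a cut site
STOP_CODON = "TAA"


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component generator from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# gene generators


def generate_conu(spec: DesignSpec, seed: int | None = None) -> list[GeneUnit]:
    """conu family units: k-mer cover split with (k-1)-base overlaps."""
    seed = spec.seed if seed is None else seed
    allowed = build_kmer_universe(spec.kmer_size, spec.enzymes)
    cover = generate_kmer_cover(allowed, seed=int(child_rng(seed, "conu").integers(2**31)))
    if isinstance(cover, list):
        raise RuntimeError(
            "k-mer cover did not join into a single sequence; "
            "relax the forbidden motif set"
        )
    return split_conu(cover, spec.conu_families, list(spec.conu_copy_numbers), spec.kmer_size)


def split_conu(
    cover: str, n_families: int, copy_numbers: list[int], k: int = 6
) -> list[GeneUnit]:
    """Split a cover into near-equal contiguous units overlapping by k-1
    bases so no k-mer is lost at the boundaries."""
    if n_families != len(copy_numbers):
        raise ValueError("n_families must equal len(copy_numbers)")
    if len(cover) <= n_families * k:
        raise ValueError("cover too short to split")
    n = len(cover)
    bounds = [round(i * n / n_families) for i in range(n_families + 1)]
    units = []
    for i in range(n_families):
        a, b = bounds[i], min(bounds[i + 1] + (k - 1), n)
        if i == n_families - 1:
            b = n
        units.append(
            GeneUnit(f"conu{i + 1}", "conu", cover[a:b], copy_number=copy_numbers[i])
        )
    return units


def generate_gece(spec: DesignSpec, seed: int | None = None) -> list[GeneUnit]:
    """Random genes at the requested GC targets; no forbidden enzyme site and
    no homopolymer >= 6 nt (repeat effects stay attributable to repe genes)."""
    seed = spec.seed if seed is None else seed
    forb = forbidden_motifs(spec.enzymes)
    units = []
    for i, target in enumerate(spec.gece_gc_targets):
        realized = round(target * spec.gece_length) / spec.gece_length
        if abs(realized - target) > 0.01:
            raise ValueError(
                f"gece_length={spec.gece_length} too short to realize GC target "
                f"{target} within 1 percentage point"
            )
        rng = child_rng(seed, f"gece{i + 1}")
        seq = random_dna(
            rng, spec.gece_length, gc=target, forbidden=sorted(forb), max_homopolymer=5
        )
        units.append(GeneUnit(f"gece{i + 1}", "gece", seq))
    return units


def _repe_tract_assignment(lengths: tuple[int, ...]) -> tuple[list, list]:
    """Alternate the 4 bases x len(lengths) tracts between the two genes so
    GC-contributing tracts split evenly."""
    tracts = [(base, n) for n in sorted(lengths) for base in "ACGT"]
    return tracts[0::2], tracts[1::2]


def generate_repe(spec: DesignSpec, seed: int | None = None) -> list[GeneUnit]:
    """Two genes jointly containing every homopolymer tract (4 bases x the
    configured lengths), each tract flanked by non-identical bases, with
    overall GC within 2 points of the target."""
    seed = spec.seed if seed is None else seed
    forb = sorted(forbidden_motifs(spec.enzymes))
    spacer_len = 30
    halves = _repe_tract_assignment(spec.repe_homopolymer_lengths)
    total_tract = 4 * sum(spec.repe_homopolymer_lengths)
    tract_gc = sum(n for base, n in halves[0] + halves[1] if base in "GC")
    n_spacers = sum(len(h) + 1 for h in halves)
    s_total = n_spacers * spacer_len
    want = spec.repe_gc_target
    spacer_gc = (want * (total_tract + s_total) - tract_gc) / s_total
    if not 0.0 <= spacer_gc <= 1.0:
        lo = tract_gc / (total_tract + s_total)
        hi = (tract_gc + s_total) / (total_tract + s_total)
        raise ValueError(
            f"repe GC target {want} infeasible; achievable range "
            f"[{lo:.3f}, {hi:.3f}] with {spacer_len} nt spacers"
        )
    units = []
    for g, tracts in enumerate(halves):
        rng = child_rng(seed, f"repe{g + 1}")
        # per-gene spacer GC so both genes land on the target; per-spacer
        # S-base counts by cumulative rounding to avoid systematic bias
        tract_len_g = sum(n for _, n in tracts)
        tract_gc_g = sum(n for base, n in tracts if base in "GC")
        n_spacers = len(tracts) + 1
        s_total_g = n_spacers * spacer_len
        gc_g = (want * (tract_len_g + s_total_g) - tract_gc_g) / s_total_g
        gc_g = min(max(gc_g, 0.0), 1.0)
        cum = [round(gc_g * spacer_len * i) for i in range(n_spacers + 1)]
        per_spacer_gc = [
            (cum[i + 1] - cum[i]) / spacer_len for i in range(n_spacers)
        ]
        for attempt in range(50):
            parts = []
            prev_base = None
            for i, (base, n) in enumerate(tracts):
                sp = _boundary_safe_spacer(
                    rng, spacer_len, per_spacer_gc[i], forb, prev_base, base
                )
                parts.append(sp)
                parts.append(base * n)
                prev_base = base
            parts.append(
                _boundary_safe_spacer(
                    rng, spacer_len, per_spacer_gc[-1], forb, prev_base, None
                )
            )
            seq = "".join(parts)
            if contains_any(seq, forb) is None:
                break
        else:
            raise RuntimeError("repe generation failed to avoid forbidden sites")
        units.append(GeneUnit(f"repe{g + 1}", "repe", seq))
    return units


def _boundary_safe_spacer(rng, length, gc, forbidden, left_base, right_base) -> str:
    """Spacer whose terminal bases differ from the adjoining tract bases so
    tract lengths stay exact."""
    for _ in range(50):
        sp = random_dna(rng, length, gc=gc, forbidden=forbidden, max_homopolymer=5)
        if (left_base is None or sp[0] != left_base) and (
            right_base is None or sp[-1] != right_base
        ):
            return sp
    raise RuntimeError("could not generate a boundary-safe spacer")


def design_proco(
    peptide_pool: list[str],
    spec: DesignSpec,
    seed: int | None = None,
    terminal_slot: str = "C",
) -> list[GeneUnit]:
    """Protein-control genes tiling pool peptides at the spec's copy scheme.

    Each gene tiles ``proco_peptides_per_gene`` unique peptides into
    ``sum(cn * n)`` tile instances with no serial repetition; the shared
    Met-initial peptide occupies the terminal slot of every gene (C-terminal
    by default, configurable).  The tiling is reverse-translated avoiding
    forbidden enzyme sites, His-tag-led, and framed by a Shine-Dalgarno
    element (the transcription terminator is added by the assembler).
    """
    seed = spec.seed if seed is None else seed
    bad = [p for p in peptide_pool if not is_fully_tryptic(p)]
    if bad:
        raise ValueError(f"pool peptides are not fully tryptic: {bad[:3]}")
    if len(set(peptide_pool)) != len(peptide_pool):
        raise ValueError("pool contains duplicate peptides")
    met = [p for p in peptide_pool if p.startswith("M")]
    if not met:
        raise ValueError("pool must contain a Met-initial peptide")
    shared = met[0]
    others = [p for p in peptide_pool if p != shared]
    per_gene = spec.proco_peptides_per_gene - 1
    forb = frozenset(forbidden_motifs(spec.enzymes))
    if len(others) < per_gene:
        raise ValueError("pool too small for one gene")
    units = []
    for g in range(spec.proco_count):
        rng = child_rng(seed, f"proco{g + 1}")
        if len(others) >= per_gene * spec.proco_count:
            mine = others[g * per_gene : (g + 1) * per_gene]
        else:  # small pools: genes reuse the pool
            mine = list(others[:per_gene])
        counts = _assign_copy_numbers(mine, shared, spec.proco_copy_scheme, rng)
        tiles = _tile_no_serial_repeat(counts, shared, rng, terminal_slot)
        protein = HIS_LEADER + "".join(tiles)
        sd_region = SHINE_DALGARNO + "ACATAC"  # spacer to the start codon
        orf = reverse_translate(protein + "*", forbidden=forb, prefix=sd_region)
        seq = sd_region + orf
        unit = GeneUnit(
            f"proco{g + 1}",
            "proco",
            seq,
            peptide_tiles=tuple(tiles),
        )
        unit.meta = {
            "orf_offset": len(sd_region),
            "protein": protein,
            "copy_numbers": counts,
            "tag_peptides": [HIS_LEADER],
        }
        units.append(unit)
    return units


def _assign_copy_numbers(mine, shared, scheme, rng) -> dict[str, int]:
    """Map each of the gene's peptides to its copy number; the shared
    terminal peptide takes a 1x slot."""
    slots: list[int] = []
    for cn, n in sorted(scheme):
        slots.extend([cn] * n)
    if 1 not in slots:
        raise ValueError("copy scheme must include a 1x slot for the shared peptide")
    slots.remove(1)
    order = list(mine)
    rng.shuffle(order)
    counts = {shared: 1}
    for pep, cn in zip(order, sorted(slots, reverse=True)):
        counts[pep] = cn
    return counts


def _tile_no_serial_repeat(counts, shared, rng, terminal_slot="C") -> list[str]:
    """Arrange the tile multiset with no two adjacent identical tiles and the
    shared peptide at the terminal slot."""
    remaining = {p: c for p, c in counts.items() if p != shared}
    remaining[shared] = counts[shared] - 1  # one copy reserved for the slot
    n_tiles = sum(remaining.values())
    order: list[str] = []
    prev = shared if terminal_slot == "N" else None
    for _ in range(n_tiles):
        candidates = sorted(
            (p for p, c in remaining.items() if c > 0 and p != prev),
            key=lambda p: (-remaining[p], p),
        )
        if not candidates:
            raise ValueError("serial-repetition constraint unsatisfiable")
        top = [p for p in candidates if remaining[p] == remaining[candidates[0]]]
        pick = top[int(rng.integers(len(top)))]
        order.append(pick)
        remaining[pick] -= 1
        prev = pick
    if terminal_slot == "N":
        tiles = [shared] + order
    else:
        if order and order[-1] == shared:
            raise ValueError("serial-repetition constraint unsatisfiable")
        tiles = order + [shared]
    return tiles


# ---------------------------------------------------------------------------
# assembly


@dataclass
class _Element:
    """A sequence element queued for layout within one EcoRI block."""

    seq: str
    name: str
    klass: str  # feature class; '' = unannotated filler
    mutable: bool = False  # repair pass may edit these bases


@dataclass
class _Block:
    size: int
    elements: list[_Element] = field(default_factory=list)
    label: str = ""

    def content_len(self) -> int:
        return sum(len(e.seq) for e in self.elements)


class DesignError(ValueError):
    pass


def _pad(rng, length, forb) -> _Element:
    if length < 0:
        raise DesignError("negative pad requested")
    return _Element(
        random_dna(rng, length, gc=0.5, forbidden=forb, max_homopolymer=5),
        "pad",
        "spacer",
        mutable=True,
    )


def _terminator(rng, forb) -> _Element:
    return _Element(
        random_dna(rng, 40, gc=0.55, forbidden=forb, max_homopolymer=5),
        "terminator",
        "terminator",
        mutable=True,
    )


def _cassette(
    rng,
    promoter: str,
    enzyme: Enzyme,
    transcript_len: int,
    genes: list[GeneUnit],
    polya_len: int,
    forb: list[str],
    inter_gene_spacer: int = 10,
) -> list[_Element]:
    """Promoter + transcribed region + downstream cut site + terminator.

    The transcribed region is G + genes (spacer-joined) + polyA + pad, sized
    so the run-off from the promoter +1 to the enzyme's cut equals
    ``transcript_len`` exactly.
    """
    prom_seq = T7_PROMOTER if promoter == "T7" else SP6_PROMOTER
    els: list[_Element] = [_Element(prom_seq, promoter, "promoter")]
    # the mutable 9 nt 5' leader keeps every immutable-immutable junction out
    # of reach of the site-repair pass
    body: list[_Element] = [_Element("G", "tss", "", mutable=False), _pad(rng, 9, forb)]
    for i, g in enumerate(genes):
        if i:
            body.append(_pad(rng, inter_gene_spacer, forb))
        body.append(_Element(g.sequence, g.name, g.klass))
    body.append(_Element("A" * polya_len, "polyA", "polya"))
    body_len = sum(len(e.seq) for e in body)
    # run-off covers body + pad + first base of the site (cut_offset bases)
    pad_len = transcript_len - body_len - enzyme.cut_offset
    if pad_len < 0:
        raise DesignError(
            f"transcript target {transcript_len} nt too short for "
            f"{[g.name for g in genes]} ({body_len} nt content)"
        )
    pad = _pad(rng, pad_len, forb)
    # polyA must stay exactly polya_len: pad cannot start with A
    if pad_len and pad.seq[0] == "A":
        pad.seq = _rotate_away(pad.seq, "A")
    els.extend(body)
    els.append(pad)
    els.append(_Element(enzyme.site, enzyme.name, "site"))
    els.append(_terminator(rng, forb))
    return els


def _rotate_away(seq: str, base: str) -> str:
    for i, b in enumerate(seq):
        if b != base:
            return b + seq[:i] + seq[i + 1:]
    return seq  # all-`base` pad; repaired later if it ever matters


def _gene_block_elements(rng, gene: GeneUnit, forb) -> list[_Element]:
    return [_Element(gene.sequence, gene.name, gene.klass)]


def assemble(
    spec: DesignSpec,
    units: list[GeneUnit] | None = None,
    seed: int | None = None,
) -> PlasmidDesign:
    """Assemble gene units into a circular design meeting the product-size
    targets; see the module docstring for the layout strategy."""
    seed = spec.seed if seed is None else seed
    if units is None:
        units = (
            generate_conu(spec, seed)
            + generate_gece(spec, seed)
            + generate_repe(spec, seed)
            + design_proco(default_peptide_pool(), spec, seed)
        )
    rng = child_rng(seed, "assembly")
    ecori = get_enzyme("EcoRI")
    hind = get_enzyme("HindIII")
    bam = get_enzyme("BamHI")
    forb = sorted(forbidden_motifs(spec.enzymes))
    targets = sorted(spec.ecori_fragment_targets)
    max_target = targets[-1]

    conu = [u for u in units if u.klass == "conu"]
    gece = [u for u in units if u.klass == "gece"]
    repe = [u for u in units if u.klass == "repe"]
    proco = [u for u in units if u.klass == "proco"]

    blocks: list[_Block] = []

    def add_block(elements: list[_Element], label: str) -> None:
        lead = _pad(rng, 10, forb)  # mutable buffer after the EcoRI site
        content = sum(len(e.seq) for e in elements) + len(lead.seq)
        need = content + len(ecori.site)
        fits = [t for t in targets if t >= need]
        if not fits:
            raise DesignError(
                f"no EcoRI fragment target can hold {label} ({need} nt needed, "
                f"largest target {max_target})"
            )
        size = fits[0]
        pad_len = size - need
        blk = _Block(
            size, [_Element(ecori.site, "EcoRI", "site"), lead] + elements, label
        )
        if pad_len:
            blk.elements.append(_pad(rng, pad_len, forb))
        blocks.append(blk)

    # --- backbone stub: ori/marker placeholders + single PstI and SpeI sites
    backbone = [
        _Element(
            random_dna(rng, 600, gc=0.5, forbidden=forb, max_homopolymer=5),
            "ori_stub",
            "backbone",
            mutable=True,
        ),
        _Element(get_enzyme("PstI").site, "PstI", "site"),
        _Element(
            random_dna(rng, 800, gc=0.5, forbidden=forb, max_homopolymer=5),
            "marker_stub",
            "backbone",
            mutable=True,
        ),
        _Element(get_enzyme("SpeI").site, "SpeI", "site"),
    ]
    add_block(backbone, "backbone")

    # --- T7 cassettes: conu units (one instance each) then gece fill
    if not units:  # backbone-only circle: no transcription cassettes
        for t in targets:
            if t not in {b.size for b in blocks}:
                add_block([], f"band{t}")
        return _finalize(blocks, spec, rng, seed, [])
    t7_genes: list[list[GeneUnit]] = [[u] for u in conu]
    for g in gece:
        if len(t7_genes) >= spec.t7_transcript_count:
            break
        t7_genes.append([g])
    if len(t7_genes) != spec.t7_transcript_count:
        raise DesignError(
            f"cannot form {spec.t7_transcript_count} T7 cassettes from "
            f"{len(conu)} conu + {len(gece)} gece genes"
        )
    for gs in t7_genes:
        add_block(
            _cassette(rng, "T7", hind, spec.t7_transcript_length, gs,
                      spec.polya_length, forb),
            f"T7:{'+'.join(g.name for g in gs)}",
        )

    # --- Sp6 cassettes: remaining genes matched to transcript-length targets
    used_in_t7 = {g.name for gs in t7_genes for g in gs}
    sp6_pool: list[list[GeneUnit]] = [[u] for u in repe]
    sp6_pool += [[g] for g in gece if g.name not in used_in_t7]
    if proco:
        sp6_pool.append(list(proco))  # polycistronic: one Sp6 mRNA, 3 ORFs
    sp6_targets = sorted(spec.sp6_transcript_lengths, reverse=True)

    def core_len(gs: list[GeneUnit]) -> int:
        return sum(len(g.sequence) for g in gs) + 10 * (len(gs) - 1)

    sp6_pool.sort(key=core_len, reverse=True)
    # best-fit: each target takes the largest remaining content that fits;
    # targets left empty become spacer-only size-control transcripts, genes
    # left over become promoterless blocks
    min_overhead = 1 + 9 + spec.polya_length + bam.cut_offset
    assignments: list[tuple[int, list[GeneUnit]]] = []
    pool_iter = list(sp6_pool)
    for t in sp6_targets:
        chosen: list[GeneUnit] = []
        for gs in pool_iter:
            if core_len(gs) + min_overhead <= t:
                chosen = gs
                break
        if chosen:
            pool_iter.remove(chosen)
        assignments.append((t, chosen))
    if any(gs for gs in pool_iter if any(g.klass in ("repe", "proco") for g in gs)):
        raise DesignError(
            f"Sp6 transcript targets too short for contents: "
            f"{[[g.name for g in gs] for gs in pool_iter]}"
        )
    for t, gs in assignments:
        label = "+".join(g.name for g in gs) if gs else "sizecontrol"
        add_block(
            _cassette(rng, "Sp6", bam, t, gs, spec.polya_length, forb),
            f"Sp6:{label}",
        )

    # --- promoterless extra copies of conu units, remaining gece genes
    sp6_names = {g.name for _, gs in assignments for g in gs}
    for u in conu:
        for c in range(u.copy_number - 1):
            add_block(_gene_block_elements(rng, u, forb), f"{u.name}_copy{c + 2}")
    for g in gece:
        if g.name not in used_in_t7 and g.name not in sp6_names:
            add_block(_gene_block_elements(rng, g, forb), g.name)

    # --- spacer-only blocks so every band size is realized at least once
    used_sizes = {b.size for b in blocks}
    for t in targets:
        if t not in used_sizes:
            add_block([], f"band{t}")

    return _finalize(blocks, spec, rng, seed, units)


def _finalize(
    blocks: list[_Block],
    spec: DesignSpec,
    rng: np.random.Generator,
    seed: int,
    units: list[GeneUnit],
) -> PlasmidDesign:
    # concatenate, annotate, repair junction-born forbidden sites
    seq_parts: list[str] = []
    features: list[Feature] = []
    mutable_mask: list[tuple[int, int]] = []
    pos = 0
    promoter_counter = {"T7": 0, "Sp6": 0}
    site_counter: dict[str, int] = {}
    for blk in blocks:
        for el in blk.elements:
            if el.seq:
                if el.klass == "promoter":
                    promoter_counter[el.name] += 1
                    fname = f"{el.name}_{promoter_counter[el.name]}"
                elif el.klass == "site":
                    site_counter[el.name] = site_counter.get(el.name, 0) + 1
                    fname = f"{el.name}_{site_counter[el.name]}"
                else:
                    fname = el.name
                if el.klass:
                    features.append(Feature(fname, el.klass, pos, pos + len(el.seq)))
                if el.mutable:
                    mutable_mask.append((pos, pos + len(el.seq)))
                seq_parts.append(el.seq)
                pos += len(el.seq)
    sequence = "".join(seq_parts)
    sequence = _repair_unintended_sites(sequence, features, mutable_mask, spec, rng)

    design = PlasmidDesign(
        sequence=sequence,
        features=features,
        provenance={
            "spec": spec.to_dict(),
            "seed": seed,
            "software": f"omnictrl {__version__}",
            "block_sizes": [b.size for b in blocks],
            "block_labels": [b.label for b in blocks],
        },
        units=list(units),
    )
    return design


def _annotated_site_positions(features: list[Feature]) -> set[int]:
    return {f.start for f in features if f.klass == "site"}


def _repair_unintended_sites(
    sequence: str,
    features: list[Feature],
    mutable_mask: list[tuple[int, int]],
    spec: DesignSpec,
    rng: np.random.Generator,
    max_rounds: int = 30,
) -> str:
    """Mutate pad/terminator/backbone bases to destroy enzyme sites created
    at element junctions.  Sites inside immutable gene content cannot occur
    by construction; finding one is an assembly error."""
    annotated = _annotated_site_positions(features)
    seq = list(sequence)
    n = len(seq)

    def mutable(p: int) -> bool:
        return any(a <= p < b for a, b in mutable_mask)

    for _ in range(max_rounds):
        dirty = False
        for enz in spec.enzymes:
            motifs = {enz.site, revcomp(enz.site)}
            for motif in motifs:
                for hit in find_sites("".join(seq), motif, circular=True):
                    if hit in annotated:
                        continue
                    editable = [
                        hit + i for i in range(len(motif)) if mutable((hit + i) % n)
                    ]
                    if not editable:
                        raise DesignError(
                            f"unintended {enz.name} site at {hit} inside "
                            "immutable content"
                        )
                    p = editable[len(editable) // 2] % n
                    old = seq[p]
                    for new in "ACGT":
                        if new != old:
                            seq[p] = new
                            window = "".join(
                                seq[max(0, p - 7) : min(n, p + 8)]
                            )
                            if (
                                contains_any(window, forbidden_motifs(spec.enzymes))
                                is None
                                and longest_homopolymer(window) <= 5
                            ):
                                break
                            seq[p] = old
                    dirty = True
        if not dirty:
            return "".join(seq)
    raise DesignError("site repair did not converge")


# ---------------------------------------------------------------------------
# validation


@dataclass
class Check:
    name: str
    passed: bool
    detail: str


@dataclass
class ValidationReport:
    checks: list[Check]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]


def validate(design: PlasmidDesign, spec: DesignSpec | None = None) -> ValidationReport:
    """Check a design against its spec: k-mer cover completeness, forbidden
    sites, GC/homopolymer targets, digest and transcript product targets,
    proco tryptic round-trip."""
    spec = spec or design.spec or DesignSpec()
    checks: list[Check] = []
    k = spec.kmer_size
    allowed = build_kmer_universe(k, spec.enzymes)

    conu_feats = design.features_of("conu")
    covered: set[str] = set()
    for f in conu_feats:
        covered |= kmer_set(design.feature_seq(f), k)
    missing = allowed - covered
    checks.append(
        Check(
            "conu_kmer_cover",
            not missing,
            f"{len(allowed) - len(missing)}/{len(allowed)} allowed {k}-mers"
            + (f"; missing e.g. {sorted(missing)[:3]}" if missing else ""),
        )
    )

    annotated = _annotated_site_positions(design.features)
    stray: list[str] = []
    for enz in spec.enzymes:
        for motif in {enz.site, revcomp(enz.site)}:
            for hit in find_sites(design.sequence, motif, circular=True):
                if hit not in annotated:
                    stray.append(f"{enz.name}@{hit}")
    checks.append(Check("no_stray_sites", not stray, f"stray sites: {stray[:5]}"))

    for f in design.features_of("gece"):
        gseq = design.feature_seq(f)
        target = None
        if f.name.startswith("gece"):
            idx = int(f.name[4:].split("_")[0]) - 1
            if idx < len(spec.gece_gc_targets):
                target = spec.gece_gc_targets[idx]
        ok_gc = target is None or abs(gc_fraction(gseq) - target) <= 0.01
        ok_hp = longest_homopolymer(gseq) <= 5
        checks.append(
            Check(
                f"gece_gc_{f.name}",
                ok_gc and ok_hp,
                f"GC={gc_fraction(gseq):.3f} target={target} "
                f"maxhp={longest_homopolymer(gseq)}",
            )
        )

    repe_feats = design.features_of("repe")
    if repe_feats:
        joined = "".join(design.feature_seq(f) for f in repe_feats)
        want_tracts = {
            (b, n) for n in spec.repe_homopolymer_lengths for b in "ACGT"
        }
        from .dna import homopolymer_runs

        have = {(b, n) for _, n, b in homopolymer_runs(joined, min(spec.repe_homopolymer_lengths))}
        checks.append(
            Check(
                "repe_tracts",
                want_tracts <= have,
                f"missing tracts: {sorted(want_tracts - have)[:4]}",
            )
        )
        checks.append(
            Check(
                "repe_gc",
                abs(gc_fraction(joined) - spec.repe_gc_target) <= 0.02,
                f"GC={gc_fraction(joined):.3f} target={spec.repe_gc_target}",
            )
        )
        checks.append(
            Check(
                "repe_longest_tract",
                longest_homopolymer(joined) == max(spec.repe_homopolymer_lengths),
                f"longest={longest_homopolymer(joined)}",
            )
        )

    frags = digest(design, "EcoRI", topology="circular")
    bands = sorted({f.length for f in frags})
    checks.append(
        Check(
            "ecori_band_ladder",
            bands == sorted(spec.ecori_fragment_targets),
            f"bands={bands}",
        )
    )
    checks.append(
        Check(
            "ecori_conservation",
            sum(f.length for f in frags) == len(design.sequence),
            f"sum={sum(f.length for f in frags)} len={len(design.sequence)}",
        )
    )

    t7 = transcribe(design, "HindIII", "T7")
    lo, hi = spec.t7_transcript_range
    checks.append(
        Check(
            "t7_transcripts",
            len(t7) == spec.t7_transcript_count
            and all(lo <= t.length <= hi for t in t7),
            f"n={len(t7)} lengths={sorted(t.length for t in t7)}",
        )
    )
    sp6 = transcribe(design, "BamHI", "Sp6")
    checks.append(
        Check(
            "sp6_transcripts",
            sorted(t.length for t in sp6) == sorted(spec.sp6_transcript_lengths),
            f"lengths={sorted(t.length for t in sp6)}",
        )
    )

    polya = design.features_of("polya")
    checks.append(
        Check(
            "polya_length",
            bool(polya)
            and all(
                f.length == spec.polya_length
                and set(design.feature_seq(f)) == {"A"}
                for f in polya
            ),
            f"n={len(polya)}",
        )
    )

    for enz_name in ("PstI", "SpeI"):
        enz = get_enzyme(enz_name)
        hits = find_sites(design.sequence, enz.site, circular=True)
        checks.append(
            Check(f"single_{enz_name}", len(hits) == 1, f"sites={hits}")
        )

    gene_count = len(design.gene_features())
    expected = (
        sum(spec.conu_copy_numbers)
        + len(spec.gece_gc_targets)
        + 2
        + spec.proco_count
    )
    checks.append(
        Check("gene_instances", gene_count == expected, f"{gene_count} vs {expected}")
    )

    for u in design.units:
        if u.klass != "proco":
            continue
        protein = u.meta.get("protein") if hasattr(u, "meta") else None
        if protein is None:
            continue
        peps = [p.sequence for p in trypsin_digest(protein, u.name)]
        tags = u.meta.get("tag_peptides", [])
        want = sorted(list(u.peptide_tiles) + list(tags))
        checks.append(
            Check(
                f"proco_roundtrip_{u.name}",
                sorted(peps) == want,
                f"{len(peps)} peptides",
            )
        )

    return ValidationReport(checks)


def conu_family_map(design: PlasmidDesign) -> dict[str, list[int]]:
    """Family name -> copy numbers, from the design's conu units."""
    out = {}
    for u in design.units:
        if u.klass == "conu":
            out[u.name] = u.copy_number
    return out


def proco_proteins(design: PlasmidDesign) -> dict[str, dict]:
    """proco gene name -> {protein, tiles, copy_numbers, tag_peptides}."""
    out = {}
    for u in design.units:
        if u.klass == "proco":
            out[u.name] = {
                "protein": u.meta["protein"],
                "tiles": list(u.peptide_tiles),
                "copy_numbers": dict(u.meta["copy_numbers"]),
                "tag_peptides": list(u.meta["tag_peptides"]),
            }
    return out
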