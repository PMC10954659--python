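"""Declarative design specification and design-artifact types.

A :class:`DesignSpec` captures every designer parameter: the k-mer size and
enzymes whose sites are excluded from the copy-number (conu) k-mer cover, the
copy-number scheme, GC-content targets for the gece genes, homopolymer tract
lengths for the repe genes, the peptide tiling scheme of the proco genes, and
the restriction-fragment / run-off transcript product-size targets that the
assembler must reproduce.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .enzymes import DEFAULT_ENZYMES, Enzyme


@dataclass(frozen=True)
class DesignSpec:
    kmer_size: int = 6
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES
    conu_families: int = 4
    conu_copy_numbers: tuple[int, ...] = (1, 2, 3, 4)
    gece_gc_targets: tuple[float, ...] = (0.21, 0.35, 0.45, 0.47, 0.56, 0.65)
    gece_length: int = 1000
    repe_homopolymer_lengths: tuple[int, ...] = (6, 9, 12, 18)
    repe_gc_target: float = 0.44
    proco_count: int = 3
    proco_peptides_per_gene: int = 12
    # copy scheme as {copy_number: n_peptides}: nine 1x, one each of 2x/4x/8x
    proco_copy_scheme: tuple[tuple[int, int], ...] = ((1, 9), (2, 1), (4, 1), (8, 1))
    polya_length: int = 30
    ecori_fragment_targets: tuple[int, ...] = (100, 200, 400, 800, 1200, 1600, 3500)
    t7_transcript_count: int = 5
    t7_transcript_range: tuple[int, int] = (1300, 1747)
    t7_transcript_length: int = 1500
    sp6_transcript_lengths: tuple[int, ...] = (89, 189, 589, 848, 1233, 1710, 2836)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmer_size < 1:
            raise ValueError("kmer_size must be >= 1")
        if self.conu_families != len(self.conu_copy_numbers):
            raise ValueError("conu_families must equal len(conu_copy_numbers)")
        if any(c < 1 for c in self.conu_copy_numbers):
            raise ValueError("copy numbers must be positive integers")
        if any(not 0 < g < 1 for g in self.gece_gc_targets):
            raise ValueError("gece GC targets must lie in (0, 1)")
        if not 0 < self.repe_gc_target < 1:
            raise ValueError("repe GC target must lie in (0, 1)")
        if any(length < 1 for length in self.repe_homopolymer_lengths):
            raise ValueError("homopolymer lengths must be positive")
        if list(self.ecori_fragment_targets) != sorted(
            set(self.ecori_fragment_targets)
        ):
            raise ValueError("fragment targets must be strictly increasing")
        if any(cn < 1 or n < 1 for cn, n in self.proco_copy_scheme):
            raise ValueError("proco copy scheme entries must be positive")
        if sum(n for _, n in self.proco_copy_scheme) != self.proco_peptides_per_gene:
            raise ValueError("proco copy scheme must cover proco_peptides_per_gene")
        lo, hi = self.t7_transcript_range
        if not lo <= self.t7_transcript_length <= hi:
            raise ValueError("t7_transcript_length outside t7_transcript_range")

    @property
    def tiles_per_proco(self) -> int:
        return sum(cn * n for cn, n in self.proco_copy_scheme)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enzymes"] = [
            {"name": e.name, "site": e.site, "cut_offset": e.cut_offset}
            for e in self.enzymes
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        if "enzymes" in d:
            d["enzymes"] = tuple(
                Enzyme(e["name"], e["site"], e["cut_offset"]) for e in d["enzymes"]
            )
        for key in (
            "conu_copy_numbers",
            "gece_gc_targets",
            "repe_homopolymer_lengths",
            "ecori_fragment_targets",
            "sp6_transcript_lengths",
            "t7_transcript_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "proco_copy_scheme" in d:
            d["proco_copy_scheme"] = tuple(
                tuple(x) for x in d["proco_copy_scheme"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the spec (for provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GeneUnit:
    """One synthetic gene: sequence plus class and copy number."""

    name: str
    klass: str  # conu | gece | repe | proco | spacer | backbone
    sequence: str
    copy_number: int = 1
    promoters: tuple[str, ...] = ()
    peptide_tiles: tuple[str, ...] = ()  # proco only: tiled peptides in order
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in {"conu", "gece", "repe", "proco", "spacer", "backbone"}:
            raise ValueError(f"unknown gene class {self.klass!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.sequence and not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"{self.name}: sequence must be ACGT only")


@dataclass(frozen=True)
class Feature:
    """Annotated interval, 0-based half-open on the canonical linearization."""

    name: str
    klass: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlasmidDesign:
    """A circular designed plasmid with feature annotations and provenance."""

    sequence: str
    features: list[Feature]
    provenance: dict = field(default_factory=dict)
    units: list[GeneUnit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of(self, *klasses: str) -> list[Feature]:
        return [f for f in self.features if f.klass in klasses]

    def gene_features(self) -> list[Feature]:
        return self.features_of("conu", "gece", "repe", "proco")

    def feature_seq(self, f: Feature) -> str:
        if f.end <= len(self.sequence):
            return self.sequence[f.start : f.end]
        return (self.sequence + self.sequence)[f.start : f.end]

    @property
    def spec(self) -> DesignSpec | None:
        s = self.provenance.get("spec")
        return DesignSpec.from_dict(s) if s else None
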