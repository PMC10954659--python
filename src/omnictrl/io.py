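"""Readers and writers for the package's interchange formats.

Designs travel as FASTA (single circular record) + GFF3 feature table +
JSON manifest (spec, seed, per-unit sequences and digests); evaluation
inputs as FASTQ/SAM (via the simulators), counts TSV (features x samples),
a plain-text control-feature list, and peptide quantification CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._version import __version__
from .designspec import DesignSpec, Feature, GeneUnit, PlasmidDesign


def write_design_fasta(design: PlasmidDesign, path, name: str = "design") -> None:
    rec = SeqRecord(
        Seq(design.sequence),
        id=name,
        description=f"circular length={len(design.sequence)}",
    )
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(design: PlasmidDesign, path, name: str = "design") -> None:
    """Minimal GFF3: one row per feature, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {len(design.sequence)}\n")
        for f in design.features:
            attrs = f"ID={f.name};class={f.klass}"
            fh.write(
                f"{name}\tomnictrl\t{_gff_type(f.klass)}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


_GFF_TYPES = {
    "conu": "gene",
    "gece": "gene",
    "repe": "gene",
    "proco": "gene",
    "promoter": "promoter",
    "terminator": "terminator",
    "polya": "polyA_signal_sequence",
    "site": "restriction_enzyme_recognition_site",
    "spacer": "spacer",
    "backbone": "region",
}


def _gff_type(klass: str) -> str:
    return _GFF_TYPES.get(klass, "region")


def read_gff3(path) -> list[Feature]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names="seqid source type start end score strand phase attributes".split(),
    )
    feats = []
    for _, row in df.iterrows():
        attrs = dict(
            kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
        )
        feats.append(
            Feature(
                name=attrs.get("ID", row["type"]),
                klass=attrs.get("class", row["type"]),
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                strand=str(row["strand"]),
            )
        )
    return feats


def write_manifest(design: PlasmidDesign, path) -> None:
    units = [
        {
            "name": u.name,
            "klass": u.klass,
            "copy_number": u.copy_number,
            "length": len(u.sequence),
            "sha1": hashlib.sha1(u.sequence.encode()).hexdigest(),
            "sequence": u.sequence,
            "peptide_tiles": list(u.peptide_tiles),
            "meta": u.meta,
        }
        for u in design.units
    ]
    blob = {
        "software": f"omnictrl {__version__}",
        "provenance": design.provenance,
        "sequence_sha1": hashlib.sha1(design.sequence.encode()).hexdigest(),
        "length": len(design.sequence),
        "units": units,
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1)


def load_design(fasta_path, gff_path, manifest_path=None) -> PlasmidDesign:
    seqs = read_fasta(fasta_path)
    (name, seq), *_ = seqs.items()
    feats = read_gff3(gff_path)
    units: list[GeneUnit] = []
    provenance: dict = {}
    if manifest_path:
        with open(manifest_path) as fh:
            blob = json.load(fh)
        provenance = blob.get("provenance", {})
        for u in blob.get("units", []):
            gu = GeneUnit(
                u["name"],
                u["klass"],
                u["sequence"],
                copy_number=u.get("copy_number", 1),
                peptide_tiles=tuple(u.get("peptide_tiles", ())),
            )
            gu.meta = u.get("meta", {})
            units.append(gu)
    return PlasmidDesign(sequence=seq, features=feats, provenance=provenance, units=units)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_feature_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


#: Column-name mapping covering Spectronaut-style peptide exports.
QUANT_COLUMN_ALIASES = {
    "protein": ("protein", "PG.ProteinNames", "PG.ProteinGroups", "Protein"),
    "peptide": ("peptide", "PEP.StrippedSequence", "Peptide", "sequence"),
    "replicate": ("replicate", "R.Replicate", "Replicate", "run"),
    "quantity": ("quantity", "PEP.Quantity", "Quantity", "intensity"),
}


def read_peptide_quant(path, sep: str | None = None) -> pd.DataFrame:
    """Read a peptide quantification table; recognizes the canonical
    (protein, peptide, replicate, quantity) columns and common
    Spectronaut-style aliases."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for canon, aliases in QUANT_COLUMN_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                rename[a] = canon
                break
        else:
            raise ValueError(f"no column found for {canon!r} in {path}")
    df = df.rename(columns=rename)
    return df[["protein", "peptide", "replicate", "quantity"]]


def write_provenance(path, config: dict) -> None:
    blob = {"software": f"omnictrl {__version__}", "config": config}
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1, default=str)
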