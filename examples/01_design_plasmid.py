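"""Design a multi-omic control plasmid and inspect its molecular products.

Builds the default design (complete 6-mer cover split into a 1x-4x
copy-number ladder, GC probes at 21-65%, homopolymer repeat probes, three
peptide-tiling protein genes), validates every declared product target, and
prints the restriction band ladder and run-off transcript sizes.
"""

from omnictrl import DesignSpec, assemble, digest, transcribe, validate
from omnictrl import io

spec = DesignSpec(seed=42)
design = assemble(spec)
report = validate(design, spec)

print(f"plasmid: {len(design)} nt, {len(design.gene_features())} gene instances")
print(f"validation: {'all checks pass' if report.passed else report.failures()}")

bands = sorted({f.length for f in digest(design, 'EcoRI')})
print(f"EcoRI band ladder (nt): {bands}")
# each band is a distinct fragment size on a gel; multiple fragments co-migrate

t7 = [t.length for t in transcribe(design, 'HindIII', 'T7')]
sp6 = sorted(t.length for t in transcribe(design, 'BamHI', 'Sp6'))
print(f"T7 run-off transcripts after HindIII digestion (nt): {sorted(t7)}")
print(f"Sp6 run-off transcripts after BamHI digestion (nt): {sp6}")

io.write_design_fasta(design, "design.fasta")
io.write_gff3(design, "design.gff3")
io.write_manifest(design, "design.manifest.json")
print("wrote design.fasta / design.gff3 / design.manifest.json")
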