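"""Recover injected sequencing-error structure from simulated alignments.

Simulates reads whose substitution rate rises linearly with local GC and
whose deletion rate rises with homopolymer length, profiles the truth
alignments per position, and fits the two regressions the error analysis is
built around.  The printed slopes should match the injected parameters and
the R^2 values should be near 1.
"""

import tempfile
from pathlib import Path

import numpy as np

from omnictrl.dna import random_dna
from omnictrl.readsim import ErrorModel, simulate_long_reads, simulate_short_reads
from omnictrl.seqprofile import (
    aggregate_regions,
    aggregate_repeat_tracts,
    per_position_profile,
    regress_error_vs_covariate,
)

rng = np.random.default_rng(0)
tmp = Path(tempfile.mkdtemp())

# --- GC-dependent substitutions across six GC-content probe genes
levels = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
genes = [random_dna(rng, 700, gc=g) for g in levels]
ref = "".join(genes)
model = ErrorModel(substitution_rate=0.002, gc_error_slope=0.04)
reads = simulate_short_reads(ref, 20_000, 100, model, seed=1, circular=False)
reads.to_sam(tmp / "gc.sam")
prof = per_position_profile(str(tmp / "gc.sam"), ref)
regions, pos = [], 0
for i, g in enumerate(genes):
    regions.append((f"gc{int(levels[i]*100)}", pos, pos + len(g)))
    pos += len(g)
fit = regress_error_vs_covariate(aggregate_regions(prof, regions), "gc")
print(f"GC slope: injected 0.040, recovered {fit.slope:.4f} (R^2 = {fit.r2:.3f})")

# --- homopolymer-length-dependent deletions (long reads)
parts = []
for n in (6, 9, 12, 18):
    for base in "ACGT":
        parts.append(random_dna(rng, 60, max_homopolymer=4))
        parts.append(base * n)
parts.append(random_dna(rng, 60, max_homopolymer=4))
repeat_ref = "".join(parts)
model = ErrorModel(deletion_rate=0.003, repeat_deletion_slope=0.012)
long_reads = simulate_long_reads(repeat_ref, 2500, len(repeat_ref), 1, model, seed=2)
long_reads.to_sam(tmp / "repeat.sam")
prof = per_position_profile(str(tmp / "repeat.sam"), repeat_ref)
tracts = aggregate_repeat_tracts(prof, min_len=6)
fit = regress_error_vs_covariate(tracts, "repeat_length", "deletion_freq")
print(
    f"repeat deletion slope: injected 0.012/nt, recovered {fit.slope:.4f}/nt "
    f"(R^2 = {fit.r2:.3f})"
)
# slopes within ~25% of the injected values demonstrate that the per-gene /
# per-tract aggregation recovers the generative error structure
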