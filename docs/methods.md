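# Methods

This note records the models, conventions and design choices behind
`omnictrl`, in the order the pipeline uses them.

## The k-mer cover and the copy-number ladder

The conu module is a cover problem: the shortest DNA string containing
every allowed 6-mer is an Eulerian walk on the de Bruijn multigraph whose
nodes are 5-mers and whose edges are the allowed 6-mers. With no
exclusions the graph is Eulerian and the optimum has length 4^k + k − 1
(4101 nt for k = 6). Excluding the five restriction sites (all 6 bp
reverse-complement palindromes, so exactly five 6-mers) removes five edges
and unbalances up to ten nodes; we add virtual balancing edges, find one
Eulerian circuit per weakly connected component (Hierholzer's algorithm,
outgoing edges shuffled with a seeded generator so tie-breaking is
reproducible), split the circuit at the virtual edges into the minimum
number of real walks, and re-join walks end-to-end wherever no
junction-spanning 6-mer is forbidden. Total length is bounded by
|allowed| + (k−1) × segments (4116 nt in the default design). The cover is
split into four family units at near-equal length with (k−1)-base overlaps
so no 6-mer is lost at a boundary; unit *i* is replicated *cn_i* ∈
{1,2,3,4} times verbatim.

Ladder quantification counts canonical 31-mers (lexicographic minimum of a
k-mer and its reverse complement) exactly: reads are 2-bit encoded and
rolled into uint64 codes, matched against the sorted code set of each
family; 31-mers shared between families (possible at unit overlaps) are
dropped. Counts are divided by the *mean k-mer depth*
`n_reads × (read_len − k + 1) / ref_len` — the expected count of a
single-copy 31-mer — so a cn-copy k-mer has expectation cn. (Dividing by
mean per-base depth instead would introduce a constant
(read_len − k + 1)/read_len ≈ 0.8 factor that cancels in ratios, R² and
CoV; we use the window convention so normalized counts are directly
interpretable as copy numbers.) The ladder fit is ordinary least squares
of normalized count on copy number; successive ratios are means of
adjacent families; the CoV is SD/mean of copy-normalized counts pooled
across families (a single pooled distribution, since per-family CoVs are
statistically equivalent after copy normalization). A vectorized counter
is cross-checked in the tests against a plain-dict canonical counter.

## Assembly to product-size targets

The sum of the seven EcoRI fragment targets is 7800 nt, while the
mandatory gene content (a 4.1 kb cover at 10 copies, six 1 kb GC genes,
repeat and protein genes) exceeds 20 kb, so the seven sizes cannot be the
complete digest of the circle. They are treated as the *band ladder*: the
assembler partitions the whole plasmid into EcoRI-delimited blocks whose
sizes are all drawn from the target list (every target used at least
once), so the complete digest shows exactly the seven band sizes, some as
co-migrating multiplicities. The largest fragment is exactly 3500 nt.

Transcription cassettes are laid out as
`promoter | +1 G | 9 nt spacer | gene(s) | 30 nt poly(A) | pad | cut site | terminator`,
with the pad solved so the run-off from +1 to the cut equals the target
length exactly. Five T7 cassettes (the four conu units and the first GC
gene) cut with HindIII at 1500 nt; seven Sp6 cassettes cut with BamHI:
the three protein genes ride one polycistronic 2836 nt cassette (each ORF
has its own Shine-Dalgarno), two GC genes at 1710/1233 nt, the two repeat
genes at 848/589 nt, and the 89/189 nt targets — too short to hold any
gene — are spacer-only size-control transcripts. The terminator sits
*after* the cut site so run-off lengths are cut-determined on digested
templates while transcription on the intact circle still terminates.
Remaining gene copies are promoterless blocks; the backbone block carries
origin/marker placeholder stubs and the single PstI and SpeI sites.
Default total: 31,700 nt in 23 blocks.

All spacers and pads are seeded random DNA at 50% GC with exact base
counts, no homopolymer > 5 nt and no restriction site; every
immutable-immutable junction is buffered by mutable spacer so a final
repair pass can destroy any site created by concatenation by editing a
spacer base. Reverse translation of protein genes uses the most-preferred
E. coli K-12 codon with synonymous backtracking around forbidden sites.
Randomness: one master seed; each component draws from a child generator
keyed by a CRC of its name, so components are independent and the whole
design is byte-reproducible.

Open conventions we fixed: the shared Met-initial peptide occupies the
C-terminal slot of each protein gene (exposed as an option, since an
N-terminal Met would be the conventional reading); repeat probes are
homopolymers only; GC genes default to 1000 nt so ±1-point GC targets are
achievable; GC genes exclude homopolymers ≥ 6 nt so repeat effects remain
attributable to the repeat genes; transcript lengths include the poly(A)
tract; the protein leader is a single N-terminal His6 tag peptide ending
at a cleavage site so tag and tiles separate cleanly under trypsin.

## Error profiling

Per-position frequencies divide the reads carrying each error type by the
reads covering the position: soft-clipped bases are excluded from both
sides, deletions are attributed to the deleted reference positions (the
read still covers them), insertions to the position after the anchor base,
and only primary alignments count. The 6-mer table averages the per-base
total error across each sliding window and summarizes each distinct 6-mer
by its coverage-weighted mean over windows (the weighting is our choice;
an unweighted mean differs only at uneven coverage). Ranking is stable
with lexicographic tie-breaks. Error-vs-GC regressions run on per-gene
aggregates and error-vs-repeat-length on per-tract aggregates (OLS; a
two-level covariate is flagged degenerate). RNA/DNA comparison computes
per-6-mer (num + pseudo)/(den + pseudo) enrichment; the inverted-repeat
class is the 64 reverse-complement-palindromic 6-mers — a hairpin *proxy*;
no secondary-structure prediction is attempted.

## Simulators: what they emulate and what they do not

Short reads: uniform fragment sampling on the (circular) reference, mates
from fragment ends, substitution probability per reference position =
base rate + GC slope × local GC (6 nt window), with per-6-mer overrides
pinning all six positions of an occurrence. Long reads add per-position
deletion probability inflated by `slope × (tract − threshold)` inside
homopolymers, plus geometric-free per-base insertions. Qualities are
constant (no analysis uses them); substitutions are uniform over the three
alternatives; truth CIGARs consume the full read. Reads may wrap the
circular origin; the SAM writer drops origin-spanning reads (a linear
header cannot represent them), so profiler fixtures use linear references
while k-mer counting never touches SAM. The simulators do not emulate
base-caller-specific quality structure, PCR duplicates, coverage bias, or
real ONT signal behavior — passing recovery tests shows the estimators are
correct and calibrated, not that real instruments behave this simply.

Count matrices: negative-binomial (gamma-Poisson) with feature base means
lognormal around 500 (2000 in the normalization fixtures), controls
constant in expectation, standards scaled by known condition fold-changes.
Unwanted variation comes in two forms: a two-level batch factor on
designated samples, and a continuous per-sample lognormal prep-efficiency
factor — both applied to *spiked* features only by default (controls and
standards experience library-prep losses that the endogenous background
does not; scope "all" is available). Control-feature dispersion in the
normalization fixtures is 0.002, technical-replicate-level noise for
spiked material, so the injected unwanted variance dominates the sampling
floor. Peptide tables: quantity = copy number × protein abundance ×
per-peptide lognormal response factor (shared across replicates — the
structure that yields high replicate reproducibility despite poor
cross-peptide accuracy) × small lognormal replicate noise; a stated
fraction of each protein's signal is reassigned to 1-missed-cleavage
merges so the expected fully-cleaved proportion equals the complement
exactly.

## Normalization

Fixed-fraction scaling solves s·C = f·(N + s·C) per sample in closed form,
so the achieved fraction is exact to floating point. UQ uses the 75th
percentile of nonzero counts, rescaled to geometric mean 1. RUVg works on
log(counts + 1) (the cited method's convention): control rows are centered
across samples, W is the first k left singular vectors of the resulting
samples × controls matrix (scaled by singular values), and each feature's
centered log counts are regressed on W — jointly with the condition
contrast when condition labels are available, so biological signal is not
absorbed — and only the W component is subtracted. k = 0 is the identity;
the default k = 1 is exposed as a flag. Differential-expression testing
itself is out of scope; adjusted log counts are emitted for external
tools.

## Proteomics evaluation

Peptides are classified against the Keil-rule tryptic digest (cut after
K/R except before P; PeptideCutter's rarer exception matrix is a
documented simplification we do not implement): exact 0-missed fragments
are *fully* cleaved, contiguous merges up to 2 missed cleavages *partial*,
anything else *unexpected* and excluded from all denominators. His-tag
peptides are flagged and excluded from the copy-number ladder (shared,
uninformative). Cleavage proportion = fully / (fully + partial) signal
per protein per replicate. Relative abundances are per-replicate fractions
of the per-protein fully-cleaved tile signal (summing to 1), then
averaged; the ladder statistic is R² of fraction vs expected copy number,
reproducibility the mean pairwise Pearson correlation of per-peptide
fractions between replicates. The physicochemical regression standardizes
MW, pI, GRAVY, instability index, aliphatic index and extinction
coefficient (Biopython ProtParam values; the aliphatic index by Ikai's
mole-percent formula) and fits OLS with per-coefficient t-tests; pI uses
Bjellqvist pKa values with 0.001 pH bisection tolerance. The
equal-abundance check follows the housekeeping-protein selection rule
(more than 8 fully-cleaved peptides longer than 7 residues) and reports
per-protein CoV of observed fractions against the uniform 1/n expectation.

The bundled default peptide pool is synthetic: 36 deterministic
fully-tryptic peptides (8–14 residues, no internal cleavage sites,
composition themes spanning acidic/basic/hydrophobic/aromatic classes for
GRAVY and pI spread), with one Met-initial member used as the shared
terminal tile.

## Problem sizes and numerical conventions

The standard simulated library is one million 150 bp pairs (≈9500× over
the 31.7 kb default design); error-recovery fixtures run at ≈1000× over
2–4 kb references; normalization fixtures use 400 features × 6–12 samples;
peptide fixtures 3 proteins × 3 replicates. The ladder CoV at the standard
depth is ≈0.9% — a purely statistical floor that scales with
√(plasmid size/depth). Tolerances: recovered injected rates are asserted
within 3 binomial standard errors; GC/repeat slope recovery within 25–35%
relative with R² > 0.9; TSV numeric output uses 6 significant digits.
Degenerate inputs (uncut circles, zero-coverage positions, zero-count
families, constant covariates, all-zero samples) return flagged values or
explicit errors rather than silent NaNs.

## Known limitations

The designer targets the default five-enzyme, four-family geometry;
radically different product-size targets may be infeasible and are
rejected with the binding constraint named. Sticky ends are not modeled
(top-strand cut coordinate only). The transcript model is pure run-off
with annotated terminators; no thermodynamics. The hairpin class is a
sequence-symmetry proxy. RUVg here is the factor-analysis core, not the
full GLM pipeline of the reference implementation. Real-instrument error
distributions are far richer than the linear GC/repeat structure the
simulators inject.
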