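"""Seeded simulators for every evaluation input.

* short paired-end reads (wgsim-style uniform fragment sampling on a
  circular reference) with substitution errors that may depend on local GC
  and on per-6-mer overrides;
* long single-end reads with homopolymer-length-dependent deletion errors;
* negative-binomial count matrices with constant spike-in controls, known
  condition fold-changes and a sample-level unwanted (batch) factor;
* peptide quantification tables with per-peptide lognormal response factors
  shared across replicates.

Base qualities are constant (Q30); none of the downstream analyses use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designspec import PlasmidDesign
from .dna import decode, encode, homopolymer_runs
from .insilico import trypsin_digest


# ---------------------------------------------------------------------------
# error model


@dataclass
class ErrorModel:
    """Per-base error probabilities and their sequence-context dependence.

    ``gc_error_slope`` adds ``slope * GC`` (local GC fraction over
    ``gc_window`` bases) to the substitution probability.
    ``repeat_deletion_slope`` adds ``slope * (tract_len - repeat_threshold)``
    to the deletion probability at every base of a homopolymer tract longer
    than the threshold.  ``per_kmer_overrides`` pins the substitution
    probability of every base inside an occurrence of a 6-mer to the given
    total error rate (overriding base rate and GC term).  Realized per-base
    probabilities are clamped to [0, 1].
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    gc_error_slope: float = 0.0
    gc_window: int = 6
    repeat_deletion_slope: float = 0.0
    repeat_threshold: int = 5
    per_kmer_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def has_indels(self) -> bool:
        return self.insertion_rate > 0 or self.deletion_rate > 0 or (
            self.repeat_deletion_slope > 0
        )

    def substitution_profile(self, reference: str) -> np.ndarray:
        """Per-reference-position substitution probability."""
        n = len(reference)
        ref = encode(reference)
        p = np.full(n, self.substitution_rate, dtype=float)
        if self.gc_error_slope:
            is_gc = ((ref == 1) | (ref == 2)).astype(float)
            w = self.gc_window
            kernel = np.ones(w) / w
            local_gc = np.convolve(
                np.concatenate([is_gc[-(w // 2):], is_gc, is_gc[: w // 2]]),
                kernel,
                mode="same",
            )[w // 2 : w // 2 + n]
            p += self.gc_error_slope * local_gc
        for kmer, rate in self.per_kmer_overrides.items():
            start = 0
            while True:
                i = reference.find(kmer, start)
                if i == -1:
                    break
                p[i : i + len(kmer)] = rate
                start = i + 1
        return np.clip(p, 0.0, 1.0)

    def deletion_profile(self, reference: str) -> np.ndarray:
        """Per-reference-position deletion probability."""
        n = len(reference)
        p = np.full(n, self.deletion_rate, dtype=float)
        if self.repeat_deletion_slope:
            for start, run, _ in homopolymer_runs(reference, self.repeat_threshold + 1):
                p[start : start + run] += self.repeat_deletion_slope * (
                    run - self.repeat_threshold
                )
        return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# short paired-end reads


@dataclass
class ShortReadSet:
    """Paired-end reads stored as 2-bit matrices plus per-read truth.

    ``r1``/``r2`` are (n, read_length) uint8 matrices in read orientation
    (r2 is the reverse complement of its template window).  ``start1`` and
    ``start2`` are the 0-based template start positions of each mate's
    window on the forward strand; r2 maps to the reverse strand.
    """

    ref_name: str
    ref_len: int
    read_length: int
    circular: bool
    r1: np.ndarray
    r2: np.ndarray
    start1: np.ndarray
    start2: np.ndarray
    n_injected_subs: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.start1)

    def mean_depth(self) -> float:
        return 2 * self.n_pairs * self.read_length / self.ref_len

    def kmer_window_depth(self, k: int) -> float:
        """Expected count of a single-copy k-mer: reads fully covering a
        k-length window."""
        return 2 * self.n_pairs * (self.read_length - k + 1) / self.ref_len

    def iter_read_matrices(self):
        yield self.r1
        yield self.r2

    def to_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_length  # constant Q40-ish; analyses ignore it
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@pair{i}/1\n{decode(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@pair{i}/2\n{decode(self.r2[i])}\n+\n{qual}\n")

    def to_sam(self, path) -> int:
        """Write truth alignments as coordinate-unsorted SAM; origin-wrapping
        reads (circular references) are dropped.  Returns records written."""
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.ref_name, "LN": self.ref_len}],
        }
        n = 0
        rl = self.read_length
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i in range(self.n_pairs):
                for mate, (codes, start, reverse) in enumerate(
                    ((self.r1[i], self.start1[i], False), (self.r2[i], self.start2[i], True))
                ):
                    if start + rl > self.ref_len:
                        continue
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"pair{i}"
                    seg = codes if not reverse else (3 - codes)[::-1]
                    a.query_sequence = decode(seg)
                    a.reference_id = 0
                    a.reference_start = int(start)
                    a.cigarstring = f"{rl}M"
                    a.mapping_quality = 60
                    a.flag = (0x1 | 0x2) | (0x40 if mate == 0 else 0x80) | (
                        0x10 if reverse else 0x20
                    )
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    out.write(a)
                    n += 1
        return n


def simulate_short_reads(
    reference: str,
    n_pairs: int,
    read_length: int = 150,
    model: ErrorModel | None = None,
    seed: int = 0,
    insert_mean: int = 400,
    insert_sd: float = 40.0,
    circular: bool = True,
    ref_name: str = "ref",
) -> ShortReadSet:
    """Uniform wgsim-style paired-end sampling with substitution errors.

    Fragments are sampled uniformly on the (circular) reference; mates are
    the two fragment ends, read 2 reverse-complemented.  Substitution
    probabilities follow ``model.substitution_profile``; indel models are
    supported by :func:`simulate_long_reads`.
    """
    model = model or ErrorModel()
    if model.has_indels:
        raise ValueError(
            "simulate_short_reads models substitutions only; "
            "use simulate_long_reads for indel error structure"
        )
    n = len(reference)
    if read_length > n:
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(seed)
    ref = encode(reference)
    inserts = np.clip(
        np.round(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int),
        read_length,
        n,
    )
    if circular:
        start1 = rng.integers(0, n, n_pairs)
    else:
        start1 = rng.integers(0, np.maximum(n - inserts + 1, 1))
    start2 = start1 + inserts - read_length
    if not circular:
        start2 = np.minimum(start2, n - read_length)
    offs = np.arange(read_length)
    pos1 = (start1[:, None] + offs) % n
    pos2 = (start2[:, None] + offs) % n
    r1 = ref[pos1]
    r2 = (3 - ref[pos2])[:, ::-1]

    n_subs = 0
    p = model.substitution_profile(reference)
    if p.any():
        for mat, pos, flip in ((r1, pos1, False), (r2, pos2, True)):
            pr = p[pos]
            if flip:
                pr = pr[:, ::-1]
            hit = rng.random(mat.shape) < pr
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, n_hit).astype(np.uint8)
                mat[hit] = (mat[hit] + shift) % 4
            n_subs += n_hit
    return ShortReadSet(
        ref_name=ref_name,
        ref_len=n,
        read_length=read_length,
        circular=circular,
        r1=r1,
        r2=r2,
        start1=start1 % n,
        start2=start2 % n,
        n_injected_subs=n_subs,
    )


# ---------------------------------------------------------------------------
# long reads


@dataclass
class LongRead:
    name: str
    sequence: str
    ref_start: int
    cigar: str
    n_sub: int
    n_ins: int
    n_del: int


@dataclass
class LongReadSet:
    ref_name: str
    ref_len: int
    reads: list[LongRead]

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    def to_sam(self, path) -> int:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.ref_name, "LN": self.ref_len}],
        }
        n = 0
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.name
                a.query_sequence = r.sequence
                a.reference_id = 0
                a.reference_start = r.ref_start
                a.cigarstring = r.cigar
                a.mapping_quality = 60
                a.flag = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
                out.write(a)
                n += 1
        return n


def _cigar_from_masks(keep: np.ndarray, ins_after: np.ndarray) -> str:
    """CIGAR over template positions: deleted where ``~keep``, with
    ``ins_after[i]`` inserted bases following template position i."""
    ops: list[tuple[int, str]] = []

    def push(n: int, op: str) -> None:
        if n <= 0:
            return
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))

    run_start = 0
    events = np.nonzero((~keep) | (ins_after > 0))[0]
    for e in events:
        if keep[e]:
            push(e - run_start + 1, "M")
            push(int(ins_after[e]), "I")
        else:
            push(e - run_start, "M")
            push(1, "D")
            push(int(ins_after[e]), "I")
        run_start = e + 1
    push(len(keep) - run_start, "M")
    return "".join(f"{n}{op}" for n, op in ops)


def simulate_long_reads(
    reference: str,
    n_reads: int,
    mean_length: int = 3000,
    sd_length: float = 1000.0,
    model: ErrorModel | None = None,
    seed: int = 0,
    circular: bool = False,
    ref_name: str = "ref",
) -> LongReadSet:
    """Single-end long reads with substitution, insertion and deletion
    errors; deletion probability is inflated inside homopolymer tracts by
    ``repeat_deletion_slope`` per tract nt beyond the threshold."""
    model = model or ErrorModel()
    n = len(reference)
    rng = np.random.default_rng(seed)
    ref = encode(reference)
    sub_p = model.substitution_profile(reference)
    del_p = model.deletion_profile(reference)
    lengths = np.clip(
        np.round(rng.normal(mean_length, sd_length, n_reads)).astype(int), 200, n
    )
    if circular:
        starts = rng.integers(0, n, n_reads)
    else:
        starts = rng.integers(0, np.maximum(n - lengths + 1, 1))
        lengths = np.minimum(lengths, n - starts)
    reads: list[LongRead] = []
    for i in range(n_reads):
        tpos = (starts[i] + np.arange(lengths[i])) % n
        template = ref[tpos]
        keep = rng.random(lengths[i]) >= del_p[tpos]
        bases = template.copy()
        sub_hit = keep & (rng.random(lengths[i]) < sub_p[tpos])
        n_sub = int(sub_hit.sum())
        if n_sub:
            bases[sub_hit] = (bases[sub_hit] + rng.integers(1, 4, n_sub).astype(np.uint8)) % 4
        ins_after = np.zeros(lengths[i], dtype=int)
        if model.insertion_rate:
            ins_after[keep] = rng.random(int(keep.sum())) < model.insertion_rate
        # assemble read: kept bases with insertions (random base) interleaved
        parts: list[np.ndarray] = []
        if ins_after.any():
            idx = np.nonzero(ins_after)[0]
            prev = 0
            for j in idx:
                seg = bases[prev : j + 1][keep[prev : j + 1]]
                parts.append(seg)
                parts.append(rng.integers(0, 4, int(ins_after[j])).astype(np.uint8))
                prev = j + 1
            parts.append(bases[prev:][keep[prev:]])
            read_codes = np.concatenate(parts)
        else:
            read_codes = bases[keep]
        cigar = _cigar_from_masks(keep, ins_after)
        reads.append(
            LongRead(
                name=f"read{i}",
                sequence=decode(read_codes),
                ref_start=int(starts[i]),
                cigar=cigar,
                n_sub=n_sub,
                n_ins=int(ins_after.sum()),
                n_del=int((~keep).sum()),
            )
        )
    return LongReadSet(ref_name=ref_name, ref_len=n, reads=reads)


# ---------------------------------------------------------------------------
# count matrices


def simulate_count_matrix(
    n_features: int,
    n_samples: int,
    spike_features: int = 20,
    dispersion: float = 0.05,
    batch_effect_size: float = 1.0,
    fold_changes: float | np.ndarray = 1.0,
    seed: int = 0,
    base_mean: float = 500.0,
    depth_factors: np.ndarray | None = None,
    batch_samples: np.ndarray | None = None,
    batch_feature_scope: str = "spikes",
    n_evaluable: int = 0,
    conditions: np.ndarray | None = None,
    prep_noise_sd: float = 0.0,
):
    """Negative-binomial count matrix with spike-in controls.

    Features 0..spike_features-1 are controls, constant in expectation across
    samples.  The next ``n_evaluable`` features are spiked standards with
    known expected fold-changes between the two conditions (``fold_changes``
    scalar or per-evaluable-feature array); remaining features are endogenous
    background.  ``batch_effect_size`` multiplies counts of designated
    samples, for spiked features only (scope "spikes": controls + evaluable,
    emulating library-prep efficiency acting on spiked material) or for every
    feature (scope "all").  ``depth_factors`` scales whole samples.
    ``prep_noise_sd`` adds a per-sample lognormal prep-efficiency factor to
    the same feature scope — the continuous unwanted-variation structure
    spike-in normalization is meant to remove.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if batch_feature_scope not in ("spikes", "all"):
        raise ValueError("batch_feature_scope must be 'spikes' or 'all'")
    from .spikenorm import CountMatrix

    rng = np.random.default_rng(seed)
    if conditions is None:
        conditions = np.array(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2))
    conditions = np.asarray(conditions)
    if depth_factors is None:
        depth_factors = np.ones(n_samples)
    if batch_samples is None:
        batch_samples = np.zeros(n_samples, dtype=bool)
        batch_samples[1::2] = True
    batch_samples = np.asarray(batch_samples, dtype=bool)

    fc = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_evaluable,)).copy()
    base = rng.lognormal(np.log(base_mean), 0.6, n_features)
    mu = np.outer(base, depth_factors)
    is_b = conditions == "B"
    for j, f in enumerate(range(spike_features, spike_features + n_evaluable)):
        mu[f, is_b] *= fc[j]
    affected = np.zeros(n_features, dtype=bool)
    if batch_feature_scope == "all":
        affected[:] = True
    else:
        affected[: spike_features + n_evaluable] = True
    if batch_effect_size != 1.0:
        mu[np.ix_(affected, batch_samples)] *= batch_effect_size
    if prep_noise_sd > 0:
        prep = rng.lognormal(0.0, prep_noise_sd, n_samples)
        mu[affected] *= prep
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    feat_names = (
        [f"ctrl_{i}" for i in range(spike_features)]
        + [f"std_{i}" for i in range(n_evaluable)]
        + [f"bg_{i}" for i in range(n_features - spike_features - n_evaluable)]
    )
    df = pd.DataFrame(
        counts, index=feat_names, columns=[f"s{i}" for i in range(n_samples)]
    )
    meta = pd.DataFrame(
        {
            "is_control": [n.startswith("ctrl_") for n in feat_names],
            "expected_lfc": [np.nan] * n_features,
        },
        index=feat_names,
    )
    for j in range(n_evaluable):
        meta.loc[f"std_{j}", "expected_lfc"] = np.log2(fc[j])
    return CountMatrix(
        counts=df,
        feature_meta=meta,
        conditions=pd.Series(conditions, index=df.columns),
    )


# ---------------------------------------------------------------------------
# peptide quantification


def simulate_peptide_quant(
    design: PlasmidDesign | dict[str, str],
    protein_abundances: dict[str, float] | None = None,
    response_factor_sd: float = 0.0,
    missed_cleavage_fraction: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    replicate_noise_sd: float = 0.02,
    response_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Peptide quantification table (protein, peptide, replicate, quantity).

    quantity = copy_number x protein_abundance x response_factor(peptide)
    x lognormal replicate noise.  Response factors are lognormal(0, sd) per
    peptide *sequence* and shared across replicates and proteins (the
    structure behind high replicate-to-replicate reproducibility despite
    poor cross-peptide quantification); explicit ``response_factors`` win
    over sampling.  A fraction ``missed_cleavage_fraction`` of each
    protein's signal is reassigned to 1-missed-cleavage merges, so the
    expected fully-cleaved proportion is exactly the complement.
    """
    if response_factor_sd < 0:
        raise ValueError("response_factor_sd must be >= 0")
    if not 0 <= missed_cleavage_fraction < 1:
        raise ValueError("missed_cleavage_fraction must be in [0, 1)")
    from .designer import proco_proteins

    if isinstance(design, PlasmidDesign):
        proteins = {
            name: info["protein"] for name, info in proco_proteins(design).items()
        }
    else:
        proteins = dict(design)
    protein_abundances = protein_abundances or {p: 1.0 for p in proteins}
    rng = np.random.default_rng(seed)
    rf: dict[str, float] = dict(response_factors or {})

    def factor(pep: str) -> float:
        if pep not in rf:
            rf[pep] = (
                float(rng.lognormal(0.0, response_factor_sd))
                if response_factor_sd > 0
                else 1.0
            )
        return rf[pep]

    rows = []
    for prot, seq in proteins.items():
        abund = protein_abundances.get(prot, 1.0)
        full = [p for p in trypsin_digest(seq, prot, max_missed=0)]
        merged = [
            p for p in trypsin_digest(seq, prot, max_missed=1) if p.missed_cleavages == 1
        ]
        q_full: dict[str, float] = {}
        for p in full:
            q_full[p.sequence] = q_full.get(p.sequence, 0.0) + abund * factor(p.sequence)
        total = sum(q_full.values())
        m = missed_cleavage_fraction
        q_partial: dict[str, float] = {}
        if m > 0 and merged:
            w = {}
            for p in merged:
                w[p.sequence] = w.get(p.sequence, 0.0) + 1.0
            wsum = sum(w.values())
            for s, wv in w.items():
                q_partial[s] = m * total * wv / wsum
            q_full = {s: v * (1 - m) for s, v in q_full.items()}
        for rep in range(1, replicates + 1):
            for s, v in list(q_full.items()) + list(q_partial.items()):
                noise = (
                    float(rng.lognormal(0.0, replicate_noise_sd))
                    if replicate_noise_sd > 0
                    else 1.0
                )
                rows.append((prot, s, rep, v * noise))
    return pd.DataFrame(rows, columns=["protein", "peptide", "replicate", "quantity"])
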