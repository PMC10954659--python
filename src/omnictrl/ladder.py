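"""Copy-number ladder analysis of the conu gene families.

Canonical 31-mers unique to each family are counted exactly in reads
(counts for a k-mer and its reverse complement are combined), normalized by
mean k-mer depth so the expectation equals the copy number, and fit against
the known copy numbers; the coefficient of variation of copy-normalized
counts measures quantitative precision, and cross-condition copy-number
pairs give an expected-vs-observed fold-change benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designspec import PlasmidDesign
from .dna import canonical, kmer_code, kmers, revcomp


@dataclass
class FamilyMap:
    """Canonical k-mer -> conu family lookup; k-mers shared between families
    are dropped."""

    k: int
    families: list[str]  # family name per group
    copy_numbers: dict[str, int]
    codes: np.ndarray  # sorted uint64 canonical codes
    family_idx: np.ndarray  # aligned family index per code

    @property
    def n_kmers(self) -> int:
        return len(self.codes)


def build_family_map(
    design_or_units, k: int = 31
) -> FamilyMap:
    """Family map from a design's conu units (or an explicit list of units)."""
    if isinstance(design_or_units, PlasmidDesign):
        units = [u for u in design_or_units.units if u.klass == "conu"]
    else:
        units = list(design_or_units)
    if not units:
        raise ValueError("no conu units available")
    seen: dict[int, int] = {}
    shared: set[int] = set()
    families = [u.name for u in units]
    for fi, u in enumerate(units):
        if len(u.sequence) < k:
            raise ValueError(f"{u.name} shorter than k={k}")
        for km in set(kmers(u.sequence, k)):
            code = kmer_code(canonical(km))
            if code in seen and seen[code] != fi:
                shared.add(code)
            else:
                seen[code] = fi
    items = sorted((c, f) for c, f in seen.items() if c not in shared)
    codes = np.array([c for c, _ in items], dtype=np.uint64)
    fidx = np.array([f for _, f in items], dtype=np.int64)
    return FamilyMap(
        k=k,
        families=families,
        copy_numbers={u.name: u.copy_number for u in units},
        codes=codes,
        family_idx=fidx,
    )


@dataclass
class KmerCounts:
    family_map: FamilyMap
    counts: np.ndarray  # aligned to family_map.codes

    def per_family(self) -> dict[str, np.ndarray]:
        return {
            name: self.counts[self.family_map.family_idx == fi]
            for fi, name in enumerate(self.family_map.families)
        }

    def normalized(self, depth: float) -> dict[str, np.ndarray]:
        return normalize_counts(self, depth)


def _rolling_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """(n_reads, L-k+1) uint64 2-bit codes of every k-mer window."""
    n, L = mat.shape
    out = np.zeros((n, L - k + 1), dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    code = np.zeros(n, dtype=np.uint64)
    m64 = mat.astype(np.uint64)
    for j in range(L):
        code = ((code << np.uint64(2)) | m64[:, j]) & mask
        if j >= k - 1:
            out[:, j - k + 1] = code
    return out


def _count_matrix_chunk(
    mat: np.ndarray, fmap: FamilyMap, counts: np.ndarray
) -> None:
    k = fmap.k
    fwd = _rolling_codes(mat, k)
    rc = _rolling_codes((3 - mat)[:, ::-1], k)[:, ::-1]
    canon = np.minimum(fwd, rc).ravel()
    idx = np.searchsorted(fmap.codes, canon)
    idx[idx == len(fmap.codes)] = 0 if len(fmap.codes) else 0
    valid = fmap.codes[idx] == canon
    if valid.any():
        counts += np.bincount(idx[valid], minlength=len(fmap.codes))


def count_canonical_kmers(
    reads, family_map: FamilyMap, chunk: int = 100_000
) -> KmerCounts:
    """Exact canonical k-mer counts restricted to the family map.

    ``reads`` may be a ShortReadSet (vectorized path), a LongReadSet, or any
    iterable of sequence strings.  Reads shorter than k contribute nothing
    (with a warning).
    """
    fmap = family_map
    counts = np.zeros(fmap.n_kmers, dtype=np.int64)
    from .readsim import LongReadSet, ShortReadSet

    if isinstance(reads, ShortReadSet):
        if fmap.k > reads.read_length:
            warnings.warn("k exceeds read length; zero counts")
            return KmerCounts(fmap, counts)
        for mat in reads.iter_read_matrices():
            for a in range(0, len(mat), chunk):
                _count_matrix_chunk(mat[a : a + chunk], fmap, counts)
        return KmerCounts(fmap, counts)
    if isinstance(reads, LongReadSet):
        reads = (r.sequence for r in reads.reads)
    code_to_pos = {int(c): i for i, c in enumerate(fmap.codes)}
    short = 0
    for seq in reads:
        if len(seq) < fmap.k:
            short += 1
            continue
        for km in kmers(seq, fmap.k):
            pos = code_to_pos.get(kmer_code(canonical(km)))
            if pos is not None:
                counts[pos] += 1
    if short:
        warnings.warn(f"{short} reads shorter than k={fmap.k} skipped")
    return KmerCounts(fmap, counts)


def count_kmers_exact(seqs, k: int) -> dict[str, int]:
    """Plain-dict canonical k-mer counter (independent oracle for the
    vectorized path; fine for small inputs)."""
    out: dict[str, int] = {}
    for seq in seqs:
        for km in kmers(seq, k):
            c = canonical(km)
            out[c] = out.get(c, 0) + 1
    return out


def normalize_counts(
    counts: KmerCounts | dict[str, np.ndarray], reference_mean_depth: float
) -> dict[str, np.ndarray]:
    """Divide per-k-mer counts by the mean k-mer depth of the library so a
    single-copy k-mer has expectation 1 and a cn-copy k-mer expectation cn."""
    if reference_mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    per_family = (
        counts.per_family() if isinstance(counts, KmerCounts) else dict(counts)
    )
    return {f: np.asarray(c, dtype=float) / reference_mean_depth for f, c in per_family.items()}


@dataclass
class LadderFit:
    slope: float
    intercept: float
    r2: float
    successive_ratios: list[float]  # mean(cn_{i+1}) / mean(cn_i), cn ascending
    cov: float  # SD/mean of pooled copy-normalized counts
    family_means: dict[str, float]
    copy_numbers: dict[str, int]


def ladder_fit(
    normalized: dict[str, np.ndarray], copy_numbers: dict[str, int]
) -> LadderFit:
    """Least-squares fit of normalized k-mer counts against copy number."""
    if len(normalized) < 2:
        raise ValueError("need at least two families")
    normalized = dict(normalized)
    for name in list(normalized):
        if np.sum(normalized[name]) == 0:
            warnings.warn(f"family {name} has zero counts; excluded from fit")
            del normalized[name]
    x = np.concatenate(
        [np.full(len(v), copy_numbers[f]) for f, v in normalized.items()]
    )
    y = np.concatenate(list(normalized.values()))
    fit = stats.linregress(x, y)
    by_cn = sorted(normalized.items(), key=lambda kv: copy_numbers[kv[0]])
    means = {f: float(np.mean(v)) for f, v in by_cn}
    vals = [means[f] for f, _ in by_cn]
    ratios = [vals[i + 1] / vals[i] for i in range(len(vals) - 1)]
    pooled = np.concatenate(
        [v / copy_numbers[f] for f, v in normalized.items()]
    )
    cov = float(np.std(pooled, ddof=1) / np.mean(pooled))
    return LadderFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        successive_ratios=ratios,
        cov=cov,
        family_means=means,
        copy_numbers={f: copy_numbers[f] for f in normalized},
    )


def fold_change_benchmark(
    counts_a: pd.Series | dict[str, float],
    counts_b: pd.Series | dict[str, float],
    copy_numbers: dict[str, int],
) -> pd.DataFrame:
    """Cross-condition copy-number fold-change benchmark.

    For every ordered family pair (i in condition A, j in condition B) the
    expected log2 fold-change is log2(cn_j / cn_i); both directions are
    reported.  Zero counts receive a 0.5 pseudocount and are flagged.
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    rows = []
    for fa in copy_numbers:
        for fb in copy_numbers:
            if fa == fb:
                continue
            ca, cb = a.get(fa, 0.0), b.get(fb, 0.0)
            pseudo = ca == 0 or cb == 0
            ca, cb = max(ca, 0.5) if pseudo else ca, max(cb, 0.5) if pseudo else cb
            expected = float(np.log2(copy_numbers[fb] / copy_numbers[fa]))
            observed = float(np.log2(cb / ca))
            rows.append(
                {
                    "family_a": fa,
                    "family_b": fb,
                    "cn_a": copy_numbers[fa],
                    "cn_b": copy_numbers[fb],
                    "expected_lfc": expected,
                    "observed_lfc": observed,
                    "deviation": observed - expected,
                    "pseudocount": pseudo,
                }
            )
    return pd.DataFrame(rows)
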