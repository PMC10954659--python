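"""Per-position and per-k-mer sequencing error profiles from alignments.

The per-position profile counts, at every reference position, the covering
reads and the reads carrying a mismatch, insertion or deletion there —
relative frequency = error reads / covering reads.  The k-mer table slides a
6-mer window along the reference and averages the per-base error frequency
across the window's bases, then summarizes every distinct 6-mer by its
coverage-weighted mean across windows.  Reverse-complement-palindromic
6-mers serve as the inverted-repeat (hairpin-proxy) class.

Conventions: primary alignments only; soft-clipped bases excluded from both
numerator and denominator; deletions attributed to the deleted reference
positions, insertions to the reference position following the anchor base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dna import encode, gc_fraction, homopolymer_runs, is_rc_palindrome


@dataclass
class ErrorProfile:
    ref_name: str
    reference: str
    coverage: np.ndarray
    mismatch: np.ndarray
    insertion: np.ndarray
    deletion: np.ndarray

    def _freq(self, counts: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / self.coverage
        f[self.coverage == 0] = np.nan
        return f

    @property
    def mismatch_freq(self) -> np.ndarray:
        return self._freq(self.mismatch)

    @property
    def insertion_freq(self) -> np.ndarray:
        return self._freq(self.insertion)

    @property
    def deletion_freq(self) -> np.ndarray:
        return self._freq(self.deletion)

    @property
    def total_freq(self) -> np.ndarray:
        return self._freq(self.mismatch + self.insertion + self.deletion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos": np.arange(len(self.reference)),
                "coverage": self.coverage,
                "mismatch_freq": self.mismatch_freq,
                "insertion_freq": self.insertion_freq,
                "deletion_freq": self.deletion_freq,
            }
        )


def _load_reference(reference) -> tuple[str, str]:
    """Accept a raw sequence or a FASTA path; return (name, sequence)."""
    if isinstance(reference, str) and os.path.exists(reference):
        from Bio import SeqIO

        rec = next(SeqIO.parse(reference, "fasta"))
        return rec.id, str(rec.seq).upper()
    return "ref", str(reference).upper()


def per_position_profile(
    alignments,
    reference,
    region: tuple[int, int] | None = None,
) -> ErrorProfile:
    """Pileup-equivalent error counts from a SAM/BAM file.

    ``alignments`` is a path or an open pysam.AlignmentFile; ``reference``
    a sequence string or FASTA path matching the alignment header.
    """
    import pysam

    ref_name, ref_seq = _load_reference(reference)
    ref = encode(ref_seq)
    n = len(ref)
    own = isinstance(alignments, (str, os.PathLike))
    af = pysam.AlignmentFile(alignments, check_sq=False) if own else alignments
    try:
        sq = {s["SN"]: s["LN"] for s in af.header.to_dict().get("SQ", [])}
        if sq:
            (name, length), *_ = sq.items()
            if length != n:
                raise ValueError(
                    f"reference length {n} does not match header {name}:{length}"
                )
            ref_name = name
        coverage = np.zeros(n, dtype=np.int64)
        mismatch = np.zeros(n, dtype=np.int64)
        insertion = np.zeros(n, dtype=np.int64)
        deletion = np.zeros(n, dtype=np.int64)
        for a in af:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            rs = a.reference_start
            q = encode(a.query_sequence) if a.query_sequence else None
            qi = 0
            for op, ln in a.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    coverage[rs : rs + ln] += 1
                    if q is not None:
                        seg = q[qi : qi + ln]
                        diff = np.nonzero(seg != ref[rs : rs + ln])[0]
                        if diff.size:
                            np.add.at(mismatch, rs + diff, 1)
                    rs += ln
                    qi += ln
                elif op == 1:  # I -> position following the anchor base
                    if rs < n:
                        insertion[rs] += 1
                    qi += ln
                elif op == 2:  # D -> the deleted reference positions
                    deletion[rs : rs + ln] += 1
                    coverage[rs : rs + ln] += 1
                    rs += ln
                elif op == 4:  # soft clip: excluded entirely
                    qi += ln
                elif op == 3:  # N
                    rs += ln
                elif op == 5:  # H
                    pass
    finally:
        if own:
            af.close()
    if region is not None:
        a, b = region
        sl = slice(a, b)
        return ErrorProfile(
            ref_name, ref_seq[sl], coverage[sl], mismatch[sl], insertion[sl], deletion[sl]
        )
    return ErrorProfile(ref_name, ref_seq, coverage, mismatch, insertion, deletion)


def kmer_windows(profile: ErrorProfile, k: int = 6) -> pd.DataFrame:
    """One row per sliding k-mer window: per-base error frequencies averaged
    across the window."""
    seq = profile.reference
    n = len(seq)
    if k > n:
        raise ValueError("k exceeds reference length")
    cov = profile.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(cov > 0, profile.mismatch / cov, np.nan)
        ins = np.where(cov > 0, profile.insertion / cov, np.nan)
        de = np.where(cov > 0, profile.deletion / cov, np.nan)

    def winmean(x: np.ndarray) -> np.ndarray:
        mat = np.lib.stride_tricks.sliding_window_view(x, k)
        return np.nanmean(mat, axis=1)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        w_mm, w_ins, w_del = winmean(mm), winmean(ins), winmean(de)
        w_cov = winmean(cov)
    kmers = [seq[i : i + k] for i in range(n - k + 1)]
    tract_len = np.zeros(n - k + 1, dtype=int)
    for start, run, _base in homopolymer_runs(seq, k):
        lo, hi = start, start + run - k  # windows fully inside the tract
        tract_len[lo : hi + 1] = run
    gc = np.array([gc_fraction(km) for km in kmers])
    return pd.DataFrame(
        {
            "pos": np.arange(n - k + 1),
            "kmer": kmers,
            "coverage": w_cov,
            "mismatch_freq": w_mm,
            "insertion_freq": w_ins,
            "deletion_freq": w_del,
            "mean_error": w_mm + w_ins + w_del,
            "gc": gc,
            "tract_length": tract_len,
            "in_repeat": tract_len > 0,
        }
    )


def kmer_error_table(
    profile: ErrorProfile, reference=None, k: int = 6
) -> pd.DataFrame:
    """Coverage-weighted per-distinct-k-mer error summary, ranked by
    mean_error (ties broken lexicographically, stable)."""
    win = kmer_windows(profile, k)
    win = win.dropna(subset=["mean_error"])

    def agg(g: pd.DataFrame) -> pd.Series:
        w = g["coverage"].to_numpy()
        if w.sum() <= 0:
            w = np.ones(len(g))
        return pd.Series(
            {
                "mean_error": np.average(g["mean_error"], weights=w),
                "mismatch_freq": np.average(g["mismatch_freq"], weights=w),
                "insertion_freq": np.average(g["insertion_freq"], weights=w),
                "deletion_freq": np.average(g["deletion_freq"], weights=w),
                "coverage": w.mean(),
                "n_windows": len(g),
                "gc": g["gc"].iloc[0],
                "tract_length": g["tract_length"].max(),
            }
        )

    table = win.groupby("kmer", sort=True).apply(agg, include_groups=False)
    table["in_repeat"] = table["tract_length"] > 0
    table["is_palindrome"] = [is_rc_palindrome(km) for km in table.index]
    return table.sort_values(
        ["mean_error"], ascending=False, kind="stable"
    )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    n: int
    degenerate: bool  # fewer than 3 covariate levels


def regress_error_vs_covariate(
    table: pd.DataFrame, covariate: str = "gc", response: str = "mean_error"
) -> RegressionFit:
    """Ordinary least squares of the error rate on a covariate ('gc' or
    'tract_length'/'repeat_length' on aggregated tables)."""
    if covariate == "repeat_length":
        covariate = "tract_length"
    df = table.dropna(subset=[covariate, response])
    x = df[covariate].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("covariate is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(x),
        degenerate=levels.size < 3,
    )


def aggregate_regions(
    profile: ErrorProfile, regions: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Mean error frequencies over named reference intervals (e.g. one row
    per GC-content probe gene)."""
    rows = []
    for name, a, b in regions:
        cov = profile.coverage[a:b]
        ok = cov > 0
        if not ok.any():
            continue
        rows.append(
            {
                "region": name,
                "gc": gc_fraction(profile.reference[a:b]),
                "mean_error": float(np.mean(profile.total_freq[a:b][ok])),
                "mismatch_freq": float(np.mean(profile.mismatch_freq[a:b][ok])),
                "deletion_freq": float(np.mean(profile.deletion_freq[a:b][ok])),
                "coverage": float(cov.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def aggregate_repeat_tracts(
    profile: ErrorProfile, min_len: int = 6
) -> pd.DataFrame:
    """Mean error frequencies per homopolymer tract of at least ``min_len``
    (one row per tract; covariate for the repeat-length regression)."""
    rows = []
    for start, run, base in homopolymer_runs(profile.reference, min_len):
        cov = profile.coverage[start : start + run]
        ok = cov > 0
        if not ok.any():
            continue
        rows.append(
            {
                "start": start,
                "base": base,
                "tract_length": run,
                "mean_error": float(np.mean(profile.total_freq[start : start + run][ok])),
                "deletion_freq": float(
                    np.mean(profile.deletion_freq[start : start + run][ok])
                ),
                "coverage": float(cov.mean()),
            }
        )
    return pd.DataFrame(rows)


def compare_profiles(
    numerator: pd.DataFrame,
    denominator: pd.DataFrame,
    pseudo: float = 1e-4,
) -> pd.DataFrame:
    """Per-k-mer fold enrichment (num + pseudo)/(den + pseudo), e.g. RNA
    errors normalized against matched DNA sequencing errors.  Palindromic
    k-mers form the inverted-repeat (hairpin-proxy) class."""
    common = numerator.index.intersection(denominator.index)
    if common.empty:
        raise ValueError("k-mer tables share no k-mers")
    num = numerator.loc[common, "mean_error"]
    den = denominator.loc[common, "mean_error"]
    if pseudo <= 0 and (den == 0).any():
        raise ValueError("zero denominator error rates require pseudo > 0")
    out = pd.DataFrame(
        {
            "numerator_error": num,
            "denominator_error": den,
            "enrichment": (num + pseudo) / (den + pseudo),
            "is_palindrome": [is_rc_palindrome(km) for km in common],
        },
        index=common,
    )
    return out


def class_enrichment(comparison: pd.DataFrame) -> dict[str, float]:
    """Median enrichment for palindromic vs non-palindromic k-mers."""
    pal = comparison[comparison["is_palindrome"]]["enrichment"]
    non = comparison[~comparison["is_palindrome"]]["enrichment"]
    return {
        "palindrome_median": float(pal.median()) if len(pal) else float("nan"),
        "other_median": float(non.median()) if len(non) else float("nan"),
    }
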