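"""Per-position / per-k-mer error profiling and the GC, repeat and hairpin
analyses, on simulated alignments with known injected error structure."""

import numpy as np
import pandas as pd
import pytest

from omnictrl.dna import revcomp
from omnictrl.readsim import ErrorModel, simulate_long_reads, simulate_short_reads
from omnictrl.seqprofile import (
    aggregate_regions,
    aggregate_repeat_tracts,
    class_enrichment,
    compare_profiles,
    kmer_error_table,
    kmer_windows,
    per_position_profile,
    regress_error_vs_covariate,
)

RNG = np.random.default_rng(21)
REF = "".join(RNG.choice(list("ACGT"), 2000))


def profile_from_sim(ref, model, n_pairs=2000, seed=0, read_length=100):
    rs = simulate_short_reads(
        ref, n_pairs, read_length, model, seed=seed, circular=False
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        sam = os.path.join(td, "truth.sam")
        rs.to_sam(sam)
        return per_position_profile(sam, ref)


class TestPerPosition:
    def test_error_free_all_zero(self):
        prof = profile_from_sim(REF, ErrorModel(), n_pairs=300)
        ok = prof.coverage > 0
        assert np.nansum(prof.mismatch_freq[ok]) == 0
        assert np.nansum(prof.insertion_freq[ok]) == 0
        assert np.nansum(prof.deletion_freq[ok]) == 0

    def test_definitional_mismatch_frequency(self, tmp_path):
        """100 covering reads, 7 carrying a mismatch at one position."""
        import pysam

        ref = REF[:200]
        sam = tmp_path / "toy.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 200}]}
        with pysam.AlignmentFile(sam, "w", header=header) as out:
            for i in range(100):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{i}"
                seq = list(ref[50:150])
                if i < 7:
                    seq[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[25]]
                a.query_sequence = "".join(seq)
                a.reference_id = 0
                a.reference_start = 50
                a.cigarstring = "100M"
                a.flag = 0
                out.write(a)
        prof = per_position_profile(str(sam), ref)
        assert prof.coverage[75] == 100
        assert prof.mismatch_freq[75] == pytest.approx(0.07)

    def test_uniform_substitution_recovery(self):
        prof = profile_from_sim(
            REF, ErrorModel(substitution_rate=0.01), n_pairs=10_000
        )
        ok = prof.coverage > 100
        assert np.mean(prof.mismatch_freq[ok]) == pytest.approx(0.01, abs=0.001)

    def test_reference_length_mismatch_rejected(self, tmp_path):
        rs = simulate_short_reads(REF, 10, 50, seed=1, circular=False)
        sam = tmp_path / "t.sam"
        rs.to_sam(sam)
        with pytest.raises(ValueError, match="length"):
            per_position_profile(str(sam), REF[:500])

    def test_deletions_and_insertions_attributed(self, tmp_path):
        model = ErrorModel(insertion_rate=0.005, deletion_rate=0.01)
        ls = simulate_long_reads(REF, 400, 1500, 300, model, seed=2)
        sam = tmp_path / "long.sam"
        ls.to_sam(sam)
        prof = per_position_profile(str(sam), REF)
        ok = prof.coverage > 50
        assert np.mean(prof.deletion_freq[ok]) == pytest.approx(0.01, abs=0.002)
        assert np.mean(prof.insertion_freq[ok]) == pytest.approx(0.005, abs=0.002)


class TestKmerTable:
    def test_window_count(self):
        prof = profile_from_sim(REF[:300], ErrorModel(), n_pairs=200)
        win = kmer_windows(prof, k=6)
        assert len(win) == 300 - 6 + 1

    def test_uniform_error_uniform_kmers(self):
        prof = profile_from_sim(REF, ErrorModel(substitution_rate=0.02), n_pairs=8000)
        table = kmer_error_table(prof, k=6)
        assert table["mean_error"].mean() == pytest.approx(0.02, abs=0.004)
        assert table["mean_error"].std() < 0.02

    def test_weighted_mean_matches_bruteforce(self):
        prof = profile_from_sim(REF[:400], ErrorModel(substitution_rate=0.05), n_pairs=500)
        win = kmer_windows(prof, k=6).dropna(subset=["mean_error"])
        table = kmer_error_table(prof, k=6)
        km = win["kmer"].iloc[10]
        sub = win[win["kmer"] == km]
        want = np.average(sub["mean_error"], weights=sub["coverage"])
        assert table.loc[km, "mean_error"] == pytest.approx(want)

    def test_override_recovery_within_binomial_error(self):
        """Injected per-6-mer substitution overrides recovered at ~1000x."""
        hi, lo = "TCTTGT", "ACTTGA"
        ref = REF[:1000] + hi + REF[1000:1500] + lo + REF[1500:2000]
        model = ErrorModel(
            substitution_rate=0.002,
            per_kmer_overrides={hi: 0.12, lo: 0.0006},
        )
        prof = profile_from_sim(ref, model, n_pairs=12_000, seed=5)
        table = kmer_error_table(prof, k=6)
        for km, rate in ((hi, 0.12), (lo, 0.0006)):
            got = table.loc[km, "mean_error"]
            n = table.loc[km, "coverage"] * 6
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(got - rate) < 3 * se + 1e-9

    def test_ranking_spread(self):
        model = ErrorModel(
            substitution_rate=0.001, per_kmer_overrides={"TCTTGT": 0.12}
        )
        ref = REF[:800] + "TCTTGT" + REF[800:1600]
        prof = profile_from_sim(ref, model, n_pairs=10_000, seed=6)
        table = kmer_error_table(prof, k=6)
        assert table.index[0] == "TCTTGT"
        assert table["mean_error"].iloc[0] / table["mean_error"].median() > 20


class TestRegressions:
    def test_gc_slope_recovery(self):
        model = ErrorModel(substitution_rate=0.002, gc_error_slope=0.05)
        gc_levels = [0.2, 0.35, 0.5, 0.65, 0.8]
        from omnictrl.dna import random_dna

        rng = np.random.default_rng(3)
        genes = [random_dna(rng, 600, gc=g) for g in gc_levels]
        ref = "".join(genes)
        prof = profile_from_sim(ref, model, n_pairs=15_000, seed=7)
        regions = []
        pos = 0
        for i, g in enumerate(genes):
            regions.append((f"g{i}", pos, pos + len(g)))
            pos += len(g)
        agg = aggregate_regions(prof, regions)
        fit = regress_error_vs_covariate(agg, "gc")
        assert fit.r2 > 0.9
        assert fit.slope == pytest.approx(0.05, rel=0.3)

    def test_repeat_length_deletion_recovery(self):
        model = ErrorModel(deletion_rate=0.002, repeat_deletion_slope=0.01)
        rng = np.random.default_rng(4)
        from omnictrl.dna import random_dna

        parts = []
        for n in (6, 9, 12, 18):
            for base in "AC":
                parts.append(random_dna(rng, 80, forbidden=(), max_homopolymer=4))
                parts.append(base * n)
        parts.append(random_dna(rng, 80, max_homopolymer=4))
        ref = "".join(parts)
        ls = simulate_long_reads(ref, 3000, len(ref), 1, model, seed=8, circular=False)
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            sam = os.path.join(td, "r.sam")
            ls.to_sam(sam)
            prof = per_position_profile(sam, ref)
        tracts = aggregate_repeat_tracts(prof, min_len=6)
        fit = regress_error_vs_covariate(tracts, "repeat_length", "deletion_freq")
        assert fit.r2 > 0.9
        assert fit.slope == pytest.approx(0.01, rel=0.35)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"gc": [0.5, 0.5], "mean_error": [0.1, 0.2]})
        with pytest.raises(ValueError, match="constant"):
            regress_error_vs_covariate(df, "gc")

    def test_two_points_degenerate_perfect_fit(self):
        df = pd.DataFrame({"gc": [0.2, 0.8], "mean_error": [0.01, 0.05]})
        fit = regress_error_vs_covariate(df, "gc")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.degenerate


class TestCompare:
    def _table(self, errs):
        return pd.DataFrame(
            {"mean_error": errs.values()}, index=list(errs.keys())
        )

    def test_identical_tables_unity(self):
        t = self._table({"AAAAAA": 0.01, "ACGTAC": 0.02})
        cmp_ = compare_profiles(t, t, pseudo=1e-4)
        assert np.allclose(cmp_["enrichment"], 1.0)

    def test_palindrome_class_enrichment(self):
        kmers = ["ACTAGT", "CTGCAG", "GAATTC", "AAAAAA", "ACGTAA", "TTTGGG"]
        den = self._table({k: 0.01 for k in kmers})
        num_vals = {
            k: 0.1 if k == revcomp(k) else 0.01 for k in kmers
        }
        cmp_ = compare_profiles(self._table(num_vals), den, pseudo=1e-5)
        med = class_enrichment(cmp_)
        assert med["palindrome_median"] == pytest.approx(10, rel=0.01)
        assert med["other_median"] == pytest.approx(1, rel=0.01)

    def test_zero_denominator_guard(self):
        t = self._table({"AAAAAA": 0.0})
        with pytest.raises(ValueError):
            compare_profiles(self._table({"AAAAAA": 0.1}), t, pseudo=0.0)

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles(
                self._table({"AAAAAA": 0.1}), self._table({"CCCCCC": 0.1})
            )
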