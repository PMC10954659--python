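"""Gene generators, assembly and design validation."""

import pytest

from omnictrl import (
    DesignSpec,
    assemble,
    design_proco,
    generate_conu,
    generate_gece,
    generate_repe,
    split_conu,
    validate,
)
from omnictrl.designspec import PlasmidDesign
from omnictrl.dna import gc_fraction, homopolymer_runs, kmer_set, longest_homopolymer
from omnictrl.enzymes import forbidden_motifs
from omnictrl.insilico import trypsin_digest
from omnictrl.kcover import build_kmer_universe, generate_kmer_cover
from omnictrl.peptides import default_peptide_pool

SPEC = DesignSpec(seed=7)
FORBIDDEN = forbidden_motifs(SPEC.enzymes)


class TestSplitConu:
    def test_kmer_union_preserved(self):
        cover = generate_kmer_cover(build_kmer_universe(6), seed=0)
        units = split_conu(cover, 4, [1, 2, 3, 4])
        union = set()
        for u in units:
            union |= kmer_set(u.sequence, 6)
        assert union == kmer_set(cover, 6)
        # near-equal unit lengths with 5-base overlaps
        lengths = [len(u.sequence) for u in units]
        assert max(lengths) - min(lengths) <= 6
        assert sum(lengths) == len(cover) + 3 * 5

    def test_copy_number_assignment(self):
        units = generate_conu(SPEC)
        assert [u.copy_number for u in units] == [1, 2, 3, 4]
        assert sum(u.copy_number for u in units) == 10

    def test_identity_split(self):
        cover = generate_kmer_cover(build_kmer_universe(4), seed=0)
        (unit,) = split_conu(cover, 1, [1], k=4)
        assert unit.sequence == cover

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            split_conu("ACGTAC", 4, [1, 2, 3, 4])


class TestGece:
    def test_targets_realized(self):
        units = generate_gece(SPEC)
        assert len(units) == 6
        gcs = sorted(gc_fraction(u.sequence) for u in units)
        for got, want in zip(gcs, sorted(SPEC.gece_gc_targets)):
            assert abs(got - want) <= 0.01
        for u in units:
            assert longest_homopolymer(u.sequence) <= 5
            assert not any(m in u.sequence for m in FORBIDDEN)

    def test_empty_targets(self):
        assert generate_gece(DesignSpec(gece_gc_targets=(), seed=1)) == []

    def test_infeasible_length_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_gece(DesignSpec(gece_gc_targets=(0.215,), gece_length=10, seed=1))


class TestRepe:
    def test_all_tracts_present_and_exact(self):
        units = generate_repe(SPEC)
        joined = "".join(u.sequence for u in units)
        runs = {(b, n) for _, n, b in homopolymer_runs(joined, 6)}
        expected = {(b, n) for n in (6, 9, 12, 18) for b in "ACGT"}
        assert expected == runs  # exact lengths: flanks break every tract
        assert longest_homopolymer(joined) == 18

    def test_gc_near_target(self):
        units = generate_repe(SPEC)
        joined = "".join(u.sequence for u in units)
        assert 0.42 <= gc_fraction(joined) <= 0.46
        assert not any(m in joined for m in FORBIDDEN)

    def test_single_length_gives_four_tracts(self):
        spec = DesignSpec(repe_homopolymer_lengths=(7,), seed=3)
        units = generate_repe(spec)
        joined = "".join(u.sequence for u in units)
        runs = [(b, n) for _, n, b in homopolymer_runs(joined, 7)]
        assert sorted(runs) == [("A", 7), ("C", 7), ("G", 7), ("T", 7)]

    def test_infeasible_gc_rejected(self):
        with pytest.raises(ValueError, match="achievable"):
            generate_repe(DesignSpec(repe_gc_target=0.95, seed=1))


class TestProco:
    def test_tiling_scheme(self):
        units = design_proco(default_peptide_pool(), SPEC)
        assert len(units) == 3
        shared = None
        for u in units:
            assert len(u.peptide_tiles) == 23  # 9*1 + 2 + 4 + 8
            assert len(set(u.peptide_tiles)) == 12
            for a, b in zip(u.peptide_tiles, u.peptide_tiles[1:]):
                assert a != b, "serial repetition"
            assert u.peptide_tiles[-1].startswith("M")
            shared = shared or u.peptide_tiles[-1]
            assert u.peptide_tiles[-1] == shared

    def test_copy_scheme_molar_proportions(self):
        units = design_proco(default_peptide_pool(), SPEC)
        for u in units:
            counts = u.meta["copy_numbers"]
            assert sorted(counts.values()) == [1] * 9 + [2, 4, 8]
            top = max(counts, key=counts.get)
            assert u.peptide_tiles.count(top) == 8
            assert 8 / 23 == pytest.approx(0.347826, abs=1e-5)

    def test_tryptic_round_trip(self):
        units = design_proco(default_peptide_pool(), SPEC)
        for u in units:
            protein = u.meta["protein"]
            peps = sorted(p.sequence for p in trypsin_digest(protein))
            assert peps == sorted(list(u.peptide_tiles) + u.meta["tag_peptides"])
            assert not any(m in u.sequence for m in FORBIDDEN)

    def test_non_tryptic_pool_rejected(self):
        with pytest.raises(ValueError, match="fully tryptic"):
            design_proco(["MAAAAAAA"], SPEC)  # no terminal K/R

    def test_single_tile_gene(self):
        spec = DesignSpec(
            proco_count=1,
            proco_peptides_per_gene=1,
            proco_copy_scheme=((1, 1),),
            seed=1,
        )
        (unit,) = design_proco(["MAAWDETVK"], spec)
        assert unit.peptide_tiles == ("MAAWDETVK",)


class TestAssembleValidate:
    def test_default_design_valid(self, design, default_spec):
        report = validate(design, default_spec)
        assert report.passed, [c.detail for c in report.failures()]
        assert len(design.gene_features()) == 21

    def test_conu_copies_identical(self, design):
        by_name = {}
        for f in design.features_of("conu"):
            by_name.setdefault(f.name, []).append(design.feature_seq(f))
        assert sorted(len(v) for v in by_name.values()) == [1, 2, 3, 4]
        for seqs in by_name.values():
            assert len(set(seqs)) == 1

    def test_determinism(self, default_spec, design):
        again = assemble(DesignSpec(seed=default_spec.seed))
        assert again.sequence == design.sequence
        assert again.features == design.features

    def test_mutated_cover_fails_validation(self, design, default_spec):
        # knock out one conu base: some 6-mer disappears from the cover
        f = design.features_of("conu")[0]
        pos = f.start + 200
        base = design.sequence[pos]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        mutated = PlasmidDesign(
            design.sequence[:pos] + new + design.sequence[pos + 1:],
            design.features,
            design.provenance,
            design.units,
        )
        report = validate(mutated, default_spec)
        cover_check = next(c for c in report.checks if c.name == "conu_kmer_cover")
        assert not cover_check.passed
        assert "missing" in cover_check.detail

    def test_empty_units_backbone_only(self, default_spec):
        d = assemble(default_spec, units=[])
        assert len(d.gene_features()) == 0
        assert len(d.sequence) > 0
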