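"""Peptide quantification evaluation: cleavage classes, copy-number ladder,
reproducibility, physicochemical regression."""

import numpy as np
import pandas as pd
import pytest

from omnictrl.insilico import physicochem, trypsin_digest
from omnictrl.proteo import (
    annotate_peptides,
    cleavage_proportion,
    equal_abundance_check,
    property_regression,
    relative_abundance,
)
from omnictrl.readsim import simulate_peptide_quant

TOY = {"prot": "MAAAWDETKGLLSVHHRAPPLNQK"}


def toy_table(rows):
    return pd.DataFrame(rows, columns=["protein", "peptide", "replicate", "quantity"])


class TestAnnotate:
    def test_classes(self):
        t = toy_table(
            [
                ("prot", "MAAAWDETK", 1, 10.0),  # exact tryptic fragment
                ("prot", "MAAAWDETKGLLSVHHR", 1, 2.0),  # one uncut K
                ("prot", "WWWWWWW", 1, 1.0),  # matches no tryptic merge
            ]
        )
        ann = annotate_peptides(t, TOY)
        assert list(ann["cleavage_class"]) == ["fully", "partial", "unexpected"]
        assert ann.loc[1, "missed_cleavages"] == 1

    def test_unknown_protein_flagged(self):
        t = toy_table([("ghost", "MAAAWDETK", 1, 1.0)])
        with pytest.warns(UserWarning, match="unknown"):
            ann = annotate_peptides(t, TOY)
        assert ann.loc[0, "cleavage_class"] == "unknown"

    def test_copy_numbers_joined_from_design(self, design):
        df = simulate_peptide_quant(design, replicates=1, seed=0, replicate_noise_sd=0)
        ann = annotate_peptides(df, design)
        from omnictrl.designer import proco_proteins

        info = proco_proteins(design)
        for prot, d in info.items():
            eight = [p for p, c in d["copy_numbers"].items() if c == 8][0]
            row = ann[(ann.protein == prot) & (ann.peptide == eight)]
            assert (row["expected_copy_number"] == 8).all()
            tag = ann[(ann.protein == prot) & ann.is_tag]
            assert not tag.empty

    def test_classification_matches_bruteforce_merges(self):
        """Every contiguous merge of <= 2 missed cleavages is classified
        'partial'; anything else 'unexpected'."""
        seq = TOY["prot"]
        peps = [p.sequence for p in trypsin_digest(seq, max_missed=0)]
        merges = set()
        for m in (1, 2):
            for i in range(len(peps) - m):
                merges.add("".join(peps[i : i + m + 1]))
        rows = [("prot", s, 1, 1.0) for s in sorted(merges)] + [
            ("prot", "AAAAAAAK", 1, 1.0)
        ]
        ann = annotate_peptides(toy_table(rows), TOY, max_missed=2)
        got = dict(zip(ann["peptide"], ann["cleavage_class"]))
        for s in merges:
            assert got[s] == "partial"
        assert got["AAAAAAAK"] == "unexpected"


class TestCleavage:
    def test_arithmetic(self):
        t = toy_table(
            [
                ("prot", "MAAAWDETK", 1, 90.0),
                ("prot", "MAAAWDETKGLLSVHHR", 1, 10.0),
            ]
        )
        out = cleavage_proportion(annotate_peptides(t, TOY))
        assert out["cleavage_proportion"].iloc[0] == pytest.approx(0.90)

    def test_no_partial_gives_one(self):
        t = toy_table([("prot", "MAAAWDETK", 1, 5.0)])
        out = cleavage_proportion(annotate_peptides(t, TOY))
        assert out["cleavage_proportion"].iloc[0] == 1.0


class TestRelativeAbundance:
    def test_ideal_fixture_copy_arithmetic(self, design):
        df = simulate_peptide_quant(design, replicates=3, seed=0, replicate_noise_sd=0)
        ann = annotate_peptides(df, design)
        fracs, summary = relative_abundance(ann)
        # fractions sum to 1 within each protein x replicate
        sums = fracs.groupby(["protein", "replicate"])["fraction"].sum()
        assert np.allclose(sums, 1.0)
        eight = fracs[fracs["expected_copy_number"] == 8]
        assert np.allclose(eight["fraction"], 8 / 23)
        assert summary["copy_number_r2"] == pytest.approx(1.0)

    def test_response_factors_break_ladder_not_reproducibility(self, design):
        """Unit response factors give R^2 = 1 exactly; lognormal sigma=1
        factors collapse the copy-number relationship (R^2 well below 1,
        typically ~0.1-0.75 depending on the draw) while the shared-factor
        structure keeps replicate-to-replicate correlation ~1."""
        df = simulate_peptide_quant(
            design, response_factor_sd=1.0, replicates=3, seed=1,
            replicate_noise_sd=0.02,
        )
        ann = annotate_peptides(df, design)
        _, summary = relative_abundance(ann)
        assert summary["copy_number_r2"] < 0.9
        assert summary["replicate_correlation"] > 0.95

    def test_single_peptide_protein(self):
        t = toy_table([("p1", "AAAAAAK", 1, 3.0)])
        ann = annotate_peptides(t, {"p1": "AAAAAAK"})
        fracs, _ = relative_abundance(ann)
        assert fracs["fraction"].iloc[0] == 1.0


class TestPropertyRegression:
    def _fixture(self, design, beta_pi=0.0, seed=0):
        from omnictrl.designer import proco_proteins

        peptides = set()
        for d in proco_proteins(design).values():
            peptides |= set(d["copy_numbers"])
        rf = None
        if beta_pi:
            profs = {p: physicochem(p) for p in peptides}
            pis = np.array([profs[p].isoelectric_point for p in peptides])
            rng = np.random.default_rng(seed)
            rf = {
                p: float(
                    np.exp(beta_pi * (profs[p].isoelectric_point - pis.mean()))
                    * rng.lognormal(0, 0.05)
                )
                for p in peptides
            }
        df = simulate_peptide_quant(
            design, response_factors=rf,
            response_factor_sd=0.3 if not beta_pi else 0.0,
            replicates=3, seed=seed, replicate_noise_sd=0.02,
        )
        return annotate_peptides(df, design)

    def test_planted_negative_pi_effect_recovered(self, design):
        ann = self._fixture(design, beta_pi=-0.4)
        table = property_regression(ann)
        row = table.loc["isoelectric_point"]
        assert row["coef"] < 0
        assert row["p"] < 0.05

    def test_too_few_peptides_rejected(self):
        t = toy_table([("p1", "AAAAAAK", 1, 1.0), ("p1", "CCCCCCR", 1, 1.0)])
        ann = annotate_peptides(t, {"p1": "AAAAAAKCCCCCCR"})
        with pytest.raises(ValueError, match="too few"):
            property_regression(ann)


class TestEqualAbundance:
    def _housekeeping(self, n_prot=3, n_pep=10, seed=0, sd=0.0):
        rng = np.random.default_rng(seed)
        proteins = {}
        for i in range(n_prot):
            parts = []
            for j in range(n_pep):
                body = "".join(rng.choice(list("ADEFGHILNQSTVWY"), 9))
                parts.append(body + "K")
            proteins[f"hk{i}"] = "".join(parts)
        quant = simulate_peptide_quant(
            proteins, response_factor_sd=sd, replicates=3, seed=seed,
            replicate_noise_sd=0.0 if sd == 0 else 0.02,
        )
        return annotate_peptides(quant, proteins)

    def test_ideal_equal_fractions(self):
        ann = self._housekeeping()
        out = equal_abundance_check(ann)
        assert len(out) == 3
        assert np.allclose(out["expected_fraction"], 0.1)
        assert np.allclose(out["cov"], 0.0, atol=1e-12)

    def test_response_factors_inflate_cov_not_reproducibility(self):
        ann = self._housekeeping(sd=1.0, seed=2)
        out = equal_abundance_check(ann)
        assert (out["cov"] > 0.3).all()
        assert (out["replicate_correlation"] > 0.95).all()

    def test_small_proteins_skipped(self):
        ann = self._housekeeping(n_pep=5)
        assert equal_abundance_check(ann).empty
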