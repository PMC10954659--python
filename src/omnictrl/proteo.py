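"""Evaluation of peptide quantification tables against a design.

Detected peptides are classified against the in silico tryptic digest of
their parent protein: *fully* cleaved (exact 0-missed-cleavage fragment),
*partial* (a contiguous merge with up to ``max_missed`` missed cleavages) or
*unexpected*.  His-tag-derived peptides are flagged and excluded from the
copy-number ladder (the tag is shared and uninformative).  Summaries follow
the per-replicate-then-average convention: proportions are computed within
each replicate and averaged, with SD across replicates reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designspec import PlasmidDesign
from .insilico import physicochem, trypsin_digest

PROPERTIES = (
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "instability_index",
    "aliphatic_index",
    "extinction_coefficient",
)


def _protein_lookup(design_or_proteins) -> dict[str, dict]:
    """name -> {sequence, copy_numbers (peptide->cn), tag_peptides}."""
    if isinstance(design_or_proteins, PlasmidDesign):
        from .designer import proco_proteins

        info = proco_proteins(design_or_proteins)
        return {
            name: {
                "sequence": d["protein"],
                "copy_numbers": d["copy_numbers"],
                "tags": set(d["tag_peptides"]),
            }
            for name, d in info.items()
        }
    out = {}
    for name, val in design_or_proteins.items():
        if isinstance(val, str):
            seq = val
            full = {p.sequence for p in trypsin_digest(seq, name)}
            out[name] = {
                "sequence": seq,
                "copy_numbers": {s: 1 for s in full},
                "tags": set(),
            }
        else:
            out[name] = {
                "sequence": val["sequence"],
                "copy_numbers": dict(val.get("copy_numbers", {})),
                "tags": set(val.get("tags", ())),
            }
    return out


def annotate_peptides(
    table: pd.DataFrame,
    design_or_proteins,
    max_missed: int = 2,
) -> pd.DataFrame:
    """Join cleavage class, missed-cleavage count, tag flag and expected copy
    number onto a (protein, peptide, replicate, quantity) table.

    Rows with unknown parent proteins are flagged ``unknown`` and excluded
    from every downstream summary.
    """
    lookup = _protein_lookup(design_or_proteins)
    digests: dict[str, dict[str, int]] = {}
    for name, info in lookup.items():
        d: dict[str, int] = {}
        for p in trypsin_digest(info["sequence"], name, max_missed=max_missed):
            if p.sequence not in d or p.missed_cleavages < d[p.sequence]:
                d[p.sequence] = p.missed_cleavages
        digests[name] = d
    out = table.copy()
    classes, missed, cn, tag = [], [], [], []
    unknown = 0
    for prot, pep in zip(out["protein"], out["peptide"]):
        info = lookup.get(prot)
        if info is None:
            unknown += 1
            classes.append("unknown")
            missed.append(np.nan)
            cn.append(np.nan)
            tag.append(False)
            continue
        mc = digests[prot].get(pep)
        if mc is None:
            classes.append("unexpected")
            missed.append(np.nan)
        elif mc == 0:
            classes.append("fully")
            missed.append(0)
        else:
            classes.append("partial")
            missed.append(mc)
        cn.append(info["copy_numbers"].get(pep, np.nan))
        tag.append(pep in info["tags"])
    if unknown:
        warnings.warn(f"{unknown} rows with unknown proteins flagged")
    out["cleavage_class"] = classes
    out["missed_cleavages"] = missed
    out["expected_copy_number"] = cn
    out["is_tag"] = tag
    return out


def cleavage_proportion(annotated: pd.DataFrame) -> pd.DataFrame:
    """Fully-cleaved signal / (fully + partial) per protein per replicate;
    unexpected and unknown peptides are excluded from the denominator."""
    df = annotated[annotated["cleavage_class"].isin(["fully", "partial"])]
    rows = []
    for (prot, rep), g in df.groupby(["protein", "replicate"]):
        full = g.loc[g["cleavage_class"] == "fully", "quantity"].sum()
        total = g["quantity"].sum()
        if total == 0:
            warnings.warn(f"{prot} rep {rep}: zero quantified signal")
            prop = np.nan
        else:
            prop = full / total
        rows.append({"protein": prot, "replicate": rep, "cleavage_proportion": prop})
    return pd.DataFrame(rows)


def relative_abundance(
    annotated: pd.DataFrame, drop_tags: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Per-peptide fraction of the per-protein fully-cleaved signal, per
    replicate, with the copy-number correlation and replicate
    reproducibility.

    Fractions within each (protein, replicate) sum to 1 over the retained
    fully-cleaved peptides.  The summary reports R^2 of fraction vs expected
    copy number (per replicate, averaged) and the mean pairwise Pearson
    correlation of peptide fractions between replicates.
    """
    df = annotated[annotated["cleavage_class"] == "fully"].copy()
    if drop_tags:
        df = df[~df["is_tag"]]
    if df.empty:
        raise ValueError("no fully cleaved peptides to summarize")
    df["fraction"] = df.groupby(["protein", "replicate"])["quantity"].transform(
        lambda q: q / q.sum()
    )
    ladder = df.dropna(subset=["expected_copy_number"])
    r2s = []
    for rep, g in ladder.groupby("replicate"):
        if g["expected_copy_number"].nunique() > 1:
            fit = stats.linregress(g["expected_copy_number"], g["fraction"])
            r2s.append(fit.rvalue**2)
    piv = df.pivot_table(
        index=["protein", "peptide"], columns="replicate", values="fraction"
    )
    reps = piv.columns
    cors = [
        piv[a].corr(piv[b]) for i, a in enumerate(reps) for b in reps[i + 1 :]
    ]
    summary = {
        "copy_number_r2": float(np.mean(r2s)) if r2s else float("nan"),
        "replicate_correlation": float(np.mean(cors)) if cors else float("nan"),
        "n_peptides": int(piv.shape[0]),
    }
    return df, summary


def property_regression(
    annotated_or_fractions: pd.DataFrame,
    profiles: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Multiple linear regression of relative quantification on standardized
    physicochemical properties (MW, pI, GRAVY, instability, aliphatic index,
    extinction coefficient); per-coefficient t-test p-values.

    Accepts an annotated quant table (fractions are computed) or a table
    already carrying a ``fraction`` column.  Property profiles are computed
    with :func:`omnictrl.insilico.physicochem` unless supplied.
    """
    df = annotated_or_fractions
    if "fraction" not in df.columns:
        df, _ = relative_abundance(df)
    mean_frac = (
        df.groupby("peptide")["fraction"].mean().rename("relative_quantification")
    )
    peptides = mean_frac.index.tolist()
    if profiles is None:
        profiles = {p: physicochem(p) for p in peptides}
    X = pd.DataFrame(
        {prop: [getattr(profiles[p], prop) for p in peptides] for prop in PROPERTIES},
        index=peptides,
    )
    if len(peptides) < X.shape[1] + 2:
        raise ValueError("too few peptides for the number of covariates")
    sd = X.std(ddof=1)
    keep = sd > 0
    Xz = (X.loc[:, keep] - X.loc[:, keep].mean()) / sd[keep]
    cond = np.linalg.cond(Xz.to_numpy())
    if cond > 1e6:
        warnings.warn(f"covariates nearly collinear (condition number {cond:.2g})")
    model = sm.OLS(mean_frac.to_numpy(), sm.add_constant(Xz)).fit()
    out = pd.DataFrame(
        {
            "coef": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    out.attrs["r2"] = float(model.rsquared)
    out.attrs["condition_number"] = float(cond)
    return out


def equal_abundance_check(
    annotated: pd.DataFrame,
    proteins: list[str] | None = None,
    min_peptides: int = 8,
    min_length: int = 7,
) -> pd.DataFrame:
    """Per-protein CoV of peptide fractions under the equal-abundance
    assumption (each unique peptide present once, expected fraction 1/n).

    Proteins with at most ``min_peptides`` qualifying peptides (longer than
    ``min_length`` residues, fully cleaved) are skipped.
    """
    df = annotated[
        (annotated["cleavage_class"] == "fully")
        & (~annotated["is_tag"])
        & (annotated["peptide"].str.len() > min_length)
    ].copy()
    if proteins is not None:
        df = df[df["protein"].isin(proteins)]
    rows = []
    for prot, g in df.groupby("protein"):
        n_pep = g["peptide"].nunique()
        if n_pep <= min_peptides:
            continue
        fracs = g.copy()
        fracs["fraction"] = fracs.groupby("replicate")["quantity"].transform(
            lambda q: q / q.sum()
        )
        per_rep_cov = fracs.groupby("replicate")["fraction"].agg(
            lambda f: f.std(ddof=1) / f.mean()
        )
        piv = fracs.pivot_table(index="peptide", columns="replicate", values="fraction")
        reps = piv.columns
        cors = [
            piv[a].corr(piv[b]) for i, a in enumerate(reps) for b in reps[i + 1 :]
        ]
        rows.append(
            {
                "protein": prot,
                "n_peptides": n_pep,
                "expected_fraction": 1.0 / n_pep,
                "cov": float(per_rep_cov.mean()),
                "replicate_correlation": float(np.mean(cors)) if cors else np.nan,
            }
        )
    return pd.DataFrame(rows)
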