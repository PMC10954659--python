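"""Spike-in-anchored normalization of count matrices.

Three strategies over a features x samples count matrix with designated
control features:

* fixed-fraction scaling — control counts rescaled per sample so they make
  up a fixed fraction (default 1%) of the library, removing input-amount
  and pipetting variation from the controls themselves;
* upper-quartile (UQ) — per-sample size factors from the 75th percentile of
  nonzero counts, rescaled to geometric mean 1;
* RUVg — factors of unwanted variation estimated from the control features
  (SVD of their centered log counts across samples) and regressed out of
  every feature, per the remove-unwanted-variation-with-control-genes
  method; controls carry no biology, so whatever varies across samples in
  them is technical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Counts (features x samples) plus feature metadata and sample
    condition labels."""

    counts: pd.DataFrame
    feature_meta: pd.DataFrame  # columns: is_control, expected_lfc (optional)
    conditions: pd.Series  # per sample

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.feature_meta.index):
            raise ValueError("counts and feature_meta indices differ")
        if not self.counts.columns.equals(self.conditions.index):
            raise ValueError("counts columns and conditions index differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def controls(self) -> pd.Index:
        return self.feature_meta.index[self.feature_meta["is_control"].astype(bool)]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizationResult:
    method: str  # scale1pct | UQ | RUVg
    log_counts: pd.DataFrame  # natural log(counts + 1), input
    adjusted_log: pd.DataFrame  # after normalization
    W: np.ndarray | None = None  # samples x k unwanted factors
    size_factors: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)


def scale_spikes_to_fraction(
    cm: CountMatrix, fraction: float = 0.01
) -> tuple[CountMatrix, pd.Series]:
    """Rescale control counts per sample so controls sum to ``fraction`` of
    the post-scaling library; non-controls are untouched.  Returns the
    scaled matrix and the per-sample scalars."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    ctrl = cm.controls
    if len(ctrl) == 0:
        raise ValueError("no control features")
    counts = cm.counts.astype(float).copy()
    scalars = {}
    for s in counts.columns:
        c = counts.loc[ctrl, s].sum()
        t = counts[s].sum() - c
        if c <= 0:
            raise ValueError(f"sample {s} has zero control counts")
        if fraction == 0:
            warnings.warn("fraction=0 zeroes the control features")
            scalars[s] = 0.0
        else:
            # solve s*c = fraction * (t + s*c)
            scalars[s] = fraction * t / (c * (1 - fraction))
        counts.loc[ctrl, s] = counts.loc[ctrl, s] * scalars[s]
    return (
        CountMatrix(counts, cm.feature_meta.copy(), cm.conditions.copy()),
        pd.Series(scalars),
    )


def uq_normalize(cm: CountMatrix) -> NormalizationResult:
    """Upper-quartile size factors (75th percentile of nonzero counts),
    rescaled to geometric mean 1; adjusted log counts subtract log(factor)."""
    counts = cm.counts
    factors = {}
    for s in counts.columns:
        col = counts[s].to_numpy()
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {s} is all zeros")
        factors[s] = float(np.percentile(nz, 75))
    f = pd.Series(factors)
    f = f / np.exp(np.mean(np.log(f)))
    y = np.log(counts + 1.0)
    adjusted = y.sub(np.log(f), axis=1)
    return NormalizationResult(
        method="UQ",
        log_counts=y,
        adjusted_log=adjusted,
        size_factors=f,
        diagnostics=_control_variance_diag(cm, y, adjusted),
    )


def ruvg(
    cm: CountMatrix, controls=None, k: int = 1, protect_conditions: bool = True
) -> NormalizationResult:
    """Remove unwanted variation estimated from control features.

    Control log counts are centered per feature across samples; W is the
    first k left singular vectors (samples) of that matrix, scaled by the
    singular values.  Each feature's log counts are regressed on W and the
    fitted unwanted component removed.  k=0 returns the input unchanged.

    With ``protect_conditions`` (and at least two condition labels), the
    condition contrast is included in the per-feature regression so the
    biological signal is not absorbed into the unwanted factors — the same
    reason the reference method carries W as a covariate into the final
    model rather than regressing it out blindly.
    """
    controls = cm.controls if controls is None else pd.Index(controls)
    if len(controls) == 0:
        raise ValueError("RUVg needs non-empty controls")
    y = np.log(cm.counts + 1.0)
    if k == 0:
        return NormalizationResult(
            "RUVg", y, y.copy(), W=np.zeros((cm.n_samples, 0)),
            diagnostics=_control_variance_diag(cm, y, y),
        )
    if k > min(len(controls), cm.n_samples):
        raise ValueError("k exceeds the control/sample dimensions")
    yc = y.loc[controls].to_numpy()
    z = (yc - yc.mean(axis=1, keepdims=True)).T  # samples x controls
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    W = u[:, :k] * s[:k]
    # per-feature regression on W (least squares, all features); the
    # condition design, when known, is a protected covariate
    ym = y.to_numpy()
    centered = ym - ym.mean(axis=1, keepdims=True)
    X = W
    if protect_conditions and cm.conditions.nunique() > 1:
        dummies = pd.get_dummies(cm.conditions, drop_first=True).to_numpy(float)
        dummies = dummies - dummies.mean(axis=0, keepdims=True)
        X = np.hstack([W, dummies])
    coef, *_ = np.linalg.lstsq(X, centered.T, rcond=None)
    alpha = coef[:k]  # only the unwanted component is removed
    adjusted = pd.DataFrame(
        ym - (W @ alpha).T, index=y.index, columns=y.columns
    )
    return NormalizationResult(
        method="RUVg",
        log_counts=y,
        adjusted_log=adjusted,
        W=W,
        diagnostics=_control_variance_diag(cm, y, adjusted),
    )


def _control_variance_diag(cm, y, adjusted) -> dict:
    ctrl = cm.controls
    if len(ctrl) == 0:
        return {}
    before = float(y.loc[ctrl].var(axis=1, ddof=1).mean())
    after = float(adjusted.loc[ctrl].var(axis=1, ddof=1).mean())
    return {"control_variance_before": before, "control_variance_after": after}


def evaluate_abundance(
    adjusted_log: pd.DataFrame,
    conditions: pd.Series,
    expected_lfc: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Observed vs expected between-condition log2 fold-differences.

    ``adjusted_log`` holds natural-log counts; the observed LFC is the mean
    difference between the two condition groups divided by ln 2.  Features
    without an expected value are skipped.  Summary: mean absolute
    deviation and R^2 of observed on expected.
    """
    groups = conditions.unique()
    if len(groups) != 2:
        raise ValueError("exactly two conditions required")
    a, b = sorted(groups)
    in_a = conditions[conditions == a].index
    in_b = conditions[conditions == b].index
    expected = expected_lfc.dropna()
    feats = adjusted_log.index.intersection(expected.index)
    obs = (
        adjusted_log.loc[feats, in_b].mean(axis=1)
        - adjusted_log.loc[feats, in_a].mean(axis=1)
    ) / np.log(2)
    table = pd.DataFrame(
        {
            "expected_lfc": expected.loc[feats],
            "observed_lfc": obs,
            "deviation": obs - expected.loc[feats],
        }
    )
    summary = {"mad": float(table["deviation"].abs().mean()), "n": len(table)}
    if table["expected_lfc"].nunique() > 1:
        fit = stats.linregress(table["expected_lfc"], table["observed_lfc"])
        summary["r2"] = float(fit.rvalue**2)
    else:
        summary["r2"] = float("nan")
    return table, summary
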