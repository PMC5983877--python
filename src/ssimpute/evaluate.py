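"""Metrics comparing imputed to ground-truth summary statistics.

RMSE and bias act on the differences d_k = z_imp_k - z_true_k; the calibration
slope is a no-intercept regression of imputed on truth; power and false
positive rate are fractions of P-values below a significance grid with
binomial standard deviations.  Stratification follows the convention that a
bin's lower bound is excluded and its upper bound included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAF_BINS = (0.01, 0.05, 0.5)
QUALITY_BINS = (0.3, 0.7, 1.0)

#: LD thresholds for labelling variants by association status: correlated with
#: a trait-associated variant (squared correlation above ``assoc``) vs null
#: (below ``null``).
LD_MAX_ASSOC = 0.3
LD_MAX_NULL = 0.05


@dataclass
class EvaluationSummary:
    """Stratified accuracy table plus a power/FPR curve table."""

    strata: pd.DataFrame = field(default_factory=pd.DataFrame)
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)


def rmse_bias(z_imp, z_truth) -> tuple[float, float]:
    """Root-mean-square error and mean signed error of imputed vs truth."""
    d = np.asarray(z_imp, dtype=float) - np.asarray(z_truth, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean(d**2))), float(np.mean(d))


def slope_correlation(z_imp, z_truth) -> tuple[float, float]:
    """No-intercept regression slope of imputed on truth, and Pearson r."""
    x = np.asarray(z_truth, dtype=float)
    y = np.asarray(z_imp, dtype=float)
    slope = float(x @ y / (x @ x))
    r = float(np.corrcoef(x, y)[0, 1]) if x.size > 1 else np.nan
    return slope, r


def power_fpr(p_assoc, p_null, alphas) -> pd.DataFrame:
    """Power q_A and FPR q_N over a significance grid, with binomial SDs.

    q = fraction of P-values strictly below alpha; SD = sqrt(q(1-q)/m).
    """
    p_assoc = np.asarray(p_assoc, dtype=float)
    p_null = np.asarray(p_null, dtype=float)
    rows = []
    for alpha in np.atleast_1d(alphas):
        row = {"alpha": float(alpha)}
        for label, p in (("power", p_assoc), ("fpr", p_null)):
            m = p.size
            q = float(np.mean(p < alpha)) if m else np.nan
            row[label] = q
            row[f"{label}_sd"] = float(np.sqrt(q * (1 - q) / m)) if m else np.nan
            row[f"m_{label}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def _bin_labels(edges, prefix: str = "") -> list[str]:
    lo = [0.0, *edges[:-1]]
    return [f"{prefix}({a:g},{b:g}]" for a, b in zip(lo, edges)]


def stratify(
    results: pd.DataFrame,
    maf_bins=MAF_BINS,
    quality_bins=QUALITY_BINS,
    ld_assoc: float = LD_MAX_ASSOC,
    ld_null: float = LD_MAX_NULL,
) -> pd.DataFrame:
    """Per-stratum accuracy of imputed vs true Z-statistics.

    ``results`` needs columns z_imp, z_true, maf, r2_pred_adj and (optionally)
    ld_max — the largest squared correlation to any trait-associated variant,
    used to label each variant ``associated`` (> ld_assoc), ``null``
    (< ld_null) or ``ambiguous``.  Every variant falls in exactly one
    MAF x quality cell; bins are (lower, upper] intervals.
    """
    df = results.copy()
    df["maf_bin"] = pd.cut(df["maf"], [0.0, *maf_bins], right=True,
                           labels=_bin_labels(list(maf_bins)))
    df["quality_bin"] = pd.cut(df["r2_pred_adj"], [-np.inf, *quality_bins], right=True,
                               labels=_bin_labels(list(quality_bins)))
    if "ld_max" in df.columns:
        df["status"] = np.select(
            [df["ld_max"] > ld_assoc, df["ld_max"] < ld_null],
            ["associated", "null"],
            default="ambiguous",
        )
    else:
        df["status"] = df.get("status", "all")

    rows = []
    for (status, maf_bin, quality_bin), grp in df.groupby(
        ["status", "maf_bin", "quality_bin"], observed=True, sort=False
    ):
        rmse, bias = rmse_bias(grp["z_imp"], grp["z_true"])
        slope, r = slope_correlation(grp["z_imp"], grp["z_true"])
        rows.append(
            {
                "status": status,
                "maf_bin": maf_bin,
                "quality_bin": quality_bin,
                "rmse": rmse,
                "bias": bias,
                "slope": slope,
                "correlation": r,
                "n_variants": len(grp),
            }
        )
    return pd.DataFrame(rows)


def ld_max_to_set(panel, target_indices, assoc_indices) -> np.ndarray:
    """Largest squared dosage correlation of each target to a set of
    trait-associated variants (0 when the set is empty)."""
    from . import ld as _ld

    if len(assoc_indices) == 0:
        return np.zeros(len(target_indices))
    c = _ld.cross_correlation(panel, target_indices, assoc_indices)  # (q_assoc, n_targets)
    return np.max(c**2, axis=0)


def genomic_inflation(z) -> float:
    """Genomic-control lambda: median chi-square over its null expectation."""
    z = np.asarray(z, dtype=float)
    return float(np.median(z**2) / stats.chi2.ppf(0.5, 1))
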