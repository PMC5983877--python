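"""LD estimation, shrinkage and imputation quality.

The tag-tag correlation matrix ``C`` and target-tag vector ``c`` are Pearson
correlations of reference-panel dosages.  Because the number of tags often
exceeds the panel size, ``C`` is shrunk towards the identity,

    C_lambda = (1 - lambda) * C + lambda * I,      c_lambda = (1 - lambda) * c,

which guarantees invertibility for lambda > 0 and damps noise-level
correlations.  Imputation quality is the quadratic form

    r2_pred = c_lambda' C_lambda^{-1} c_lambda,

optionally adjusted for the panel size n and the effective number of tags
q_eff (analogous to an adjusted R^2):

    r2_pred_adj = 1 - (1 - r2_pred) * (n - 1) / (n - q_eff - 1),

clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import ReferencePanel

logger = logging.getLogger(__name__)

#: Default spectral cutoff for the effective number of variants.
QEFF_VARIANCE_EXPLAINED = 0.995


def solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``A x = b`` for symmetric positive-definite ``A``.

    Cholesky factorisation; falls back to the pseudo-inverse (with a warning)
    when A is singular, e.g. duplicate tag columns at lambda = 0.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    try:
        c, low = linalg.cho_factor(A, lower=True, check_finite=False)
        return linalg.cho_solve((c, low), b, check_finite=False)
    except linalg.LinAlgError:
        logger.warning("solve_spd: matrix not positive definite, using pseudo-inverse "
                       "(consider lambda > 0)")
        return linalg.pinvh(A) @ b


@dataclass
class QualityReport:
    """Raw and adjusted imputation quality for one target variant."""

    r2_pred: float
    r2_pred_adj: float
    q_eff: float
    q: int
    n_panel: int


@dataclass
class LdSystem:
    """Shrunk LD system for one window: tags, C_lambda and per-target c_lambda."""

    tag_ids: list
    C: np.ndarray
    c: np.ndarray  # (q,) or (q, n_targets)
    lam: float
    C_lambda: np.ndarray
    c_lambda: np.ndarray
    n_panel: int


def standardized_dosages(panel: ReferencePanel, variant_indices=None) -> np.ndarray:
    """Mean-imputed, column-standardised (ddof=0) dosage matrix."""
    g = panel.dosages_imputed()
    if variant_indices is not None:
        g = g[:, np.asarray(variant_indices)]
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(sd > 0, g / sd, np.nan)
    return g


def correlation_matrix(panel: ReferencePanel, variant_indices=None) -> np.ndarray:
    """Pearson correlation of (mean-imputed) dosage columns, exact unit diagonal.

    Raises ValueError if any requested column has zero variance after
    mean-imputation; such variants cannot serve as tags.
    """
    g = panel.dosages_imputed()
    if variant_indices is not None:
        g = g[:, np.asarray(variant_indices)]
    if g.shape[1] < 1:
        raise ValueError("correlation_matrix needs at least one variant")
    sd = g.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance dosage column(s) at indices {bad.tolist()}")
    C = np.corrcoef(g, rowvar=False)
    C = np.atleast_2d(C)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def cross_correlation(panel: ReferencePanel, target_indices, tag_indices) -> np.ndarray:
    """Correlation between target columns and tag columns, shape (q_tags, n_targets)."""
    gt = standardized_dosages(panel, tag_indices)
    gu = standardized_dosages(panel, target_indices)
    c = gt.T @ gu / panel.n
    return np.clip(np.nan_to_num(c), -1.0, 1.0)


def choose_lambda(mode: str = "fixed", n_panel: int | None = None, value: float | None = None) -> float:
    """Shrinkage intensity: ``fixed`` -> 0.1, ``sqrt_n`` -> 2/sqrt(n), ``value`` -> user value."""
    if mode == "fixed":
        return 0.1
    if mode == "sqrt_n":
        if n_panel is None or n_panel < 1:
            raise ValueError("sqrt_n rule needs a panel size >= 1")
        return min(1.0, 2.0 / np.sqrt(n_panel))
    if mode == "value":
        if value is None or not (0.0 <= value <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {value}")
        return float(value)
    raise ValueError(f"unknown lambda mode {mode!r}")


def shrink(C: np.ndarray, c: np.ndarray | None, lam: float) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply ``C_lambda = (1-lambda) C + lambda I`` and ``c_lambda = (1-lambda) c``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    C_lam = (1.0 - lam) * C + lam * np.eye(C.shape[0])
    np.fill_diagonal(C_lam, 1.0)  # diagonal of C is exactly 1 by contract
    c_lam = None if c is None else (1.0 - lam) * np.asarray(c, dtype=float)
    return C_lam, c_lam


def impute_quality(c_lambda: np.ndarray, C_lambda: np.ndarray, clamp: bool = True) -> float | np.ndarray:
    """``r2_pred = c_lambda' C_lambda^{-1} c_lambda`` (clamped to [0, 1] by default).

    ``c_lambda`` may be a vector (one target) or a (q, n_targets) matrix.
    Sampling noise near lambda = 0 can push the raw quadratic form above 1;
    the raw value is logged when that happens.
    """
    c_lambda = np.asarray(c_lambda, dtype=float)
    w = solve_spd(C_lambda, c_lambda)
    if c_lambda.ndim == 1:
        r2 = float(c_lambda @ w)
    else:
        r2 = np.einsum("qt,qt->t", c_lambda, w)
    if clamp:
        over = np.any(np.asarray(r2) > 1.0)
        if over:
            logger.debug("impute_quality: raw value(s) above 1 clamped (max %.4f)", float(np.max(r2)))
        r2 = np.clip(r2, 0.0, 1.0)
        if np.ndim(r2) == 0:
            r2 = float(r2)
    return r2


def effective_num_variants(C: np.ndarray, variance_explained: float = QEFF_VARIANCE_EXPLAINED) -> int:
    """Effective number of variants: leading eigenvalues needed to reach a
    ``variance_explained`` fraction of the trace of the tag correlation matrix.

    Equals q for independent tags, 1 for a block in perfect LD.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    eig = np.sort(linalg.eigvalsh(C))[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        return len(eig)
    frac = np.cumsum(eig) / total
    return int(np.searchsorted(frac, variance_explained - 1e-12) + 1)


def adjust_quality(r2_pred: float, n_panel: int, q_eff: float) -> float:
    """Panel-size/parameter-count adjusted quality, clamped to [0, 1].

    Returns 0 with a warning when the panel is too small (n <= q_eff + 1) for
    the adjustment to be estimable.
    """
    if n_panel <= q_eff + 1:
        logger.warning("adjust_quality: panel size %d <= q_eff+1 (%.1f); quality not estimable",
                       n_panel, q_eff + 1)
        return 0.0
    adj = 1.0 - (1.0 - r2_pred) * (n_panel - 1.0) / (n_panel - q_eff - 1.0)
    return float(min(1.0, max(0.0, adj)))


def quality_report(c_lambda: np.ndarray, C_lambda: np.ndarray, C_raw: np.ndarray, n_panel: int) -> QualityReport:
    """Bundle raw and adjusted quality for one target."""
    r2 = impute_quality(c_lambda, C_lambda)
    q_eff = effective_num_variants(C_raw)
    return QualityReport(
        r2_pred=r2,
        r2_pred_adj=adjust_quality(r2, n_panel, q_eff),
        q_eff=q_eff,
        q=C_raw.shape[0],
        n_panel=n_panel,
    )
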