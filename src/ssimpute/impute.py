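"""Summary-statistics imputation of Z-statistics and standardized effects.

The imputed Z-statistic of an untyped variant u is the conditional mean of a
multivariate normal given the tag Z-statistics,

    z_hat_u = c_lambda' C_lambda^{-1} z,

where c and C are reference-panel LD estimates (after shrinkage).  When tag
summaries come from meta-analyses with variable per-SNV sample size N_k, the
correlation between observed statistics is attenuated by the sample overlap,

    Cor[z_k, z_l] = C_kl * delta_kl,     delta_kl = N_{k n l} / sqrt(N_k N_l),

giving an adjusted system (d, D) and

    z_hat_u = d' D^{-1} z,     a_hat_u = z_hat_u / (sqrt(N_max) * d' D^{-1} d),

with d' D^{-1} d the corresponding imputation quality.  The overlap N_{k n l}
is either known, assumed maximal ("dependent": min(N_k, N_l), the conservative
recommendation) or assumed random ("independent": N_k N_l / N_max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ld
from .io import ReferencePanel

logger = logging.getLogger(__name__)

#: Below this imputation quality the standardized effect is suppressed
#: (the division in the effect conversion would amplify pure noise).
QUALITY_FLOOR = 1e-4

CORE_BP = 1_000_000
FLANK_BP = 250_000
TAG_RADIUS_BP = 750_000


def zscore_pvalue(z) -> np.ndarray | float:
    """Two-sided normal P-value; survival function keeps precision for |z| >> 0."""
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class MissingnessModel:
    """Per-tag sample sizes and the assumed cross-SNV overlap structure.

    mode: 'none' (equal N assumed), 'dependent' (maximal overlap),
    'independent' (random overlap) or 'known' (overlap matrix supplied).
    """

    mode: str = "dependent"
    N: np.ndarray | None = None
    overlap: np.ndarray | None = None
    n_max: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "dependent", "independent", "known"):
            raise ValueError(f"unknown missingness mode {self.mode!r}")
        if self.N is not None:
            self.N = np.asarray(self.N, dtype=float)
            if np.any(self.N < 1):
                raise ValueError("all sample sizes must be >= 1")
        if self.mode == "known":
            if self.overlap is None or self.N is None:
                raise ValueError("mode='known' requires N and the overlap matrix")
            ov = np.asarray(self.overlap, dtype=float)
            lo = np.minimum.outer(self.N, self.N)
            if ov.shape != (len(self.N),) * 2 or np.any(ov > lo + 1e-9):
                raise ValueError("overlap matrix violates overlap_{kl} <= min(N_k, N_l)")
            if not np.allclose(np.diag(ov), self.N):
                raise ValueError("overlap diagonal must equal N")
            self.overlap = ov

    @property
    def N_max(self) -> float:
        if self.n_max is not None:
            return float(self.n_max)
        if self.N is None:
            raise ValueError("no sample sizes recorded")
        return float(np.max(self.N))


@dataclass
class ImputationResult:
    """Imputed summary statistic for one target variant."""

    variant_id: str
    z_imp: float
    a_imp: float
    r2_pred: float
    r2_pred_adj: float
    n_max: float
    p_imp: float
    n_tags: int
    chromosome: str | None = None
    position: int | None = None
    source: str = "imputed"


def delta_dep(N_k, N_l):
    """Maximal-overlap attenuation: min(sqrt(N_k/N_l), sqrt(N_l/N_k))."""
    N_k = np.asarray(N_k, dtype=float)
    N_l = np.asarray(N_l, dtype=float)
    r = np.sqrt(N_k / N_l)
    return np.minimum(r, 1.0 / r)


def delta_ind(N_k, N_l, N_max):
    """Random-overlap attenuation: sqrt(N_k * N_l) / N_max."""
    return np.sqrt(np.asarray(N_k, dtype=float) * np.asarray(N_l, dtype=float)) / np.asarray(
        N_max, dtype=float
    )


def build_D(C_lambda: np.ndarray, model: MissingnessModel) -> np.ndarray:
    """Missingness-adjusted tag-tag matrix ``D_kl = (C_lambda)_kl * delta_kl``, unit diagonal.

    mode='none' returns C_lambda itself so the variable-N path reduces exactly
    to the base method.
    """
    if model.mode == "none":
        return C_lambda
    N = model.N
    if N is None or len(N) != C_lambda.shape[0]:
        raise ValueError("model.N must align with the tag dimension of C_lambda")
    if model.mode == "dependent":
        delta = delta_dep(N[:, None], N[None, :])
    elif model.mode == "independent":
        delta = delta_ind(N[:, None], N[None, :], model.N_max)
    else:  # known
        delta = model.overlap / np.sqrt(np.outer(N, N))
    D = C_lambda * delta
    np.fill_diagonal(D, 1.0)
    return D


def build_d(c_lambda_target: np.ndarray, model: MissingnessModel) -> np.ndarray:
    """Target-tag vector ``d_k = (c_lambda)_uk * sqrt(N_k / N_max)``.

    The target is imputed at the full N_max, so only the tag-side sample size
    attenuates the correlation.  ``c_lambda_target`` may be (q,) or (q, n_targets).
    """
    c = np.asarray(c_lambda_target, dtype=float)
    if model.mode == "none":
        return c
    scale = np.sqrt(model.N / model.N_max)
    return c * (scale[:, None] if c.ndim == 2 else scale)


def impute_z(z_tags: np.ndarray, C_lambda: np.ndarray, c_lambda: np.ndarray):
    """Base imputation ``z_hat = c_lambda' C_lambda^{-1} z``; linear in z.

    ``c_lambda`` may be (q,) for one target or (q, n_targets).
    """
    z_tags = np.asarray(z_tags, dtype=float)
    if z_tags.shape[0] != C_lambda.shape[0]:
        raise ValueError("z_tags and C_lambda dimensions disagree")
    w = ld.solve_spd(C_lambda, np.asarray(c_lambda, dtype=float))
    out = w.T @ z_tags
    return float(out) if np.ndim(out) == 0 else out


def impute_z_varN(z_obs: np.ndarray, d: np.ndarray, D: np.ndarray):
    """Variable-sample-size imputation ``z_hat = d' D^{-1} z``.

    With equal sample sizes d = c_lambda and D = C_lambda, so this is
    identical (bitwise) to :func:`impute_z`.
    """
    return impute_z(z_obs, D, d)


def z_to_effect(z_imp, N_max: float, quality, quality_floor: float = QUALITY_FLOOR):
    """Standardized effect ``a_hat = z_hat / (sqrt(N_max) * quality)``.

    ``quality`` is the corresponding d' D^{-1} d.  Because the imputed
    statistic satisfies E[z_hat] = quality * alpha * sqrt(N_max), dividing by
    the quality de-attenuates the effect estimate; below ``quality_floor``
    the effect is reported as NaN (z is still meaningful) to avoid exploding
    estimates from noise-level quality.
    """
    z_imp = np.asarray(z_imp, dtype=float)
    quality = np.asarray(quality, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = z_imp / (np.sqrt(float(N_max)) * quality)
    a = np.where(quality > quality_floor, a, np.nan)
    return float(a) if a.ndim == 0 else a


def rescale_observed_z(z_u, N_u, N_max):
    """Rescale an observed Z from its own N to N_max: ``z* = z * sqrt(N_max/N_u)``.

    Used to make directly observed statistics comparable to imputed ones that
    refer to the full sample.
    """
    return np.asarray(z_u, dtype=float) * np.sqrt(float(N_max) / np.asarray(N_u, dtype=float))


def _window_grid(positions: np.ndarray, core_bp: int) -> np.ndarray:
    """Core-window start positions: from the smallest tag position rounded down
    to a multiple of core_bp, up to the largest position."""
    start = int(positions.min() // core_bp) * core_bp
    stop = int(positions.max()) + 1
    return np.arange(start, stop, core_bp)


def _impute_window(
    tags: pd.DataFrame,
    panel: ReferencePanel,
    target_indices: np.ndarray,
    lam: float,
    missingness: str,
    overlap: np.ndarray | None = None,
) -> pd.DataFrame:
    """Impute all targets of one window from one shrunk LD system."""
    tag_idx = tags["panel_index"].to_numpy()
    C = ld.correlation_matrix(panel, tag_idx)
    c = ld.cross_correlation(panel, target_indices, tag_idx)  # (q, n_targets)
    C_lam, c_lam = ld.shrink(C, c, lam)

    N = tags["sample_size"].to_numpy(dtype=float)
    model = MissingnessModel(mode=missingness, N=N, overlap=overlap)
    D = build_D(C_lam, model)
    d = build_d(c_lam, model)

    z = tags["z"].to_numpy(dtype=float)
    z_imp = impute_z_varN(z, d, D)
    quality = ld.impute_quality(d, D)
    q_eff = ld.effective_num_variants(C)
    r2_adj = np.array([ld.adjust_quality(r2, panel.n, q_eff) for r2 in np.atleast_1d(quality)])
    n_max = model.N_max
    a_imp = z_to_effect(z_imp, n_max, quality)

    meta = panel.variants.iloc[target_indices]
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"].to_numpy(),
            "chromosome": meta["chromosome"].to_numpy(),
            "position": meta["position"].to_numpy(),
            "effect_allele": meta["alt"].to_numpy(),
            "other_allele": meta["ref"].to_numpy(),
            "z_imp": np.atleast_1d(z_imp),
            "a_imp": np.atleast_1d(a_imp),
            "r2_pred": np.atleast_1d(quality),
            "r2_pred_adj": r2_adj,
            "N_max": n_max,
            "p_imp": zscore_pvalue(np.atleast_1d(z_imp)),
            "n_tags": len(tags),
            "source": "imputed",
        }
    )


def window_impute(
    records: pd.DataFrame,
    panel: ReferencePanel,
    core_bp: int = CORE_BP,
    flank_bp: int = FLANK_BP,
    lam: float | None = None,
    lambda_mode: str = "fixed",
    missingness: str = "dependent",
    maf_min: float = 0.001,
    min_quality: float = 0.3,
    target_ids: set | None = None,
) -> pd.DataFrame:
    """Impute every non-tag panel variant, window by window.

    Tags for a core window ``[w, w + core_bp)`` are the harmonized records in
    ``[w - flank_bp, w + core_bp + flank_bp)``; one shrunk LD system per window
    is reused for all its targets.  Targets are panel variants in the core with
    MAF >= ``maf_min`` (``target_ids`` members are imputed regardless of MAF)
    that do not coincide with a tag position.  Tag records are passed through
    with ``source='tag'``.  ``quality_ok`` flags r2_pred_adj >= ``min_quality``;
    nothing is filtered out.
    """
    if lam is None:
        lam = ld.choose_lambda(lambda_mode, n_panel=panel.n)
    out_frames = []
    maf = panel.maf()
    for chrom, tags_chr in records.groupby("chromosome", sort=False):
        panel_chr_mask = (panel.variants["chromosome"].astype(str) == str(chrom)).to_numpy()
        positions = tags_chr["position"].to_numpy()
        tag_pos = set(positions.tolist())
        for w0 in _window_grid(positions, core_bp):
            w1 = w0 + core_bp
            in_flank = (positions >= w0 - flank_bp) & (positions < w1 + flank_bp)
            tags = tags_chr.iloc[np.flatnonzero(in_flank)]
            pos_panel = panel.variants["position"].to_numpy()
            core_mask = panel_chr_mask & (pos_panel >= w0) & (pos_panel < w1)
            ids = panel.variants["variant_id"]
            maf_ok = maf >= maf_min
            if target_ids:
                maf_ok = maf_ok | ids.isin(target_ids).to_numpy()
            not_tag = ~np.isin(pos_panel, list(tag_pos))
            target_idx = np.flatnonzero(core_mask & maf_ok & not_tag)
            if len(target_idx) == 0:
                continue
            if len(tags) == 0:
                meta = panel.variants.iloc[target_idx]
                out_frames.append(
                    pd.DataFrame(
                        {
                            "variant_id": meta["variant_id"].to_numpy(),
                            "chromosome": meta["chromosome"].to_numpy(),
                            "position": meta["position"].to_numpy(),
                            "effect_allele": meta["alt"].to_numpy(),
                            "other_allele": meta["ref"].to_numpy(),
                            "z_imp": np.nan,
                            "a_imp": np.nan,
                            "r2_pred": 0.0,
                            "r2_pred_adj": 0.0,
                            "N_max": np.nan,
                            "p_imp": np.nan,
                            "n_tags": 0,
                            "source": "imputed",
                        }
                    )
                )
                continue
            out_frames.append(_impute_window(tags, panel, target_idx, lam, missingness))

        passthrough = tags_chr.copy()
        passthrough = passthrough.rename(columns={"z": "z_imp"})
        passthrough["a_imp"] = passthrough["z_imp"] / np.sqrt(passthrough["sample_size"])
        passthrough["r2_pred"] = 1.0
        passthrough["r2_pred_adj"] = 1.0
        passthrough["N_max"] = passthrough["sample_size"]
        passthrough["p_imp"] = zscore_pvalue(passthrough["z_imp"].to_numpy())
        passthrough["n_tags"] = 0
        passthrough["source"] = "tag"
        cols = ["variant_id", "chromosome", "position", "effect_allele", "other_allele",
                "z_imp", "a_imp", "r2_pred", "r2_pred_adj", "N_max", "p_imp", "n_tags", "source"]
        out_frames.append(passthrough[cols])

    if not out_frames:
        return pd.DataFrame()
    out = pd.concat(out_frames, ignore_index=True)
    out["quality_ok"] = out["r2_pred_adj"] >= min_quality
    return out.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)


def mask_and_impute(
    records: pd.DataFrame,
    panel: ReferencePanel,
    focal_id: str,
    tag_radius_bp: int = TAG_RADIUS_BP,
    lam: float | None = None,
    lambda_mode: str = "fixed",
    missingness: str = "dependent",
) -> ImputationResult:
    """Leave-one-out imputation of one focal variant.

    Tags are all harmonized records within ``tag_radius_bp`` of the focal
    position (a 1.5 Mb window by default), excluding the focal variant itself.
    """
    if lam is None:
        lam = ld.choose_lambda(lambda_mode, n_panel=panel.n)
    focal = records[records["variant_id"] == focal_id]
    if len(focal) == 0:
        raise KeyError(f"focal variant {focal_id!r} not found among records")
    focal = focal.iloc[0]
    near = (
        (records["chromosome"] == focal["chromosome"])
        & (records["position"] - focal["position"]).abs().le(tag_radius_bp)
        & (records["variant_id"] != focal_id)
    )
    tags = records[near]
    pm = panel.variants["variant_id"] == focal_id
    if not pm.any():
        raise KeyError(f"focal variant {focal_id!r} not found in panel")
    target_idx = np.array([int(np.flatnonzero(pm.to_numpy())[0])])
    if len(tags) == 0:
        return ImputationResult(focal_id, np.nan, np.nan, 0.0, 0.0, np.nan, np.nan, 0,
                                chromosome=focal["chromosome"], position=int(focal["position"]))
    res = _impute_window(tags, panel, target_idx, lam, missingness)
    row = res.iloc[0]
    return ImputationResult(
        variant_id=focal_id,
        z_imp=float(row["z_imp"]),
        a_imp=float(row["a_imp"]),
        r2_pred=float(row["r2_pred"]),
        r2_pred_adj=float(row["r2_pred_adj"]),
        n_max=float(row["N_max"]),
        p_imp=float(row["p_imp"]),
        n_tags=int(row["n_tags"]),
        chromosome=str(row["chromosome"]),
        position=int(row["position"]),
    )
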