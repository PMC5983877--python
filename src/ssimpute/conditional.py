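"""Approximate conditional analysis and the candidate-locus scan.

A variant's association conditional on a set S of reported variants is
computed from summary statistics and reference-panel LD alone: with shrunk
correlations c (target-to-S) and C (within S),

    z_cond = (z_u - c' C^{-1} z_S) / sqrt(1 - c' C^{-1} c),

the standardized residual of the target Z given the conditioners.  A window is
declared a candidate locus when at least one well-imputed variant stays
significant (conditional P <= threshold) after conditioning on all reported
variants nearby.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ld
from .impute import CORE_BP, zscore_pvalue
from .io import ReferencePanel

logger = logging.getLogger(__name__)

#: Residual variance below this is treated as non-estimable (near-perfect LD
#: with the conditioning set), not inflated into a huge statistic.
RESIDUAL_VARIANCE_FLOOR = 1e-3

P_THRESHOLD = 1e-8


@dataclass
class ConditionalResult:
    """Target association conditioned on a set of reported variants."""

    variant_id: str
    conditioning_ids: list
    z_cond: float
    p_cond: float
    ld_to_conditioners: float  # max squared correlation to the set
    estimable: bool = True


@dataclass
class CandidateLocus:
    """A window with at least one conditionally significant imputed variant."""

    chromosome: str
    start: int
    end: int
    members: pd.DataFrame = field(repr=False)
    top_variant: str = ""
    top_p_cond: float = np.nan


def conditional_z(
    z_u: float,
    z_S: np.ndarray,
    c_uS: np.ndarray,
    C_SS: np.ndarray,
    lam: float = 0.1,
    variant_id: str = "",
    conditioning_ids: list | None = None,
    variance_floor: float = RESIDUAL_VARIANCE_FLOOR,
) -> ConditionalResult:
    """Condition ``z_u`` on the variants in S; empty S is the identity."""
    conditioning_ids = conditioning_ids or []
    z_S = np.asarray(z_S, dtype=float)
    c_uS = np.asarray(c_uS, dtype=float)
    if z_S.size == 0:
        return ConditionalResult(variant_id, conditioning_ids, float(z_u),
                                 float(zscore_pvalue(z_u)), 0.0)
    C_lam, c_lam = ld.shrink(np.atleast_2d(C_SS), c_uS, lam)
    w = ld.solve_spd(C_lam, c_lam)
    resid_var = 1.0 - float(c_lam @ w)
    ld_max = float(np.max(c_uS**2))
    if resid_var < variance_floor:
        return ConditionalResult(variant_id, conditioning_ids, np.nan, np.nan, ld_max, estimable=False)
    z_cond = (float(z_u) - float(w @ z_S)) / np.sqrt(resid_var)
    return ConditionalResult(variant_id, conditioning_ids, z_cond, float(zscore_pvalue(z_cond)), ld_max)


def _panel_index_of(panel: ReferencePanel, variant_id: str) -> int | None:
    hit = np.flatnonzero((panel.variants["variant_id"] == variant_id).to_numpy())
    return int(hit[0]) if hit.size else None


def _condition_one(
    row: pd.Series,
    set2: pd.DataFrame,
    panel: ReferencePanel,
    lam: float,
) -> ConditionalResult:
    u_idx = _panel_index_of(panel, row["variant_id"])
    if u_idx is None:
        return ConditionalResult(row["variant_id"], [], np.nan, np.nan, np.nan, estimable=False)
    if set2.empty:
        return conditional_z(row["z_imp"], np.array([]), np.array([]), np.empty((0, 0)),
                             lam=lam, variant_id=row["variant_id"])
    s_idx = set2["panel_index"].to_numpy(dtype=int)
    C_SS = ld.correlation_matrix(panel, s_idx)
    c_uS = ld.cross_correlation(panel, [u_idx], s_idx)[:, 0]
    return conditional_z(
        row["z_imp"],
        set2["z"].to_numpy(dtype=float),
        c_uS,
        C_SS,
        lam=lam,
        variant_id=row["variant_id"],
        conditioning_ids=set2["variant_id"].tolist(),
    )


def _prepare_reported(reported: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Attach panel indices to reported variants; drop (with a warning) those absent."""
    idx = [(_panel_index_of(panel, vid)) for vid in reported["variant_id"]]
    present = np.array([i is not None for i in idx])
    if (~present).any():
        logger.warning("locus_scan: %d reported variants absent from panel dropped",
                       int((~present).sum()))
    out = reported.loc[present].copy()
    out["panel_index"] = [i for i in idx if i is not None]
    return out


def condition_on_reported(
    row: pd.Series,
    reported: pd.DataFrame,
    panel: ReferencePanel,
    lam: float = 0.1,
) -> ConditionalResult:
    """Condition one result row (with ``z_imp``) on a frame of reported
    variants (id/chromosome/position/z), resolving LD from the panel."""
    rep = _prepare_reported(reported, panel) if not reported.empty else reported
    return _condition_one(row, rep, panel, lam)


def locus_scan(
    imputed: pd.DataFrame,
    reported: pd.DataFrame,
    panel: ReferencePanel,
    p_threshold: float = P_THRESHOLD,
    flank_bp: int = 1_000_000,
    min_quality: float = 0.3,
    core_bp: int = CORE_BP,
    lam: float = 0.1,
) -> list[CandidateLocus]:
    """Scan imputed results for candidate loci independent of reported variants.

    Per core window: set1 = imputed variants with r2_pred_adj >= min_quality
    and imputed P <= threshold, spanning positions bp(1)..bp(2); set2 =
    reported variants within [bp(1) - flank, bp(2) + flank] on the same
    chromosome.  Each set1 member is conditioned on all of set2; the window is
    a candidate locus iff some conditional P <= threshold.  The top variant has
    the smallest conditional P (ties: smaller position, then id).
    """
    loci: list[CandidateLocus] = []
    screened = imputed[
        (imputed["source"] == "imputed")
        & (imputed["r2_pred_adj"] >= min_quality)
        & (imputed["p_imp"] <= p_threshold)
    ]
    if screened.empty:
        return loci
    rep = _prepare_reported(reported, panel)
    for chrom, grp in screened.groupby("chromosome", sort=False):
        windows = (grp["position"].to_numpy() // core_bp) * core_bp
        for w0 in np.unique(windows):
            set1 = grp[windows == w0]
            bp1, bp2 = int(set1["position"].min()), int(set1["position"].max())
            rep_chr = rep[rep["chromosome"].astype(str) == str(chrom)]
            set2 = rep_chr[
                (rep_chr["position"] >= bp1 - flank_bp) & (rep_chr["position"] <= bp2 + flank_bp)
            ]
            results = [_condition_one(row, set2, panel, lam) for _, row in set1.iterrows()]
            members = set1.copy()
            members["z_cond"] = [r.z_cond for r in results]
            members["p_cond"] = [r.p_cond for r in results]
            members["estimable"] = [r.estimable for r in results]
            ok = members[members["estimable"] & (members["p_cond"] <= p_threshold)]
            if ok.empty:
                continue
            top = ok.sort_values(["p_cond", "position", "variant_id"]).iloc[0]
            loci.append(
                CandidateLocus(
                    chromosome=str(chrom),
                    start=int(w0),
                    end=int(w0 + core_bp),
                    members=members.reset_index(drop=True),
                    top_variant=str(top["variant_id"]),
                    top_p_cond=float(top["p_cond"]),
                )
            )
    return loci


def pairwise_conditional(
    top_row: pd.Series,
    neighbors: pd.DataFrame,
    panel: ReferencePanel,
    lam: float = 0.1,
) -> float:
    """Worst-case single-conditioner P: condition the top variant on each
    neighbour in turn and return the maximum conditional P (marginal P when
    there are no neighbours)."""
    if neighbors.empty:
        return float(zscore_pvalue(top_row["z_imp"]))
    p_max = 0.0
    for _, nb in neighbors.iterrows():
        res = _condition_one(top_row, nb.to_frame().T, panel, lam)
        p = res.p_cond if res.estimable else 1.0  # explained away entirely
        p_max = max(p_max, p)
    return p_max


def merge_adjacent_loci(
    loci: list[CandidateLocus],
    panel: ReferencePanel,
    p_threshold: float = P_THRESHOLD,
    lam: float = 0.1,
) -> list[CandidateLocus]:
    """Merge neighbouring-window loci that tag the same signal.

    For each adjacent pair (same chromosome, touching windows) the weaker top
    variant is conditioned on the stronger; if its conditional P rises above
    the threshold the two loci merge and the stronger top is retained.
    """
    if not loci:
        return loci
    loci = sorted(loci, key=lambda l: (l.chromosome, l.start))
    merged: list[CandidateLocus] = []
    for locus in loci:
        if merged and merged[-1].chromosome == locus.chromosome and merged[-1].end >= locus.start:
            prev = merged[-1]
            weaker, stronger = (locus, prev) if prev.top_p_cond <= locus.top_p_cond else (prev, locus)
            w_row = weaker.members[weaker.members["variant_id"] == weaker.top_variant].iloc[0]
            s_row = stronger.members[stronger.members["variant_id"] == stronger.top_variant].iloc[0]
            cond_set = pd.DataFrame(
                {
                    "variant_id": [s_row["variant_id"]],
                    "chromosome": [s_row["chromosome"]],
                    "position": [s_row["position"]],
                    "z": [s_row["z_imp"]],
                }
            )
            cond_set = _prepare_reported(cond_set, panel)
            res = _condition_one(w_row, cond_set, panel, lam) if not cond_set.empty else None
            explained = res is None or not res.estimable or res.p_cond > p_threshold
            if explained:
                merged[-1] = CandidateLocus(
                    chromosome=stronger.chromosome,
                    start=min(prev.start, locus.start),
                    end=max(prev.end, locus.end),
                    members=pd.concat([prev.members, locus.members], ignore_index=True),
                    top_variant=stronger.top_variant,
                    top_p_cond=stronger.top_p_cond,
                )
                continue
        merged.append(locus)
    return merged
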