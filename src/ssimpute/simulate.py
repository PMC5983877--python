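"""Synthetic GWAS data with controllable LD, missingness and sample sizes.

The generator emulates the statistical structure of a meta-analysed GWAS:

* genotypes in LD blocks, produced by thresholding latent-Gaussian haplotypes;
  the latent correlation is *calibrated* (via the bivariate-normal orthant
  probability) so the realised dosage correlation matches the requested r;
* a continuous phenotype with one (or more) causal variant of fixed explained
  variance h2_snp on the standardized genotype;
* per-SNV sample sizes drawn from wide / narrow empirical-style distributions
  and rescaled to the simulated GWAS size;
* per-SNV missingness whose cross-SNV correlation is controlled by
  theta_miss in [0, 1]: 0 = independent uniform subsets, 1 = fully nested
  observation sets (maximum possible sample overlap).

All randomness flows from a single integer seed through spawned substreams,
so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import ld
from .impute import MissingnessModel, build_D, build_d, impute_z, impute_z_varN, z_to_effect
from .io import ReferencePanel

logger = logging.getLogger(__name__)

# Sample-size ranges of the two published GWAS distributions the simulator
# mimics: a very heterogeneous one ("wide") and a homogeneous one ("narrow").
WIDE_RANGE = (13, 110_219)
NARROW_RANGE = (50_000, 187_167)


@dataclass
class BlockSpec:
    """One equicorrelated LD block: all pairwise dosage correlations target ``r``."""

    n_variants: int
    r: float
    maf: float


@dataclass
class RegionSpec:
    """A simulated region: independent LD blocks laid out along one chromosome."""

    blocks: list
    chromosome: str = "1"
    start: int = 10_000
    spacing: int = 5_000


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiments.

    Defaults mirror the simulated association study the package validates
    against: a 25'000-individual cohort split half/half into an LD panel and a
    12'500-individual GWAS, one causal variant per region explaining 2% of
    phenotypic variance, and sample sizes rescaled to the GWAS size.
    """

    n_individuals: int = 25_000
    n_regions: int = 10
    variants_per_region: int = 80
    block_size_range: tuple = (4, 8)
    block_r_range: tuple = (0.6, 0.95)
    maf_range: tuple = (0.1, 0.5)
    tag_fraction: float = 0.8
    h2_snp: float = 0.02
    theta_miss: float = 1.0
    sample_size_source: str = "wide"
    seed: int = 0
    regions: list | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_snp < 1.0:
            raise ValueError("h2_snp must lie in [0, 1)")
        if not 0.0 <= self.theta_miss <= 1.0:
            raise ValueError("theta_miss must lie in [0, 1]")


_LATENT_RHO_CACHE: dict = {}


def _binary_corr(rho: float, t: float, p: float) -> float:
    """Correlation of two 1{Z > t} indicators under latent correlation rho."""
    if rho >= 1.0:
        return 1.0
    cdf = stats.multivariate_normal.cdf([t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    p11 = 1.0 - 2.0 * stats.norm.cdf(t) + cdf
    return (p11 - p * p) / (p * (1.0 - p))


def latent_rho(target_r: float, maf: float) -> float:
    """Latent-Gaussian correlation whose thresholded binaries attain ``target_r``.

    Thresholding attenuates correlation, so the latent value exceeds the
    target; solved by bisection on the orthant probability and cached.
    """
    if target_r <= 0.0:
        return float(target_r)
    key = (round(target_r, 4), round(maf, 4))
    if key in _LATENT_RHO_CACHE:
        return _LATENT_RHO_CACHE[key]
    t = stats.norm.ppf(1.0 - maf)
    f = lambda rho: _binary_corr(rho, t, maf) - target_r
    if f(0.99999) < 0:  # target not attainable; use the maximum
        out = 0.99999
    else:
        out = float(optimize.brentq(f, 0.0, 0.99999, xtol=1e-6))
    _LATENT_RHO_CACHE[key] = out
    return out


def random_regions(config: SimulationConfig, rng: np.random.Generator) -> list[RegionSpec]:
    """Draw per-region block layouts from the config's ranges.

    Block sizes, within-block target correlations and (block-constant) MAFs
    are uniform over their ranges; each region sits on its own chromosome so
    regions are trivially independent.
    """
    regions = []
    lo, hi = config.block_size_range
    for r in range(config.n_regions):
        blocks, total = [], 0
        while total < config.variants_per_region:
            size = min(int(rng.integers(lo, hi + 1)), config.variants_per_region - total)
            blocks.append(
                BlockSpec(
                    n_variants=size,
                    r=float(rng.uniform(*config.block_r_range)),
                    maf=float(rng.uniform(*config.maf_range)),
                )
            )
            total += size
        regions.append(RegionSpec(blocks=blocks, chromosome=str(r + 1)))
    return regions


def _draw_block_dosages(n: int, block: BlockSpec, rng: np.random.Generator) -> np.ndarray:
    """Dosages for one equicorrelated block: two thresholded latent haplotypes."""
    m = block.n_variants
    t = stats.norm.ppf(1.0 - block.maf)
    rho = latent_rho(block.r, block.maf) if m > 1 else 0.0
    g = np.zeros((n, m))
    for _ in range(2):  # two haplotypes per individual
        shared = rng.standard_normal((n, 1))
        indiv = rng.standard_normal((n, m))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
        g += z > t
    return g


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Simulate the full cohort's dosage panel.

    Variant metadata carries region/block bookkeeping plus ``is_tag`` (typed
    in the GWAS, a ``tag_fraction`` draw per block) and ``is_causal`` (one
    untyped variant per region, in a block with at least two tags).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regions = config.regions if config.regions is not None else random_regions(config, rng)
    cols, meta = [], []
    b = -1  # block ids are global so regions sharing a chromosome stay distinct
    for region in regions:
        pos = region.start
        for block in region.blocks:
            b += 1
            cols.append(_draw_block_dosages(config.n_individuals, block, rng))
            is_tag = rng.random(block.n_variants) < config.tag_fraction
            if block.n_variants > 1 and is_tag.sum() == block.n_variants:
                is_tag[rng.integers(block.n_variants)] = False  # keep an imputable variant
            for j in range(block.n_variants):
                meta.append(
                    {
                        "variant_id": f"rs{region.chromosome}_{pos}",
                        "chromosome": region.chromosome,
                        "position": pos,
                        "ref": "A",
                        "alt": "G",
                        "block": b,
                        "block_r": block.r,
                        "maf_target": block.maf,
                        "is_tag": bool(is_tag[j]),
                        "is_causal": False,
                    }
                )
                pos += region.spacing
    panel = ReferencePanel(np.concatenate(cols, axis=1), pd.DataFrame(meta))
    _assign_causals(panel, rng)
    return panel


def _assign_causals(panel: ReferencePanel, rng: np.random.Generator) -> None:
    """Mark one causal variant per chromosome: untyped, in a block with >= 2 tags."""
    v = panel.variants
    for chrom, grp in v.groupby("chromosome", sort=False):
        good_blocks = [
            b for b, bg in grp.groupby("block")
            if bg["is_tag"].sum() >= 2 and (~bg["is_tag"]).any()
        ]
        if not good_blocks:
            logger.warning("region %s has no block suitable for a causal variant", chrom)
            continue
        block = good_blocks[int(rng.integers(len(good_blocks)))]
        cand = grp[(grp["block"] == block) & (~grp["is_tag"])]
        v.loc[cand.index[int(rng.integers(len(cand)))], "is_causal"] = True


def split_panel(
    panel: ReferencePanel, fraction: float = 0.5, rng: np.random.Generator | None = None
) -> tuple[ReferencePanel, ReferencePanel]:
    """Random disjoint individual split: (LD-estimation panel, GWAS panel).

    ``fraction`` is the LD-panel share; the halves differ in size by <= 1 at
    the default 0.5.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = panel.n
    perm = rng.permutation(n)
    k = int(round(n * fraction))
    return panel.subset_individuals(perm[:k]), panel.subset_individuals(perm[k:])


def simulate_phenotype(
    gwas_panel: ReferencePanel,
    causal_indices,
    h2_snp,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Continuous phenotype ``y = sum_i sqrt(h2_i) g_i_std + e``, Var(e) = 1 - sum h2.

    ``causal_indices`` may be a scalar or a sequence; ``h2_snp`` likewise.
    The true standardized effect of causal i is sqrt(h2_i).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    causal_indices = np.atleast_1d(np.asarray(causal_indices, dtype=int))
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(h2_snp, dtype=float)), causal_indices.shape)
    if h2.sum() >= 1.0:
        raise ValueError("total explained variance must be < 1")
    n = gwas_panel.n
    y = np.sqrt(1.0 - h2.sum()) * rng.standard_normal(n)
    for idx, h in zip(causal_indices, h2):
        g = gwas_panel.dosages_imputed()[:, idx]
        sd = g.std()
        if sd == 0:
            raise ValueError(f"causal variant column {idx} is constant")
        y = y + np.sqrt(h) * (g - g.mean()) / sd
    return y


def draw_sample_sizes(
    source: str,
    m: int,
    scale_to: int,
    rng: np.random.Generator | None = None,
    values=None,
) -> np.ndarray:
    """Per-SNV sample sizes, rescaled so the distribution's maximum maps to ``scale_to``.

    ``wide``: log-uniform over [13, 110219] (very heterogeneous meta-analysis);
    ``narrow``: uniform over [50000, 187167]; ``list``: resampled from
    ``values``.  Result is clipped to [1, scale_to].
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if source == "wide":
        raw = np.exp(rng.uniform(np.log(WIDE_RANGE[0]), np.log(WIDE_RANGE[1]), size=m))
        top = WIDE_RANGE[1]
    elif source == "narrow":
        raw = rng.uniform(*NARROW_RANGE, size=m)
        top = NARROW_RANGE[1]
    elif source == "list":
        if values is None or len(values) == 0:
            raise ValueError("source='list' requires a non-empty values sequence")
        values = np.asarray(values, dtype=float)
        raw = rng.choice(values, size=m, replace=True)
        top = values.max()
    else:
        raise ValueError(f"unknown sample-size source {source!r}")
    return np.clip(np.round(raw * scale_to / top), 1, scale_to).astype(int)


def assign_missingness(
    N_targets,
    n_individuals: int,
    theta_miss: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean observed-mask (n_individuals x m) with |set_k| = N_k exactly.

    Each individual gets the score ``theta * rank/n + (1 - theta) * u_ik``
    against a shared random ordering; the N_k lowest scores are observed.
    theta=1 gives fully nested sets (pairwise overlap min(N_k, N_l)); theta=0
    gives independent uniform subsets (expected overlap N_k N_l / n).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    N_targets = np.asarray(N_targets, dtype=int)
    if np.any(N_targets > n_individuals):
        raise ValueError("sample sizes cannot exceed the number of individuals")
    n, m = n_individuals, len(N_targets)
    rank = np.empty(n)
    rank[rng.permutation(n)] = np.arange(n) / n
    mask = np.zeros((n, m), dtype=bool)
    for k, Nk in enumerate(N_targets):
        score = theta_miss * rank + (1.0 - theta_miss) * rng.random(n)
        mask[np.argpartition(score, Nk - 1)[:Nk], k] = True
    return mask


def run_gwas(
    gwas_panel: ReferencePanel,
    phenotype: np.ndarray,
    mask: np.ndarray | None = None,
    variant_indices=None,
) -> pd.DataFrame:
    """Per-SNV standardized regression on each variant's observed subset.

    For variant k with observed set O_k: both y and g are standardized on O_k
    (zero mean, unit variance), a_k = g'y / N_k and z_k = a_k * sqrt(N_k).
    Variants whose observed genotypes are constant are dropped with a warning.
    Returns a frame in the summary-statistics column contract.
    """
    y = np.asarray(phenotype, dtype=float)
    idx = np.arange(gwas_panel.m) if variant_indices is None else np.asarray(variant_indices)
    g_all = gwas_panel.dosages_imputed()
    rows, dropped = [], 0
    v = gwas_panel.variants
    for j, k in enumerate(idx):
        obs = slice(None) if mask is None else mask[:, j]
        g = g_all[obs, k]
        yy = y[obs]
        Nk = g.shape[0]
        sd = g.std()
        if sd == 0 or yy.std() == 0 or Nk < 2:
            dropped += 1
            continue
        gs = (g - g.mean()) / sd
        ys = (yy - yy.mean()) / yy.std()
        a = float(gs @ ys) / Nk
        rows.append(
            {
                "variant_id": v.iloc[k]["variant_id"],
                "chromosome": str(v.iloc[k]["chromosome"]),
                "position": int(v.iloc[k]["position"]),
                "effect_allele": v.iloc[k]["alt"],
                "other_allele": v.iloc[k]["ref"],
                "z": a * np.sqrt(Nk),
                "sample_size": Nk,
                "allele_freq": g.mean() / 2.0,
                "panel_index": int(k),
            }
        )
    if dropped:
        # expected for tiny observed subsets under heavy missingness
        level = logging.DEBUG if mask is not None else logging.WARNING
        logger.log(level, "run_gwas: dropped %d variants with undefined statistics", dropped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation experiments
# ---------------------------------------------------------------------------


def _region_indices(panel: ReferencePanel, chrom: str) -> dict:
    v = panel.variants
    on = v["chromosome"] == chrom
    return {
        "tags": np.flatnonzero((on & v["is_tag"]).to_numpy()),
        "causal": int(np.flatnonzero((on & v["is_causal"]).to_numpy())[0]),
    }


def variable_sample_size_experiment(
    distributions=("wide", "narrow"),
    thetas=(0.0, 0.5, 1.0),
    replicates: int = 50,
    config: SimulationConfig | None = None,
    lam: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """MSE of the imputed standardized effect under three estimators.

    For each region the causal (untyped) variant is masked and its
    standardized effect imputed from the tag summaries under (a) the
    conventional estimator that ignores missingness, (b) the maximal-overlap
    ("dependent") and (c) the random-overlap ("independent") adjustment, and
    compared against the known truth sqrt(h2).  Regions' genotypes are fixed
    across replicates; sample sizes, missingness masks and phenotypes are
    redrawn each replicate.  Returns a tidy frame:
    distribution, theta_miss, region, method, mse.
    """
    config = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    ss_geno, ss_split, ss_rep = root.spawn(3)
    panel = simulate_genotypes(config, np.random.default_rng(ss_geno))
    ld_half, gwas_half = split_panel(panel, 0.5, np.random.default_rng(ss_split))
    n_gwas = gwas_half.n
    alpha_true = np.sqrt(config.h2_snp)

    regions = []
    for chrom in panel.variants["chromosome"].unique():
        info = _region_indices(panel, chrom)
        C = ld.correlation_matrix(ld_half, info["tags"])
        c = ld.cross_correlation(ld_half, [info["causal"]], info["tags"])[:, 0]
        regions.append((chrom, info, C, c))

    rng = np.random.default_rng(ss_rep)
    records = []
    for dist in distributions:
        for theta in thetas:
            errors: dict = {}
            for _ in range(replicates):
                for chrom, info, C, c in regions:
                    q = len(info["tags"])
                    N = draw_sample_sizes(dist, q, n_gwas, rng)
                    m_mask = assign_missingness(N, n_gwas, theta, rng)
                    y = simulate_phenotype(gwas_half, info["causal"], config.h2_snp, rng)
                    summary = run_gwas(gwas_half, y, mask=m_mask, variant_indices=info["tags"])
                    if summary.empty:
                        continue
                    keep = np.isin(info["tags"], summary["panel_index"].to_numpy())
                    sub = np.flatnonzero(keep)
                    C_lam, c_lam = ld.shrink(C[np.ix_(sub, sub)], c[sub], lam)
                    z = summary["z"].to_numpy()
                    Nk = summary["sample_size"].to_numpy(dtype=float)

                    a_conv = impute_z(z / np.sqrt(Nk), C_lam, c_lam)
                    ests = {"conventional": a_conv}
                    for mode in ("dependent", "independent"):
                        model = MissingnessModel(mode=mode, N=Nk)
                        D = build_D(C_lam, model)
                        d = build_d(c_lam, model)
                        z_hat = impute_z_varN(z, d, D)
                        quality = ld.impute_quality(d, D, clamp=False)
                        ests[mode] = z_to_effect(z_hat, model.N_max, quality)
                    for method, a_hat in ests.items():
                        if np.isnan(a_hat):
                            continue
                        errors.setdefault((chrom, method), []).append((a_hat - alpha_true) ** 2)
            for (chrom, method), errs in errors.items():
                records.append(
                    {
                        "distribution": dist,
                        "theta_miss": theta,
                        "region": chrom,
                        "method": method,
                        "mse": float(np.mean(errs)),
                        "n_replicates": len(errs),
                    }
                )
    return pd.DataFrame(records)
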