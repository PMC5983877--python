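"""End-to-end simulation studies composing the generator, imputation and scan.

Three drivers:

* :func:`null_fpr_experiment` — GWAS statistics on null phenotypes across
  independent variants; their P-values must be uniform, so the false positive
  rate should track the significance level.
* :func:`power_comparison_experiment` — power of imputed vs directly computed
  statistics at a weakly causal variant, under well- and poorly-tagged LD, to
  quantify the power cost of imputing instead of genotyping.
* :func:`locus_recovery_experiment` — a two-signal region (one reported, one
  novel and independent); the candidate-locus scan must keep exactly the novel
  signal after conditioning on the reported one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import conditional, ld
from .impute import window_impute, zscore_pvalue
from .io import ReferencePanel
from .simulate import (
    BlockSpec,
    RegionSpec,
    SimulationConfig,
    run_gwas,
    simulate_genotypes,
    simulate_phenotype,
    split_panel,
)


def null_correlation_se(
    n: int = 3871,
    pairs: int = 100_000,
    seed: int = 0,
    batch: int = 2500,
) -> float:
    """Empirical SD of the sample correlation of independent pairs at panel size n.

    Quantifies the noise floor of reference-panel LD estimates: under zero
    true correlation the sampling SE is ~ 1/sqrt(n).
    """
    rng = np.random.default_rng(seed)
    sums = np.empty(pairs)
    done = 0
    while done < pairs:
        b = min(batch, pairs - done)
        x = rng.standard_normal((n, b))
        y = rng.standard_normal((n, b))
        x = (x - x.mean(0)) / x.std(0)
        y = (y - y.mean(0)) / y.std(0)
        sums[done:done + b] = np.einsum("ij,ij->j", x, y) / n
        done += b
    return float(sums.std())


def masked_imputation_oracle_check(
    n_panel: int = 5000,
    n_variants: int = 50,
    n_masked: int = 10,
    seed: int = 0,
) -> float:
    """Max relative error of impute_z against an independent linear solve.

    GWAS individuals equal the panel individuals, no missingness, lambda = 0,
    so the imputed z must equal ``c' C^{-1} z`` computed by a generic solver.
    Also asserts that the variable-N path with equal sample sizes is bitwise
    identical to the base path.  Returns the max relative discrepancy.
    """
    root = np.random.SeedSequence(seed)
    ss_geno, ss_phen = root.spawn(2)
    rng = np.random.default_rng(ss_geno)
    blocks = [BlockSpec(5, float(r), float(m))
              for r, m in zip(rng.uniform(0.4, 0.9, n_variants // 5),
                              rng.uniform(0.1, 0.5, n_variants // 5))]
    config = SimulationConfig(n_individuals=n_panel, regions=[RegionSpec(blocks=blocks)])
    panel = simulate_genotypes(config, rng)
    prng = np.random.default_rng(ss_phen)
    y = simulate_phenotype(panel, n_variants // 2, 0.01, prng)
    summary = run_gwas(panel, y)
    z_all = summary.set_index("panel_index")["z"]

    from .impute import MissingnessModel, build_D, build_d, impute_z, impute_z_varN

    max_rel = 0.0
    targets = prng.choice(panel.m, size=n_masked, replace=False)
    for u in targets:
        tags = np.array([k for k in range(panel.m) if k != u])
        C = ld.correlation_matrix(panel, tags)
        c = ld.cross_correlation(panel, [u], tags)[:, 0]
        z = z_all.loc[tags].to_numpy()
        z_pkg = impute_z(z, C, c)  # lambda = 0: no shrinkage applied
        z_oracle = float(c @ np.linalg.solve(C, z))
        max_rel = max(max_rel, abs(z_pkg - z_oracle) / max(1e-12, abs(z_oracle)))

        model = MissingnessModel(mode="dependent", N=np.full(len(tags), float(panel.n)))
        z_varn = impute_z_varN(z, build_d(c, model), build_D(C, model))
        if z_varn != z_pkg:
            raise AssertionError("variable-N path with equal N is not bitwise identical")
    return max_rel


def null_fpr_experiment(
    n_variants: int = 2000,
    n_phenotypes: int = 5,
    n_individuals: int = 2500,
    maf_range=(0.1, 0.5),
    seed: int = 0,
) -> np.ndarray:
    """P-values of per-SNV association tests under the global null.

    ``n_variants`` mutually independent variants are tested against
    ``n_phenotypes`` independent standard-normal phenotypes; because both the
    variants and the phenotypes are independent, the pooled P-values are
    i.i.d. uniform and binomial error bars apply to the empirical FPR.
    """
    root = np.random.SeedSequence(seed)
    ss_geno, ss_phen = root.spawn(2)
    rng = np.random.default_rng(ss_geno)
    regions = [
        RegionSpec(blocks=[BlockSpec(1, 0.0, float(m)) for m in rng.uniform(*maf_range, n_variants)])
    ]
    config = SimulationConfig(n_individuals=n_individuals, regions=regions)
    panel = simulate_genotypes(config, rng)
    prng = np.random.default_rng(ss_phen)
    pvals = []
    for _ in range(n_phenotypes):
        y = prng.standard_normal(panel.n)
        summary = run_gwas(panel, y)
        pvals.append(zscore_pvalue(summary["z"].to_numpy()))
    return np.concatenate(pvals)


def _tagged_region_panels(
    r: float,
    n_block: int,
    maf: float,
    n_total: int,
    ld_fraction: float,
    rng: np.random.Generator,
) -> tuple[ReferencePanel, ReferencePanel]:
    region = RegionSpec(blocks=[BlockSpec(n_block, r, maf)])
    config = SimulationConfig(n_individuals=n_total, regions=[region])
    panel = simulate_genotypes(config, rng)
    return split_panel(panel, ld_fraction, rng)


def power_comparison_experiment(
    replicates: int = 150,
    h2_snp: float = 0.0001,
    n_gwas: int = 12_500,
    n_ld_panel: int = 2500,
    block_size: int = 16,
    maf: float = 0.3,
    r_levels=(0.2, 0.9),
    lam: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct vs imputed P-values at a weak causal variant, by tagging quality.

    One equicorrelated block per LD level; the causal variant is typed for the
    direct statistic and masked (imputed from the remaining tags) for the
    imputed one.  Genotypes are fixed per LD level; phenotypes are redrawn
    each replicate.  Returns one row per (LD level, replicate) with the
    imputation quality and both P-values.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for r_level, ss in zip(r_levels, root.spawn(len(r_levels))):
        ss_geno, ss_rep = ss.spawn(2)
        rng = np.random.default_rng(ss_geno)
        n_total = n_gwas + n_ld_panel
        ld_half, gwas_half = _tagged_region_panels(
            r_level, block_size, maf, n_total, n_ld_panel / n_total, rng
        )
        causal = 0
        tags = np.arange(1, block_size)
        C = ld.correlation_matrix(ld_half, tags)
        c = ld.cross_correlation(ld_half, [causal], tags)[:, 0]
        C_lam, c_lam = ld.shrink(C, c, lam)
        quality = ld.impute_quality(c_lam, C_lam)
        q_eff = ld.effective_num_variants(C)
        quality_adj = ld.adjust_quality(quality, ld_half.n, q_eff)
        w = ld.solve_spd(C_lam, c_lam)

        rep_rng = np.random.default_rng(ss_rep)
        for rep in range(replicates):
            y = simulate_phenotype(gwas_half, causal, h2_snp, rep_rng)
            summary = run_gwas(gwas_half, y)
            z = summary.set_index("panel_index")["z"]
            z_direct = float(z.loc[causal])
            z_imp = float(w @ z.loc[tags].to_numpy())
            rows.append(
                {
                    "block_r": r_level,
                    "replicate": rep,
                    "r2_pred": quality,
                    "r2_pred_adj": quality_adj,
                    "p_direct": float(zscore_pvalue(z_direct)),
                    "p_imputed": float(zscore_pvalue(z_imp)),
                }
            )
    return pd.DataFrame(rows)


def _two_signal_panel(
    n_total: int,
    ld_fraction: float,
    rng: np.random.Generator,
    block_size: int = 8,
    r: float = 0.9,
    maf: float = 0.3,
) -> tuple[ReferencePanel, ReferencePanel, dict]:
    """Two independent high-LD blocks ~900 kb apart on one chromosome.

    Block A holds the "reported" signal (typed lead + three untyped decoys);
    block B holds the novel signal at an untyped causal variant tagged by the
    rest of its block.
    """
    regions = [
        RegionSpec(blocks=[BlockSpec(block_size, r, maf)], chromosome="1", start=476_000),
        RegionSpec(blocks=[BlockSpec(block_size, r, maf)], chromosome="1", start=1_376_000),
    ]
    config = SimulationConfig(n_individuals=n_total, regions=regions)
    panel = simulate_genotypes(config, rng)
    idx_a = np.arange(block_size)
    idx_b = np.arange(block_size, 2 * block_size)
    layout = {
        "reported": int(idx_a[0]),
        "decoys": idx_a[[2, 4, 6]].tolist(),
        "novel": int(idx_b[3]),
    }
    untyped = set(layout["decoys"]) | {layout["novel"]}
    typed = np.array([i for i in range(2 * block_size) if i not in untyped])
    layout["typed"] = typed
    ld_half, gwas_half = split_panel(panel, ld_fraction, rng)
    return ld_half, gwas_half, layout


def locus_recovery_experiment(
    replicates: int = 100,
    h2_each: float = 0.01,
    n_gwas: int = 12_500,
    n_ld_panel: int = 2500,
    p_threshold: float = 1e-8,
    seed: int = 0,
) -> pd.DataFrame:
    """Candidate-locus scan on a planted two-signal truth.

    Each replicate simulates a GWAS where a *reported* (typed) variant and an
    independent *novel* (untyped) variant each explain ``h2_each`` of the
    phenotype.  Untyped proxies of the reported signal reach genome-wide
    significance when imputed, but must be conditioned away; the novel
    variant's window must survive.  Returns one row per replicate with the
    number of surviving loci and whether exactly the novel locus survived.
    """
    root = np.random.SeedSequence(seed)
    ss_geno, ss_rep = root.spawn(2)
    n_total = n_gwas + n_ld_panel
    rng = np.random.default_rng(ss_geno)
    ld_half, gwas_half, layout = _two_signal_panel(n_total, n_ld_panel / n_total, rng)
    novel_id = ld_half.variants.iloc[layout["novel"]]["variant_id"]
    novel_window = int(ld_half.variants.iloc[layout["novel"]]["position"] // 1_000_000) * 1_000_000
    reported_meta = ld_half.variants.iloc[layout["reported"]]

    rep_rng = np.random.default_rng(ss_rep)
    rows = []
    for rep in range(replicates):
        y = simulate_phenotype(gwas_half, [layout["reported"], layout["novel"]], h2_each, rep_rng)
        records = run_gwas(gwas_half, y, variant_indices=layout["typed"])
        imputed = window_impute(records, ld_half, missingness="none")
        z_rep = records.set_index("panel_index")["z"].get(layout["reported"], np.nan)
        reported = pd.DataFrame(
            {
                "variant_id": [reported_meta["variant_id"]],
                "chromosome": [str(reported_meta["chromosome"])],
                "position": [int(reported_meta["position"])],
                "z": [z_rep],
            }
        )
        loci = conditional.locus_scan(imputed, reported, ld_half, p_threshold=p_threshold)
        loci = conditional.merge_adjacent_loci(loci, ld_half, p_threshold=p_threshold)
        novel_only = len(loci) == 1 and loci[0].start == novel_window
        rows.append(
            {
                "replicate": rep,
                "n_loci": len(loci),
                "novel_locus_survives": any(l.start == novel_window for l in loci),
                "novel_only": bool(novel_only),
                "top_is_novel": bool(novel_only and loci[0].top_variant == novel_id),
            }
        )
    return pd.DataFrame(rows)
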