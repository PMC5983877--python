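"""Reading, writing and harmonising GWAS summary statistics and reference panels.

Summary statistics live in a :class:`pandas.DataFrame` with the column contract

    variant_id, chromosome, position, effect_allele, other_allele, z, sample_size
    [, allele_freq]

(``position`` is 1-based; window arithmetic elsewhere uses half-open bp
intervals ``[start, end)``).  Reference panels are wrapped in
:class:`ReferencePanel`: an ``n individuals x m variants`` dosage matrix in
``[0, 2]`` (``NaN`` = missing genotype) plus a variant-metadata frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "z",
    "sample_size",
]

#: Strand-ambiguous allele pairs that cannot be oriented without strand info.
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association summary (Z-statistic scale)."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    z: float
    sample_size: int
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if self.sample_size < 1:
            raise ValueError(f"{self.variant_id}: sample_size must be >= 1")

    @classmethod
    def from_beta_se(cls, *, beta: float, se: float, **kwargs) -> "SummaryRecord":
        if se <= 0:
            raise ValueError("standard error must be > 0")
        return cls(z=beta / se, **kwargs)


@dataclass
class ReferencePanel:
    """Dosage matrix (n individuals x m variants) with per-variant metadata.

    ``variants`` columns: variant_id, chromosome, position, ref, alt, alt_freq.
    Missing dosages are NaN; :meth:`dosages_imputed` mean-imputes per variant so
    correlation estimates stay valid without dropping individuals.
    """

    dosages: np.ndarray
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage columns ({self.dosages.shape[1]}) != metadata rows ({len(self.variants)})"
            )
        self.variants = self.variants.reset_index(drop=True)
        if "alt_freq" not in self.variants.columns:
            with np.errstate(invalid="ignore"):
                self.variants["alt_freq"] = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n(self) -> int:
        """Number of individuals in the panel."""
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        """Number of variants in the panel."""
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        f = self.variants["alt_freq"].to_numpy(dtype=float)
        return np.minimum(f, 1.0 - f)

    def dosages_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the variant mean (cached)."""
        cached = getattr(self, "_imputed_cache", None)
        if cached is not None:
            return cached
        g = self.dosages
        if np.isnan(g).any():
            g = g.copy()
            col_mean = np.nanmean(g, axis=0)
            idx = np.where(np.isnan(g))
            g[idx] = np.take(col_mean, idx[1])
        self._imputed_cache = g
        return g

    def subset(self, variant_mask) -> "ReferencePanel":
        variant_mask = np.asarray(variant_mask)
        if variant_mask.dtype == bool:
            variant_mask = np.flatnonzero(variant_mask)
        return ReferencePanel(
            self.dosages[:, variant_mask],
            self.variants.iloc[variant_mask].reset_index(drop=True),
        )

    def subset_individuals(self, rows) -> "ReferencePanel":
        return ReferencePanel(self.dosages[np.asarray(rows), :], self.variants.copy())

    def region(self, chromosome: str, start: int | None = None, end: int | None = None) -> "ReferencePanel":
        """Variants on ``chromosome`` with position in half-open ``[start, end)``."""
        v = self.variants
        mask = v["chromosome"].astype(str) == str(chromosome)
        if start is not None:
            mask &= v["position"] >= start
        if end is not None:
            mask &= v["position"] < end
        return self.subset(mask.to_numpy())


def read_summary(path, column_map: dict[str, str], sep: str = "\t") -> pd.DataFrame:
    """Read delimited summary statistics into the standard column contract.

    ``column_map`` maps roles to header names.  Mandatory roles: ``id``,
    ``chr``, ``pos``, ``effect_allele``, ``other_allele``, ``n`` and either
    ``z`` or both ``beta`` and ``se``.  Optional: ``freq``.  Rows with
    non-numeric z (or beta/se) or N are dropped with a logged count; duplicate
    (chr, pos, alleles) rows keep the first occurrence.
    """
    mandatory = ["id", "chr", "pos", "effect_allele", "other_allele", "n"]
    for role in mandatory:
        if role not in column_map:
            raise KeyError(f"column_map is missing the mandatory role {role!r}")
    has_z = "z" in column_map
    if not has_z and not ("beta" in column_map and "se" in column_map):
        raise KeyError("column_map must provide role 'z' or both 'beta' and 'se'")

    raw = pd.read_csv(path, sep=sep, comment="#")
    for role, col in column_map.items():
        if col not in raw.columns:
            raise KeyError(f"role {role!r}: column {col!r} not found in header")

    df = pd.DataFrame(
        {
            "variant_id": raw[column_map["id"]].astype(str),
            "chromosome": raw[column_map["chr"]].astype(str),
            "position": pd.to_numeric(raw[column_map["pos"]], errors="coerce"),
            "effect_allele": raw[column_map["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[column_map["other_allele"]].astype(str).str.upper(),
            "sample_size": pd.to_numeric(raw[column_map["n"]], errors="coerce"),
        }
    )
    if has_z:
        df["z"] = pd.to_numeric(raw[column_map["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[column_map["beta"]], errors="coerce")
        se = pd.to_numeric(raw[column_map["se"]], errors="coerce")
        se = se.where(se > 0)
        df["z"] = beta / se
    if "freq" in column_map:
        df["allele_freq"] = pd.to_numeric(raw[column_map["freq"]], errors="coerce")

    bad = df["z"].isna() | df["sample_size"].isna() | df["position"].isna()
    if bad.any():
        logger.warning("read_summary: dropped %d rows with non-numeric z/N/position", int(bad.sum()))
        df = df[~bad]

    dup = df.duplicated(subset=["chromosome", "position", "effect_allele", "other_allele"], keep="first")
    if dup.any():
        logger.warning("read_summary: dropped %d duplicated (chr,pos,alleles) rows", int(dup.sum()))
        df = df[~dup]

    df["position"] = df["position"].astype(int)
    df["sample_size"] = df["sample_size"].astype(int)
    df = df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    return df


def write_summary(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a summary (or imputation-result) frame as TSV, optionally with ``#`` header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _dosage_from_gt(variant, n_samples: int) -> np.ndarray:
    gts = variant.gt_types  # 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
    out = gts.astype(float)
    out[gts == 3] = np.nan
    return out


def read_panel_vcf(path, region: tuple[str, int, int] | None = None) -> ReferencePanel:
    """Read a VCF into a :class:`ReferencePanel` (DS field if present, else GT).

    ``region`` is ``(chromosome, start, end)`` with a half-open bp interval.
    Multi-allelic sites are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    n_samples = len(vcf.samples)
    cols, meta = [], []
    n_multi = 0
    for variant in vcf:
        if region is not None:
            chrom, start, end = region
            if str(variant.CHROM) != str(chrom) or not (start <= variant.POS < end):
                continue
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        fmts = variant.FORMAT
        if "DS" in fmts:
            ds = np.asarray(variant.format("DS"), dtype=float).reshape(n_samples)
        else:
            ds = _dosage_from_gt(variant, n_samples)
        cols.append(ds)
        meta.append(
            {
                "variant_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chromosome": str(variant.CHROM),
                "position": int(variant.POS),
                "ref": variant.REF.upper(),
                "alt": variant.ALT[0].upper(),
            }
        )
    if n_multi:
        logger.warning("read_panel_vcf: skipped %d multi-allelic sites", n_multi)
    if not cols:
        dos = np.empty((n_samples, 0))
        variants = pd.DataFrame(columns=["variant_id", "chromosome", "position", "ref", "alt"])
        return ReferencePanel(dos, variants)
    return ReferencePanel(np.column_stack(cols), pd.DataFrame(meta))


def read_panel_matrix(dosage_path, metadata_path, region: tuple[str, int, int] | None = None) -> ReferencePanel:
    """Read the plain-matrix panel layout.

    ``dosage_path``: TSV, one variant per column (header = variant ids), one
    individual per row, entries in [0,2], empty/NA = missing.  ``metadata_path``:
    TSV with columns variant_id, chromosome, position, ref, alt in column order
    matching the dosage header.
    """
    dos = pd.read_csv(dosage_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"chromosome": str})
    if list(dos.columns) != list(meta["variant_id"].astype(str)):
        raise ValueError("dosage header does not match metadata variant order")
    panel = ReferencePanel(dos.to_numpy(dtype=float), meta)
    if region is not None:
        panel = panel.region(*region)
    return panel


def read_panel(path, metadata_path=None, region: tuple[str, int, int] | None = None) -> ReferencePanel:
    """Dispatch on file type: ``.vcf``/``.vcf.gz`` -> VCF, otherwise plain matrix."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_panel_vcf(path, region=region)
    if metadata_path is None:
        raise ValueError("plain-matrix panels require metadata_path")
    return read_panel_matrix(path, metadata_path, region=region)


def is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in PALINDROMIC_PAIRS


def harmonize(
    records: pd.DataFrame, panel: ReferencePanel, drop_palindromic: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align summary records to the panel's (ref, alt) allele coding.

    For each record matching a panel variant on (chromosome, position):

    * effect allele == panel alt  -> kept as is;
    * effect allele == panel ref (and other == alt) -> z sign flipped and the
      alleles swapped, so the effect allele is always the panel alt;
    * any other allele combination -> excluded (``mismatch``);
    * A/T and C/G pairs -> excluded (``palindromic``) when ``drop_palindromic``
      (strand flips are never inferred for them).

    Returns ``(aligned, exclusions)``; ``aligned`` gains a ``panel_index``
    column.  Every input record lands in exactly one of the two frames, so
    harmonisation is idempotent.
    """
    v = panel.variants
    panel_key = pd.DataFrame(
        {
            "chromosome": v["chromosome"].astype(str),
            "position": v["position"].astype(int),
            "ref": v["ref"].astype(str).str.upper(),
            "alt": v["alt"].astype(str).str.upper(),
            "panel_index": np.arange(len(v)),
        }
    )
    merged = records.merge(panel_key, on=["chromosome", "position"], how="left")

    reasons = pd.Series(pd.NA, index=merged.index, dtype="object")
    reasons[merged["panel_index"].isna()] = "not_in_panel"

    pal = merged.apply(lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1)
    if drop_palindromic:
        reasons[reasons.isna() & pal] = "palindromic"

    same = (merged["effect_allele"] == merged["alt"]) & (merged["other_allele"] == merged["ref"])
    flipped = (merged["effect_allele"] == merged["ref"]) & (merged["other_allele"] == merged["alt"])
    reasons[reasons.isna() & ~(same | flipped)] = "mismatch"

    excluded = reasons.notna()
    exclusions = merged.loc[excluded, list(records.columns)].copy()
    exclusions["reason"] = reasons[excluded].to_numpy()

    aligned = merged.loc[~excluded].copy()
    flip = flipped.loc[~excluded]
    aligned.loc[flip, "z"] = -aligned.loc[flip, "z"]
    aligned.loc[flip, ["effect_allele", "other_allele"]] = aligned.loc[
        flip, ["other_allele", "effect_allele"]
    ].to_numpy()
    if "allele_freq" in aligned.columns:
        aligned.loc[flip, "allele_freq"] = 1.0 - aligned.loc[flip, "allele_freq"]
    aligned["panel_index"] = aligned["panel_index"].astype(int)
    aligned = aligned.drop(columns=["ref", "alt"]).reset_index(drop=True)

    counts = exclusions["reason"].value_counts().to_dict()
    if counts:
        logger.info("harmonize: excluded %s", counts)
    return aligned, exclusions.reset_index(drop=True)
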