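"""Instrumental-variable selection for two-sample MR.

Instruments for an exposure trait are selected in three stages, using the
conventional thresholds for microbiome/immune-trait GWAS as defaults:

1. association: keep SNPs with p < 1e-5 (genome-wide suggestive);
2. independence: greedy LD clumping at r² < 0.001 within a 10,000 kb
   window, keeping the most significant SNP of each clump;
3. strength: the trait-level F-statistic
   F = ((N - k - 1) / k) · (R² / (1 - R²)), with R² the summed per-SNP
   variance explained 2·MAF·(1-MAF)·β²; instrument sets with F < 10 are
   excluded as weak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDInfo, TraitTable


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure trait plus strength summary."""

    trait_id: str
    table: TraitTable
    r2_per_snp: dict[str, float] = field(default_factory=dict)
    r2_total: float = 0.0
    f_stat: float = float("nan")
    exclusion_reason: str | None = None

    @property
    def k(self) -> int:
        return self.table.n_snps


def select_by_pvalue(table: TraitTable, threshold: float = 1e-5) -> TraitTable:
    """Subset to SNPs with p < threshold, preserving row order."""
    kept = table.df[table.df["p"] < threshold].reset_index(drop=True)
    return TraitTable(table.trait_id, table.trait_type, kept,
                      dict(table.rejections))


def ld_clump(table: TraitTable, ld: LDInfo, r2_threshold: float = 0.001,
             window_kb: int = 10_000) -> TraitTable:
    """Greedy LD clumping: most significant SNP per clump survives.

    SNPs are visited in ascending (p, snp_id) order — the snp_id
    tie-break makes the pass deterministic and order-invariant. A SNP is
    accepted iff no already-accepted SNP on the same chromosome lies
    within ``window_kb`` kilobases with r² ≥ ``r2_threshold``. A pair
    absent from ``ld`` is treated as r²=0.
    """
    df = table.df
    if df.empty:
        return TraitTable(table.trait_id, table.trait_type, df.copy(),
                          dict(table.rejections))
    order = df.sort_values(["p", "snp"], kind="mergesort")
    accepted: list[int] = []
    window_bp = window_kb * 1000
    for idx, row in order.iterrows():
        ok = True
        for aidx in accepted:
            arow = df.loc[aidx]
            if arow["chrom"] != row["chrom"]:
                continue
            if pd.notna(row["pos"]) and pd.notna(arow["pos"]) \
                    and abs(int(row["pos"]) - int(arow["pos"])) > window_bp:
                continue
            if ld.r2(row["snp"], arow["snp"]) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(idx)
    kept = df.loc[sorted(accepted)].reset_index(drop=True)
    return TraitTable(table.trait_id, table.trait_type, kept,
                      dict(table.rejections))


def snp_r2(eaf: float, beta: float, se: float | None = None,
           formula: str = "standard") -> float:
    """Variance in exposure explained by one instrument.

    ``standard`` computes 2·MAF·(1-MAF)·β² for a standardized trait.
    ``beta_over_se`` computes 2·MAF·(1-MAF)·β²/se² — an alternative
    reading of the same quantity found in some applied reports; it is
    exposed so the choice is explicit rather than silent.
    """
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        raise ValueError("eaf missing; per-SNP R² unavailable")
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf={eaf} outside (0,1)")
    maf = min(eaf, 1.0 - eaf)
    base = 2.0 * maf * (1.0 - maf) * beta * beta
    if formula == "standard":
        return base
    if formula == "beta_over_se":
        if se is None or se <= 0:
            raise ValueError("beta_over_se formula requires se > 0")
        return base / (se * se)
    raise ValueError(f"unknown R² formula {formula!r}")


def f_statistic(n: int, k: int, r2_total: float) -> float:
    """Trait-level instrument-strength F = ((N-k-1)/k)·(R²/(1-R²))."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"r2_total={r2_total} outside [0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} instruments")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def filter_weak(iv: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Exclude the whole instrument set when F < f_min (strict: F==f_min kept)."""
    if np.isnan(iv.f_stat) or iv.f_stat >= f_min:
        return iv
    empty = TraitTable(iv.trait_id, iv.table.trait_type,
                       iv.table.df.iloc[0:0].copy(), dict(iv.table.rejections))
    return InstrumentSet(iv.trait_id, empty, {}, iv.r2_total, iv.f_stat,
                         exclusion_reason="weak_instruments")


def build_instrument_set(table: TraitTable, ld: LDInfo, *,
                         p_threshold: float = 1e-5, clump_r2: float = 0.001,
                         clump_kb: int = 10_000, f_min: float = 10.0,
                         r2_formula: str = "standard") -> InstrumentSet:
    """Full selection pipeline: p-threshold → clump → F filter.

    SNPs with missing EAF contribute 0 to the summed R² (their variance
    explained cannot be evaluated). Sample size N for the F-statistic is
    the median per-SNP N; if absent, the F filter cannot run and the set
    is retained with f_stat = NaN.
    """
    sel = select_by_pvalue(table, p_threshold)
    if sel.n_snps == 0:
        return InstrumentSet(table.trait_id, sel,
                             exclusion_reason="no_instruments")
    clumped = ld_clump(sel, ld, clump_r2, clump_kb)
    r2_map: dict[str, float] = {}
    for _, row in clumped.df.iterrows():
        if pd.isna(row["eaf"]):
            r2_map[row["snp"]] = 0.0
        else:
            r2_map[row["snp"]] = snp_r2(row["eaf"], row["beta"], row["se"],
                                        formula=r2_formula)
    r2_total = min(float(sum(r2_map.values())), 1.0 - 1e-12)
    n_vals = clumped.df["n"].dropna()
    f = float("nan")
    if len(n_vals):
        n = int(np.median(n_vals))
        if n > clumped.n_snps + 1:
            f = f_statistic(n, clumped.n_snps, r2_total)
    iv = InstrumentSet(table.trait_id, clumped, r2_map, r2_total, f)
    return filter_weak(iv, f_min)
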