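"""Reading, validation and writing of GWAS summary statistics and LD tables.

Everything downstream of this module works on :class:`TraitTable` (one
trait's per-SNP associations held in a pandas DataFrame with canonical
columns) and :class:`LDInfo` (sparse pairwise r-squared between SNPs).

Three input dialects are supported:

``generic``
    Tab-separated with header ``SNP CHR POS EA OA EAF BETA SE P N``;
    ``.`` or an empty field means missing.
``gwas_catalog``
    The GWAS Catalog harmonised-sumstats header
    (``variant_id``, ``chromosome``, ``base_pair_location``, ...).
``finngen``
    FinnGen release files (``rsids``, ``#chrom``, ``pos``, ``alt``,
    ``ref``, ...) with ``alt`` taken as the effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order used throughout the package
COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

#: smallest representable p-value; inputs printing p=0 are clamped here
P_FLOOR = 1e-300

_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "SNP": "snp", "CHR": "chrom", "POS": "pos", "EA": "ea", "OA": "oa",
        "EAF": "eaf", "BETA": "beta", "SE": "se", "P": "p", "N": "n",
    },
    "gwas_catalog": {
        "variant_id": "snp", "chromosome": "chrom",
        "base_pair_location": "pos", "effect_allele": "ea",
        "other_allele": "oa", "effect_allele_frequency": "eaf",
        "beta": "beta", "standard_error": "se", "p_value": "p", "n": "n",
    },
    "finngen": {
        "rsids": "snp", "#chrom": "chrom", "pos": "pos", "alt": "ea",
        "ref": "oa", "af_alt": "eaf", "beta": "beta", "sebeta": "se",
        "pval": "p", "n": "n",
    },
}

# eaf and n may be absent from real files; everything else is mandatory
_OPTIONAL = {"eaf", "n"}


class SumstatsFormatError(ValueError):
    """A file does not conform to the declared dialect."""


class EmptyInputError(ValueError):
    """No valid records survived validation."""


@dataclass
class TraitTable:
    """Per-SNP summary statistics for one trait.

    Parameters
    ----------
    trait_id
        Identifier for the trait (a GWAS accession or a simulation label).
    trait_type
        One of ``exposure``, ``mediator``, ``outcome``.
    df
        DataFrame with the canonical :data:`COLUMNS`.
    rejections
        Count of dropped input rows keyed by reason.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise ValueError("trait_id must be non-empty")
        if self.trait_type not in {"exposure", "mediator", "outcome"}:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")


@dataclass
class LDInfo:
    """Sparse symmetric map of pairwise LD r-squared.

    Pairs are stored once under a sorted key; an absent pair is read as
    r²=0 (pairwise LD files only report values above a floor). The
    self-pair r²=1 is implied, never stored.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return
        if not 0.0 <= r2 <= 1.0:
            raise SumstatsFormatError(f"r2({a},{b})={r2} outside [0,1]")
        self.pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)


def _validate(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply record-level invariants, returning kept rows and drop counts."""
    rejections: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        k = int(mask.sum())
        if k:
            rejections[reason] = rejections.get(reason, 0) + k
            logger.warning("%s: dropped %d rows (%s)", trait_id, k, reason)
        return df[~mask]

    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    df = drop(df["snp"].isna() | (df["snp"].astype(str) == ""), "missing_snp_id")
    df = drop(df["beta"].isna() | df["se"].isna() | df["p"].isna(), "missing_stats")
    df = drop(~(df["se"] > 0), "nonpositive_se")
    df = drop(df["ea"] == df["oa"], "identical_alleles")
    df = drop((df["p"] < 0) | (df["p"] > 1), "pvalue_out_of_range")
    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    df = drop(bad_eaf, "eaf_out_of_range")

    n_zero = int((df["p"] == 0).sum())
    if n_zero:
        logger.warning("%s: clamped %d zero p-values to %g", trait_id, n_zero, P_FLOOR)
        df.loc[df["p"] == 0, "p"] = P_FLOOR

    # duplicate rsIDs: keep the most significant record, mirroring the
    # "best instrument" convention of clumping
    dup = df.duplicated("snp", keep=False)
    if dup.any():
        rejections["duplicate_snp_id"] = int(dup.sum()) - df.loc[dup, "snp"].nunique()
        logger.warning("%s: %d duplicate snp_id collisions resolved by min p",
                       trait_id, rejections["duplicate_snp_id"])
        df = df.sort_values(["p", "snp"], kind="mergesort").drop_duplicates("snp")
        df = df.sort_index()

    return df.reset_index(drop=True), rejections


def read_sumstats(path: str | Path, dialect: str = "generic", *,
                  trait_id: str, trait_type: str = "exposure",
                  sep: str | None = None) -> TraitTable:
    """Load one trait's summary statistics from a delimited text file.

    Invalid rows (non-positive SE, identical alleles, missing core
    statistics, out-of-range p or EAF) are dropped and counted in
    ``TraitTable.rejections``; duplicate rsIDs keep the smallest p.

    Raises
    ------
    SumstatsFormatError
        if a mandatory column for the dialect is absent.
    EmptyInputError
        if no valid rows remain.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    raw = pd.read_csv(path, sep=sep or "\t", dtype=str,
                      na_values=[".", "", "NA", "nan"], keep_default_na=False)
    missing = [c for c in mapping
               if c not in raw.columns and mapping[c] not in _OPTIONAL]
    if missing:
        raise SumstatsFormatError(
            f"{path}: dialect {dialect!r} requires column(s) {missing}")
    df = raw.rename(columns=mapping)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[COLUMNS]
    for col in ("eaf", "beta", "se", "p"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")
    df["chrom"] = df["chrom"].astype(str)

    df, rejections = _validate(df, trait_id)
    if df.empty:
        raise EmptyInputError(f"{path}: zero valid rows after validation "
                              f"(rejections: {rejections})")
    return TraitTable(trait_id=trait_id, trait_type=trait_type, df=df,
                      rejections=rejections)


def write_sumstats(table: TraitTable, path: str | Path) -> Path:
    """Write a TraitTable in the generic TSV dialect (round-trips to 10 s.f.)."""
    path = Path(path)
    out = table.df.copy()
    out.columns = [c for c in _DIALECTS["generic"]]
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep=".")
    return path


def write_results(estimates: Iterable, path: str | Path) -> Path:
    """Write causal-effect estimates as a TSV forest-plot table.

    Columns: method, exposure, outcome, nsnp, beta, se, or_, ci_low,
    ci_high, pvalue. Numeric fields round-trip at 10 significant digits.
    """
    path = Path(path)
    rows = []
    for est in estimates:
        rows.append({
            "method": est.method, "exposure": est.exposure_id,
            "outcome": est.outcome_id, "nsnp": est.nsnp, "beta": est.beta,
            "se": est.se, "or_": est.or_, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "pvalue": est.pvalue,
        })
    cols = ["method", "exposure", "outcome", "nsnp", "beta", "se", "or_",
            "ci_low", "ci_high", "pvalue"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.10g")
    return path


def read_ld(path: str | Path, dialect: str = "pairwise") -> LDInfo:
    """Load LD information from a square matrix or a pairwise listing.

    ``square_matrix``: TSV whose first column and header carry identical,
    identically ordered SNP labels; asymmetry beyond 1e-6 is a format
    error and the diagonal is ignored. ``pairwise``: whitespace-separated
    ``SNP_A SNP_B R2`` lines (header optional).
    """
    ld = LDInfo()
    if dialect == "square_matrix":
        mat = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(x) for x in mat.index]
        if labels != [str(c) for c in mat.columns]:
            raise SumstatsFormatError(f"{path}: row/column labels differ")
        vals = mat.to_numpy(dtype=float)
        if np.nanmax(np.abs(vals - vals.T)) > 1e-6:
            raise SumstatsFormatError(f"{path}: matrix asymmetric beyond 1e-6")
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                r2 = vals[i, j]
                if r2 > 0:
                    ld.set_r2(a, labels[j], r2)
    elif dialect == "pairwise":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].upper() in {"SNP_A", "#"}:
                    continue
                if len(parts) < 3:
                    raise SumstatsFormatError(f"{path}: malformed line {line!r}")
                ld.set_r2(parts[0], parts[1], float(parts[2]))
    else:
        raise ValueError(f"unknown LD dialect {dialect!r}")
    return ld


def write_ld(ld: LDInfo, path: str | Path) -> Path:
    """Write LDInfo in the pairwise format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("SNP_A SNP_B R2\n")
        for (a, b), r2 in sorted(ld.pairs.items()):
            fh.write(f"{a} {b} {r2:.10g}\n")
    return path
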