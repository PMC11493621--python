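"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs every instrument's effect on exposure and outcome
expressed relative to the same effect allele. This module matches SNPs by
rsID, resolves allele swaps and strand flips, applies the usual
allele-frequency rule to palindromic (A/T, C/G) variants, and emits the
per-SNP (bx, se_x, by, se_y) quadruples every estimator consumes.

The harmonization rules here are package assumptions following standard
two-sample MR practice: sign-flip on swapped alleles, strand-complement
matching for single-base alleles only, and palindromic SNPs kept only
when both allele frequencies are well away from 0.5 and concordant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import TraitTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class EmptyHarmonizationError(ValueError):
    """No SNP survived harmonization; carries per-reason drop counts."""

    def __init__(self, exposure_id: str, outcome_id: str, drops: dict[str, int]):
        self.drops = drops
        super().__init__(
            f"no SNPs survived harmonization of {exposure_id} vs {outcome_id}; "
            f"drops by reason: {drops}")


@dataclass
class HarmonizedSet:
    """Allele-aligned instrument effects for one exposure–outcome pair.

    ``df`` columns: snp, bx, se_x, by, se_y, eaf_x (NaN when missing).
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    drops: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.df
        return (d["bx"].to_numpy(float), d["se_x"].to_numpy(float),
                d["by"].to_numpy(float), d["se_y"].to_numpy(float))

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.df[mask].reset_index(drop=True), dict(self.drops))


def from_arrays(bx, se_x, by, se_y, *, exposure_id: str = "X",
                outcome_id: str = "Y", snp_ids=None, eaf_x=None) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (tests, simulations)."""
    bx = np.asarray(bx, float)
    k = bx.size
    df = pd.DataFrame({
        "snp": snp_ids if snp_ids is not None else [f"snp{i}" for i in range(k)],
        "bx": bx, "se_x": np.asarray(se_x, float),
        "by": np.asarray(by, float), "se_y": np.asarray(se_y, float),
        "eaf_x": np.asarray(eaf_x, float) if eaf_x is not None else np.nan,
    })
    if (df["se_x"] <= 0).any() or (df["se_y"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return HarmonizedSet(exposure_id, outcome_id, df)


def _complement(allele: str) -> str | None:
    if len(allele) != 1:
        return None  # complementing multi-base alleles is ill-defined
    return _COMPLEMENT.get(allele)


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and _COMPLEMENT.get(ea) == oa


def harmonize(exposure: TraitTable, outcome: TraitTable,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Matching is by snp_id. Outcome records whose alleles are the exact
    swap of the exposure's have their beta sign flipped and EAF
    complemented; strand-complement matches (single-base alleles only)
    are resolved likewise. Palindromic SNPs are retained only when both
    EAFs lie outside ``[0.5 - w, 0.5 + w]``; their orientation is then
    inferred from minor-allele concordance. Everything else is dropped
    and counted by reason.

    Raises
    ------
    EmptyHarmonizationError
        when no SNP survives, carrying the drop counts.
    """
    w = palindrome_eaf_window
    drops: dict[str, int] = {}

    def bump(reason: str) -> None:
        drops[reason] = drops.get(reason, 0) + 1

    exp = exposure.df.set_index("snp")
    out = outcome.df.set_index("snp")
    rows = []
    for snp in exp.index:
        if snp not in out.index:
            bump("not_in_outcome")
            continue
        ex, oy = exp.loc[snp], out.loc[snp]
        ea_x, oa_x = str(ex["ea"]).upper(), str(ex["oa"]).upper()
        ea_y, oa_y = str(oy["ea"]).upper(), str(oy["oa"]).upper()
        flip: bool | None = None

        if _is_palindromic(ea_x, oa_x):
            eaf_x, eaf_y = ex["eaf"], oy["eaf"]
            ambiguous = (
                pd.isna(eaf_x) or pd.isna(eaf_y)
                or abs(eaf_x - 0.5) <= w or abs(eaf_y - 0.5) <= w
            )
            alleles_match = {ea_x, oa_x} == {ea_y, oa_y}
            if not alleles_match:
                bump("allele_mismatch")
                continue
            if ambiguous:
                bump("palindromic_ambiguous")
                continue
            # infer orientation from which side of 0.5 each frequency of
            # the (nominally identical) effect allele falls on
            eaf_y_aligned = eaf_y if ea_y == ea_x else 1.0 - eaf_y
            flip = (eaf_x < 0.5) != (eaf_y_aligned < 0.5)
        else:
            if ea_y == ea_x and oa_y == oa_x:
                flip = False
            elif ea_y == oa_x and oa_y == ea_x:
                flip = True
            else:
                cea, coa = _complement(ea_y or ""), _complement(oa_y or "")
                if cea == ea_x and coa == oa_x:
                    flip = False
                elif cea == oa_x and coa == ea_x:
                    flip = True
                else:
                    bump("allele_mismatch")
                    continue

        by = -oy["beta"] if flip else oy["beta"]
        if not (ex["se"] > 0 and oy["se"] > 0):
            bump("nonpositive_se")
            continue
        rows.append({"snp": snp, "bx": ex["beta"], "se_x": ex["se"],
                     "by": by, "se_y": oy["se"], "eaf_x": ex["eaf"]})

    if not rows:
        raise EmptyHarmonizationError(exposure.trait_id, outcome.trait_id, drops)
    df = pd.DataFrame(rows)
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, df, drops)
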