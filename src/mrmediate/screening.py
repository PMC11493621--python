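"""Batch bidirectional MR screening across many exposure traits.

Implements the four-stage screen used to sift hundreds of candidate
exposures against one outcome:

1. forward MR of every exposure on the outcome, tiered on the primary
   (IVW) p-value: < 0.01 "significant", < 0.05 "suggestive", else
   rejected;
2. reverse MR (outcome instrumented as an exposure) — a trait is
   "reverse clear" when the reverse IVW p exceeds 0.05;
3. Bayesian re-validation of significant traits: bwmr p < 0.05
   confirms, otherwise the trait is demoted ("bayes_unconfirmed");
4. results carried forward to mediation.

Thresholds are raw p-values by design (the screening convention this
mirrors applies no multiplicity correction); a Benjamini–Hochberg
q-value column is emitted for information only and never filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .diagnostics import DiagnosticsReport, sensitivity_report
from .estimators import MREstimate, run_all
from .harmonize import EmptyHarmonizationError, HarmonizedSet, harmonize
from .instruments import build_instrument_set
from .sumstats import LDInfo, TraitTable

logger = logging.getLogger(__name__)

TIERS = ("rejected", "suggestive", "significant")


@dataclass
class ScreenRecord:
    exposure_id: str
    outcome_id: str
    direction: str = "forward"
    estimates: list[MREstimate] = field(default_factory=list)
    diagnostics: DiagnosticsReport | None = None
    tier: str = "rejected"
    reverse_clear: bool | None = None
    reverse_p: float | None = None
    bayes_confirmed: bool | None = None
    bh_q: float | None = None
    n_instruments: int = 0
    f_stat: float | None = None
    failure_reason: str | None = None
    method_failures: list[tuple[str, str]] = field(default_factory=list)
    harmonized: HarmonizedSet | None = None

    @property
    def primary(self) -> MREstimate | None:
        """The tiering estimate: IVW, or the Wald ratio when k=1."""
        for method in ("ivw", "wald_ratio"):
            for est in self.estimates:
                if est.method == method:
                    return est
        return None

    def estimate(self, method: str) -> MREstimate | None:
        for est in self.estimates:
            if est.method == method:
                return est
        return None


def _tier(p: float, config: RunConfig) -> str:
    if p < config.tier_significant:
        return "significant"
    if p < config.tier_suggestive:
        return "suggestive"
    return "rejected"


def _analyze_pair(exposure: TraitTable, outcome: TraitTable, ld: LDInfo,
                  config: RunConfig, seed: int) -> ScreenRecord:
    rec = ScreenRecord(exposure_id=exposure.trait_id,
                       outcome_id=outcome.trait_id)
    iv = build_instrument_set(
        exposure, ld, p_threshold=config.p_instrument,
        clump_r2=config.clump_r2, clump_kb=config.clump_kb,
        f_min=config.f_min)
    rec.f_stat = None if np.isnan(iv.f_stat) else iv.f_stat
    if iv.exclusion_reason or iv.k == 0:
        rec.failure_reason = iv.exclusion_reason or "no_instruments"
        return rec
    try:
        h = harmonize(iv.table, outcome, config.palindrome_eaf_window)
    except EmptyHarmonizationError as exc:
        rec.failure_reason = f"empty_harmonization:{exc.drops}"
        return rec
    rec.harmonized = h
    rec.n_instruments = h.k
    rec.estimates = run_all(h, seed=seed, n_boot=config.n_boot,
                            failures=rec.method_failures)
    if h.k >= 2:
        rec.diagnostics = sensitivity_report(h)
    primary = rec.primary
    if primary is not None:
        rec.tier = _tier(primary.pvalue, config)
    else:
        rec.failure_reason = "primary_estimate_failed"
    return rec


def forward_screen(exposures: list[TraitTable], outcome: TraitTable,
                   ld: LDInfo, config: RunConfig | None = None,
                   seed: int | None = None) -> list[ScreenRecord]:
    """Forward MR of every exposure on the outcome; one record each.

    Per-exposure failures (no instruments, weak F, empty harmonization)
    are recorded with a reason and never abort the batch.
    """
    if not exposures:
        raise ValueError("empty exposure collection")
    config = config or RunConfig()
    seed = config.seeds.get("estimators", 0) if seed is None else seed
    records = [_analyze_pair(exp, outcome, ld, config, seed)
               for exp in exposures]
    # information-only BH q-values over the primary p-values
    pvals = [(i, r.primary.pvalue) for i, r in enumerate(records)
             if r.primary is not None]
    if pvals:
        idx, p = zip(*pvals)
        q = _benjamini_hochberg(np.asarray(p))
        for i, qv in zip(idx, q):
            records[i].bh_q = float(qv)
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def reverse_screen(outcome_as_exposure: TraitTable,
                   exposures: dict[str, TraitTable],
                   records: list[ScreenRecord], ld: LDInfo,
                   config: RunConfig | None = None,
                   seed: int | None = None) -> list[ScreenRecord]:
    """Reverse-causality check for tiered records (suggestive or better).

    The outcome trait is instrumented with the same selection rules and
    tested against each tiered exposure; ``reverse_clear`` is True when
    the reverse IVW p exceeds ``config.reverse_clear_p``. An exposure
    that cannot be tested (no reverse instruments) is conservatively
    marked not clear with the reason recorded.
    """
    config = config or RunConfig()
    seed = config.seeds.get("estimators", 0) if seed is None else seed
    for rec in records:
        if rec.tier == "rejected":
            continue
        target = exposures.get(rec.exposure_id)
        if target is None:
            rec.reverse_clear = False
            rec.failure_reason = "reverse_exposure_table_missing"
            continue
        rev = _analyze_pair(outcome_as_exposure, target, ld, config, seed)
        rev.direction = "reverse"
        primary = rev.primary
        if primary is None:
            rec.reverse_clear = False
            rec.failure_reason = f"reverse_failed:{rev.failure_reason}"
        else:
            rec.reverse_p = primary.pvalue
            rec.reverse_clear = bool(primary.pvalue > config.reverse_clear_p)
    return records


def bayes_validate(records: list[ScreenRecord],
                   config: RunConfig | None = None) -> list[ScreenRecord]:
    """Bayesian confirmation gate for significant records.

    ``bayes_confirmed`` is True when the bwmr p-value is strictly below
    ``config.bayes_confirm_p`` (a boundary p exactly at the threshold is
    demoted). Unconfirmed records are demoted to suggestive with reason
    ``bayes_unconfirmed``; a missing/failed bwmr fit demotes likewise.
    """
    config = config or RunConfig()
    for rec in records:
        if rec.tier != "significant":
            continue
        est = rec.estimate("bwmr")
        if est is None:
            rec.bayes_confirmed = False
            rec.failure_reason = "bwmr_unavailable"
        else:
            rec.bayes_confirmed = bool(est.pvalue < config.bayes_confirm_p)
        if not rec.bayes_confirmed:
            rec.tier = "suggestive"
            if rec.failure_reason is None:
                rec.failure_reason = "bayes_unconfirmed"
    return records


def screen_table(records: list[ScreenRecord]) -> pd.DataFrame:
    """Flatten screen records into the per-trait report table."""
    rows = []
    for r in records:
        primary = r.primary
        d = r.diagnostics
        rows.append({
            "exposure": r.exposure_id, "outcome": r.outcome_id,
            "nsnp": r.n_instruments, "f_stat": r.f_stat,
            "beta": primary.beta if primary else np.nan,
            "se": primary.se if primary else np.nan,
            "pvalue": primary.pvalue if primary else np.nan,
            "or_": primary.or_ if primary else np.nan,
            "ci_low": primary.ci_low if primary else np.nan,
            "ci_high": primary.ci_high if primary else np.nan,
            "tier": r.tier, "bh_q": r.bh_q,
            "reverse_p": r.reverse_p, "reverse_clear": r.reverse_clear,
            "bayes_confirmed": r.bayes_confirmed,
            "q_p": d.q_p if d else np.nan,
            "egger_intercept_p": d.egger_intercept_p if d else np.nan,
            "heterogeneity_clear": d.heterogeneity_clear if d else None,
            "pleiotropy_clear": d.pleiotropy_clear if d else None,
            "failure_reason": r.failure_reason,
        })
    return pd.DataFrame(rows)


def write_screen_table(records: list[ScreenRecord], path: str | Path) -> Path:
    path = Path(path)
    screen_table(records).to_csv(path, sep="\t", index=False,
                                 float_format="%.10g")
    return path
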