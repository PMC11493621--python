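"""Two-step mediation decomposition on the MR effect scale.

With β_total the exposure→outcome effect, β1 the exposure→mediator
effect and β2 the mediator→outcome effect (each from univariable
two-sample MR), the product-of-coefficients decomposition is

    indirect (mediated) effect = β1·β2
    direct effect              = β_total − β1·β2
    proportion mediated        = 100·β1·β2 / β_total  (percent)

The proportion is reported only when the indirect and total effects
share sign; a sign-discordant decomposition gets a null proportion
(printed "/") and the qualitative note that the mediated path runs
opposite to the overall trend. An indirect effect larger in magnitude
than the total is flagged ">100%".

The delta-method standard error sqrt(β2²·se1² + β1²·se2²) for the
indirect effect is an extension beyond the basic decomposition and is
labelled as such in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .estimators import run_all
from .harmonize import EmptyHarmonizationError, harmonize
from .instruments import build_instrument_set
from .screening import ScreenRecord, _analyze_pair
from .sumstats import LDInfo, TraitTable


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    total_beta: float
    beta1: float
    beta2: float
    mediation_beta: float
    direct_beta: float
    proportion_pct: float | None
    note: str | None = None
    mediation_se: float | None = None

    def proportion_str(self) -> str:
        if self.proportion_pct is None:
            return "/"
        return f"{self.proportion_pct:.2f}%"


def decompose(total_beta: float, beta1: float, beta2: float, *,
              exposure_id: str = "exposure", mediator_id: str = "mediator",
              outcome_id: str = "outcome") -> MediationResult:
    """Product-of-coefficients decomposition with the sign-consistency rule.

    ``direct + mediation == total`` holds bit-exactly. The proportion is
    null when the total effect is zero, the mediated effect is zero, or
    the two disagree in sign; when |mediation| > |total| the proportion
    is still reported but flagged ">100%".
    """
    for name, v in (("total_beta", total_beta), ("beta1", beta1),
                    ("beta2", beta2)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    mediation_beta = beta1 * beta2
    direct_beta = total_beta - mediation_beta
    proportion: float | None
    note = None
    if mediation_beta == 0.0:
        proportion, note = None, "null_mediation"
    elif total_beta == 0.0:
        proportion, note = None, "total_effect_zero"
    elif (mediation_beta > 0) != (total_beta > 0):
        proportion, note = None, "opposite_to_overall_trend"
    else:
        proportion = 100.0 * mediation_beta / total_beta
        if proportion > 100.0:
            note = ">100%"
    return MediationResult(exposure_id, mediator_id, outcome_id,
                           total_beta, beta1, beta2, mediation_beta,
                           direct_beta, proportion, note)


def mediation_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Delta-method SE of the product β1·β2 (symmetric in its two legs)."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(beta2 * beta2 * se1 * se1 + beta1 * beta1 * se2 * se2)


@dataclass
class MediationCandidate:
    """One exposure–mediator–outcome link surviving both leg screens."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    p1: float
    beta2: float
    se2: float
    p2: float
    bayes_p: float | None
    conditions: dict = field(default_factory=dict)
    result: MediationResult | None = None


def find_mediators(exposure_records: list[ScreenRecord],
                   exposures: dict[str, TraitTable],
                   mediator_panel: list[TraitTable],
                   outcome: TraitTable, ld: LDInfo,
                   config: RunConfig | None = None,
                   seed: int | None = None) -> list[MediationCandidate]:
    """Screen a mediator panel between passed exposures and the outcome.

    For each exposure that survived the full screen and each mediator:
    leg 1 estimates exposure→mediator (β1) with the exposure's
    instruments; when its p < tier_suggestive, leg 2 estimates
    mediator→outcome (β2) with the mediator's own instruments, subject
    to Bayesian confirmation (bwmr p < bayes_confirm_p) as for the main
    screen. Surviving links are decomposed against the exposure's total
    effect. The three mediation conditions (exposure→mediator causal,
    mediator→outcome causal, exposure→outcome causal without reverse
    causality) are recorded per candidate.
    """
    config = config or RunConfig()
    seed = config.seeds.get("estimators", 0) if seed is None else seed
    out: list[MediationCandidate] = []
    mediator_records: dict[str, ScreenRecord] = {}

    for rec in exposure_records:
        if rec.tier == "rejected" or rec.primary is None:
            continue
        exp_table = exposures.get(rec.exposure_id)
        if exp_table is None:
            continue
        iv = build_instrument_set(
            exp_table, ld, p_threshold=config.p_instrument,
            clump_r2=config.clump_r2, clump_kb=config.clump_kb,
            f_min=config.f_min)
        if iv.exclusion_reason or iv.k == 0:
            continue
        for mediator in mediator_panel:
            try:
                h1 = harmonize(iv.table, mediator,
                               config.palindrome_eaf_window)
            except EmptyHarmonizationError:
                continue
            ests = run_all(h1, seed=seed, n_boot=config.n_boot)
            leg1 = next((e for e in ests if e.method in ("ivw", "wald_ratio")),
                        None)
            if leg1 is None or leg1.pvalue >= config.tier_suggestive:
                continue
            # leg 2: mediator on outcome with the mediator's own instruments
            mrec = mediator_records.get(mediator.trait_id)
            if mrec is None:
                mrec = _analyze_pair(mediator, outcome, ld, config, seed)
                mediator_records[mediator.trait_id] = mrec
            leg2 = mrec.primary
            if leg2 is None or leg2.pvalue >= config.tier_suggestive:
                continue
            bwmr_est = mrec.estimate("bwmr")
            bayes_p = bwmr_est.pvalue if bwmr_est else None
            bayes_ok = bayes_p is not None and bayes_p < config.bayes_confirm_p
            cand = MediationCandidate(
                exposure_id=rec.exposure_id, mediator_id=mediator.trait_id,
                outcome_id=outcome.trait_id,
                beta1=leg1.beta, se1=leg1.se, p1=leg1.pvalue,
                beta2=leg2.beta, se2=leg2.se, p2=leg2.pvalue,
                bayes_p=bayes_p,
                conditions={
                    "exposure_to_mediator": True,
                    "mediator_to_outcome": True,
                    "exposure_to_outcome_no_reverse":
                        rec.tier != "rejected"
                        and (rec.reverse_clear is not False),
                    "bayes_confirmed": bayes_ok,
                })
            if bayes_ok:
                res = decompose(rec.primary.beta, leg1.beta, leg2.beta,
                                exposure_id=rec.exposure_id,
                                mediator_id=mediator.trait_id,
                                outcome_id=outcome.trait_id)
                res.mediation_se = mediation_se(leg1.beta, leg1.se,
                                                leg2.beta, leg2.se)
                cand.result = res
            out.append(cand)
    return out


def mediation_table(candidates: list[MediationCandidate]) -> pd.DataFrame:
    """Flatten candidates into the mediation report (total, indirect,
    proportion — '/' when sign-discordant)."""
    rows = []
    for c in candidates:
        r = c.result
        rows.append({
            "exposure": c.exposure_id, "mediator": c.mediator_id,
            "outcome": c.outcome_id,
            "beta1": c.beta1, "p1": c.p1, "beta2": c.beta2, "p2": c.p2,
            "bayes_p": c.bayes_p,
            "total_beta": r.total_beta if r else None,
            "mediation_beta": r.mediation_beta if r else None,
            "direct_beta": r.direct_beta if r else None,
            "mediation_se": r.mediation_se if r else None,
            "proportion": r.proportion_str() if r else None,
            "note": r.note if r else "bayes_unconfirmed",
        })
    return pd.DataFrame(rows)


def write_mediation_table(candidates: list[MediationCandidate],
                          path: str | Path) -> Path:
    path = Path(path)
    mediation_table(candidates).to_csv(path, sep="\t", index=False,
                                       float_format="%.10g")
    return path
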