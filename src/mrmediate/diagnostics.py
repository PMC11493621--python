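"""Sensitivity diagnostics reported alongside every MR fit.

Covers Cochran's Q heterogeneity (at the IVW and Egger fits), the
MR-Egger intercept test for directional horizontal pleiotropy,
leave-one-out influence analysis, and single-SNP Wald ratios — the
standard battery that accompanies a two-sample MR report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import (InsufficientInstrumentsError, MREstimate, egger,
                         ivw, wald_ratio)
from .harmonize import HarmonizedSet


@dataclass
class DiagnosticsReport:
    q_ivw: float
    q_df: int
    q_p: float
    q_egger: float | None = None
    q_egger_df: int | None = None
    q_egger_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    loo: list[tuple[str, MREstimate]] = field(default_factory=list)
    single_snp: list[tuple[str, MREstimate]] = field(default_factory=list)
    influential_snps: list[str] = field(default_factory=list)

    @property
    def heterogeneity_clear(self) -> bool:
        """True when Q does not reject at 0.05 (booleans, never filters)."""
        return self.q_p > 0.05

    @property
    def pleiotropy_clear(self) -> bool:
        return self.egger_intercept_p is None or self.egger_intercept_p > 0.05

    def to_dict(self) -> dict:
        return {
            "q_ivw": self.q_ivw, "q_df": self.q_df, "q_p": self.q_p,
            "q_egger": self.q_egger, "q_egger_df": self.q_egger_df,
            "q_egger_p": self.q_egger_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "heterogeneity_clear": self.heterogeneity_clear,
            "pleiotropy_clear": self.pleiotropy_clear,
            "influential_snps": list(self.influential_snps),
        }


def cochran_q(h: HarmonizedSet, beta: float) -> tuple[float, int, float]:
    """Cochran's Q at a given pooled beta: Σ wj(βj − beta)², df = k−1.

    βj = by/bx are the per-SNP ratio estimates, wj = (bx/se_y)² their
    first-order inverse variances; p is the upper-tail chi-square.
    """
    if h.k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires k >= 2")
    bx, _, by, se_y = h.arrays()
    ok = bx != 0
    ratios = by[ok] / bx[ok]
    w = (bx[ok] / se_y[ok]) ** 2
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = h.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept, its SE and two-sided normal p (pleiotropy test)."""
    est = egger(h)
    return (est.extra["intercept"], est.extra["intercept_se"],
            est.extra["intercept_p"])


def leave_one_out(h: HarmonizedSet) -> tuple[list[tuple[str, MREstimate]],
                                             list[str]]:
    """IVW re-estimated with each SNP left out in turn.

    Flags as influential any SNP whose omission flips the sign of the
    pooled beta or moves it by more than one reported SE of the refit.
    (The refit's own SE is the yardstick: a gross outlier inflates the
    full-set random-effects SE and would otherwise mask itself.)
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires k >= 3")
    full = ivw(h)
    out: list[tuple[str, MREstimate]] = []
    flagged: list[str] = []
    for j in range(h.k):
        mask = np.ones(h.k, bool)
        mask[j] = False
        sub = h.subset(mask)
        est = ivw(sub)
        snp = str(h.df["snp"].iloc[j])
        out.append((snp, est))
        sign_flip = np.sign(est.beta) != np.sign(full.beta) and full.beta != 0
        if sign_flip or abs(est.beta - full.beta) > est.se:
            flagged.append(snp)
    return out, flagged


def single_snp(h: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """Per-SNP Wald ratios (the data behind single-SNP forest plots)."""
    out = []
    for j in range(h.k):
        mask = np.zeros(h.k, bool)
        mask[j] = True
        out.append((str(h.df["snp"].iloc[j]), wald_ratio(h.subset(mask))))
    return out


def sensitivity_report(h: HarmonizedSet) -> DiagnosticsReport:
    """Full diagnostics battery for one harmonized set (needs k >= 2)."""
    beta_ivw = ivw(h, model="fixed").beta
    q, df, p = cochran_q(h, beta_ivw)
    rep = DiagnosticsReport(q_ivw=q, q_df=df, q_p=p)
    if h.k >= 3:
        est = egger(h)
        rep.q_egger = est.extra["q"]
        rep.q_egger_df = h.k - 2
        rep.q_egger_p = float(stats.chi2.sf(rep.q_egger, rep.q_egger_df))
        rep.egger_intercept = est.extra["intercept"]
        rep.egger_intercept_se = est.extra["intercept_se"]
        rep.egger_intercept_p = est.extra["intercept_p"]
        rep.loo, rep.influential_snps = leave_one_out(h)
        rep.single_snp = single_snp(h)
    return rep
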