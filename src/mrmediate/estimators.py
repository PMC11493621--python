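"""Causal-effect estimators for two-sample summary-data MR.

Five complementary estimators operate on a :class:`~mrmediate.harmonize.
HarmonizedSet` of per-SNP instrument effects (bx, se_x, by, se_y):

``ivw``
    Inverse-variance-weighted meta-analysis of Wald ratios, equivalently
    the zero-intercept weighted regression of by on bx with weights
    1/se_y². Default is multiplicative random effects: the fixed-effect
    SE is inflated by max(1, sqrt(Q/(k-1))) so heterogeneity never
    deflates uncertainty.
``egger``
    Weighted regression of by on bx with an intercept; the intercept
    estimates directional horizontal pleiotropy (valid under InSIDE) and
    the slope is the pleiotropy-corrected causal effect.
``weighted_median``
    Weighted median of per-SNP ratio estimates; consistent when at least
    half the weight comes from valid instruments. SE by parametric
    bootstrap.
``weighted_mode``
    Mode of a weighted kernel density over ratio estimates; consistent
    when the largest group of instruments sharing a causal estimate is
    valid. SE by parametric bootstrap.
``bwmr``
    Bayesian weighted MR: a Gaussian measurement model with a N(0, 10²)
    prior on the causal effect, an overdispersion component τ², and
    per-SNP inlier/outlier responsibility weights that down-weight gross
    outliers. Posterior mean/SD reported; see docs/methods.md.

All effects are on the scale of the input betas (log-odds for binary
outcomes); odds ratios and 95% CIs are derived fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet

#: 95% normal quantile, fixed for bit-stable confidence intervals
Z95 = 1.959963985

_P_FLOOR = 1e-300


class DegenerateInstrumentError(ValueError):
    pass


class InsufficientInstrumentsError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_beta: float):
        super().__init__(message)
        self.last_beta = last_beta


def _normal_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(min(1.0, max(p, _P_FLOOR)))


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate for one exposure–outcome pair."""

    method: str
    beta: float
    se: float
    pvalue: float
    nsnp: int
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


def _make(method: str, h: HarmonizedSet, beta: float, se: float,
          pvalue: float | None = None, **extra) -> MREstimate:
    if se <= 0:
        raise ValueError(f"{method}: non-positive se {se}")
    p = _normal_p(beta, se) if pvalue is None else pvalue
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      pvalue=p, nsnp=h.k, exposure_id=h.exposure_id,
                      outcome_id=h.outcome_id, extra=extra)


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-SNP ratio estimate: beta = by/bx, se = |se_y/bx| (delta method)."""
    if h.k != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    bx, _, by, se_y = (a[0] for a in h.arrays())
    if bx == 0:
        raise DegenerateInstrumentError("instrument effect bx is zero")
    return _make("wald_ratio", h, by / bx, abs(se_y / bx))


def _ivw_core(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray
              ) -> tuple[float, float, float]:
    """Closed-form IVW: beta, fixed-effect se, Cochran's Q at that beta."""
    w = bx * bx / (se_y * se_y)
    sw = w.sum()
    if sw == 0:
        raise DegenerateInstrumentError("all instrument effects are zero")
    beta = float(np.sum(bx * by / (se_y * se_y)) / sw)
    se_fixed = float(np.sqrt(1.0 / sw))
    ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (delegates to Wald ratio at k=1)."""
    if h.k == 1:
        return wald_ratio(h)
    if model not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, se_y = h.arrays()
    beta, se, q = _ivw_core(bx, by, se_y)
    if model == "multiplicative_random" and h.k > 1:
        se *= max(1.0, float(np.sqrt(q / (h.k - 1))))
    return _make("ivw", h, beta, se, model=model, q=q)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Instrument effects are oriented so every bx ≥ 0 (joint sign flip)
    before the 1/se_y²-weighted fit; the SE uses multiplicative
    random-effects scaling bounded below by 1.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires k >= 3")
    bx, _, by, se_y = h.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / (se_y * se_y)
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=w).fit()
    q_egger = float(np.sum(w * res.resid ** 2))
    # res.bse carries scale = Q/(k-2); re-bound it below by 1 so
    # under-dispersion never shrinks the SE beneath fixed-effect
    adj = np.sqrt(max(1.0, res.scale) / res.scale)
    intercept, slope = float(res.params[0]), float(res.params[1])
    se_int = float(res.bse[0] * adj)
    se_slope = float(res.bse[1] * adj)
    return _make("egger", h, slope, se_slope,
                 intercept=intercept, intercept_se=se_int,
                 intercept_p=_normal_p(intercept, se_int), q=q_egger)


def _ratio_weights(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    ok = bx != 0
    ratios = by[ok] / bx[ok]
    weights = (bx[ok] / se_y[ok]) ** 2
    if ratios.size == 0:
        raise DegenerateInstrumentError("all instrument effects are zero")
    return ratios, weights


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Centered cumulative-weight interpolation at probability 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w)
    s = (cum - w / 2.0) / w.sum()
    return float(np.interp(0.5, s, r))


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9·min(sd, scaled MAD)·k^(-1/5)."""
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if spread == 0.0:
        spread = max(abs(float(np.median(ratios))), 1.0) * 1e-6
    return factor * 0.9 * spread * ratios.size ** (-1.0 / 5.0)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth_factor: float) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)

    def argmax_on(lo: float, hi: float) -> tuple[float, float]:
        grid = np.linspace(lo, hi, 512)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2
                      ) @ weights
        i = int(np.argmax(dens))
        return float(grid[i]), float(grid[1] - grid[0])

    lo, hi = float(ratios.min()) - 3 * h, float(ratios.max()) + 3 * h
    x, step = argmax_on(lo, hi)
    # zoom twice around the coarse peak so grid resolution never limits
    # the estimate on wide ratio ranges
    for _ in range(2):
        x, step = argmax_on(x - 2 * step, x + 2 * step)
    return x


def _bootstrap_se(h: HarmonizedSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample bx, by from their sampling distributions."""
    bx, se_x, by, se_y = h.arrays()
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, se_x)
        bys = rng.normal(by, se_y)
        ratios, weights = _ratio_weights(bxs, bys, se_y)
        est[b] = point_fn(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
                    ) -> MREstimate:
    """Weighted median of ratio estimates with bootstrap SE.

    Robust to up to 50% of the weight coming from invalid instruments.
    The p-value uses a normal approximation beta/se(boot).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("weighted median requires k >= 3")
    bx, _, by, se_y = h.arrays()
    ratios, weights = _ratio_weights(bx, by, se_y)
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(h, _weighted_median_point, n_boot, seed)
    return _make("weighted_median", h, beta, se, n_boot=n_boot, seed=seed)


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimate (kernel density argmax) with bootstrap SE."""
    if h.k < 3:
        raise InsufficientInstrumentsError("weighted mode requires k >= 3")
    bx, _, by, se_y = h.arrays()
    ratios, weights = _ratio_weights(bx, by, se_y)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)

    def point(r, w):
        return _weighted_mode_point(r, w, bandwidth_factor)

    se = _bootstrap_se(h, point, n_boot, seed)
    return _make("weighted_mode", h, beta, se,
                 bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed)


def bwmr(h: HarmonizedSet, prior_sd_theta: float = 10.0, max_iter: int = 500,
         tol: float = 1e-8, seed: int = 0, outlier_scale: float = 5.0,
         outlier_prior: float = 0.05) -> MREstimate:
    """Bayesian weighted MR with outlier down-weighting.

    Model: bx_j ~ N(γ_j, se_x²); by_j ~ N(θ·γ_j, se_y² + τ²);
    θ ~ N(0, prior_sd_theta²). An EM-style iteration alternates (i) the
    Gaussian posterior of each γ_j, (ii) the posterior mean/variance of
    θ, (iii) inlier responsibilities from a two-component (N(0,1) vs
    N(0, outlier_scale²)) model of standardized residuals, and (iv) a
    moment update of τ². Gross outliers receive responsibility ≈ 0 and
    stop influencing θ. Returns posterior mean/SD with a normal-
    approximation p-value.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("bwmr requires k >= 3")
    bx, se_x, by, se_y = h.arrays()
    theta, _, _ = _ivw_core(bx, by, se_y)
    tau2 = 0.0
    c2 = outlier_scale * outlier_scale
    # EM precision weight for the two-component scale mixture: an outlier
    # (responsibility 1-w) keeps 1/c² of its precision, so influence is
    # bounded rather than zeroed and the iteration cannot starve itself
    u = np.ones(h.k)
    w = np.ones(h.k)
    prior_prec = 1.0 / (prior_sd_theta * prior_sd_theta)
    theta_var = float("nan")
    for _ in range(max_iter):
        vy = se_y * se_y + tau2
        prec_g = 1.0 / (se_x * se_x) + u * theta * theta / vy
        m = (bx / (se_x * se_x) + u * theta * by / vy) / prec_g
        v = 1.0 / prec_g
        post_prec = float(np.sum(u * (m * m + v) / vy)) + prior_prec
        theta_new = float(np.sum(u * m * by / vy)) / post_prec
        theta_var = 1.0 / post_prec
        resid = by - theta_new * m
        s2 = vy + theta_new * theta_new * v
        z2 = resid * resid / s2
        li = (1.0 - outlier_prior) * np.exp(-0.5 * z2)
        lo = outlier_prior / outlier_scale * np.exp(-0.5 * z2 / c2)
        w = li / (li + lo)
        u = w + (1.0 - w) / c2
        tau2 = max(0.0, float(np.sum(u * (resid * resid - se_y * se_y
                                          - theta_new * theta_new * v))
                              / np.sum(u)))
        if abs(theta_new - theta) < tol:
            theta = theta_new
            break
        theta = theta_new
    else:
        raise ConvergenceError(
            f"bwmr did not converge in {max_iter} iterations", theta)
    se = float(np.sqrt(theta_var))
    return _make("bwmr", h, theta, se, tau2=tau2,
                 min_weight=float(w.min()), posterior_sd=se)


def run_all(h: HarmonizedSet, seed: int = 0, n_boot: int = 1000,
            failures: list | None = None) -> list[MREstimate]:
    """Run every estimator applicable at this instrument count.

    k=1 → Wald ratio only; k=2 → IVW only; k≥3 → all five methods.
    Per-method errors never abort the batch: they are appended to
    ``failures`` (if given) as (method, message) pairs.
    """
    if h.k < 1:
        raise InsufficientInstrumentsError("empty harmonized set")
    if h.k == 1:
        jobs: Sequence = [("wald_ratio", lambda: wald_ratio(h))]
    elif h.k == 2:
        jobs = [("ivw", lambda: ivw(h))]
    else:
        jobs = [
            ("ivw", lambda: ivw(h)),
            ("egger", lambda: egger(h)),
            ("weighted_median", lambda: weighted_median(h, n_boot, seed)),
            ("weighted_mode", lambda: weighted_mode(h, 1.0, n_boot, seed + 1)),
            ("bwmr", lambda: bwmr(h, seed=seed + 2)),
        ]
    out: list[MREstimate] = []
    for name, job in jobs:
        try:
            out.append(job())
        except Exception as exc:  # noqa: BLE001 — batch must survive any method
            if failures is not None:
                failures.append((name, str(exc)))
    return out
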