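"""Seeded Monte-Carlo calibration and recovery studies.

These are the package's standing numerical experiments: type-I error
calibration of the IVW test, the Egger slope test and Cochran's Q;
parameter recovery for all five estimators; robustness of the weighted
median under 40% invalid instruments; Egger intercept recovery under
directional pleiotropy; and end-to-end mediation-proportion recovery.

Experiment designs use large-cohort, strong-instrument configurations
so that finite-sample weak-instrument attenuation does not confound
what is being checked (estimator consistency and test calibration);
the generator's *defaults* instead emulate the data scale of a
microbiome→biobank screen. See docs/methods.md for the rationale and
parameter tables.
"""

from __future__ import annotations

import numpy as np

from .estimators import (_ratio_weights, _weighted_median_point,
                         _weighted_mode_point, bwmr, egger, ivw)
from .harmonize import HarmonizedSet, from_arrays
from .instruments import select_by_pvalue
from .simulate import (MediationParams, PleiotropyConfig, SimulationConfig,
                       simulate_mediation_triple, simulate_pair)
from .sumstats import TraitTable


def _rep_seed(seed: int, rep: int) -> int:
    return (seed * 1_000_003 + rep) % (2**31 - 1)


def _harmonized_from_tables(exposure: TraitTable, outcome: TraitTable
                            ) -> HarmonizedSet:
    """Direct (already-aligned) harmonized set from simulated tables."""
    e, o = exposure.df, outcome.df
    merged = e.merge(o, on="snp", suffixes=("_x", "_y"))
    return from_arrays(merged["beta_x"], merged["se_x"], merged["beta_y"],
                       merged["se_y"], snp_ids=merged["snp"].tolist(),
                       eaf_x=merged["eaf_x"])


def _point_estimates(h: HarmonizedSet, methods: tuple[str, ...]) -> dict:
    """Point estimates only (no bootstrap SEs) for replicate studies."""
    bx, _, by, se_y = h.arrays()
    out = {}
    if "ivw" in methods:
        out["ivw"] = ivw(h).beta
    if "egger" in methods:
        out["egger"] = egger(h).beta
    if {"weighted_median", "weighted_mode"} & set(methods):
        ratios, weights = _ratio_weights(bx, by, se_y)
        if "weighted_median" in methods:
            out["weighted_median"] = _weighted_median_point(ratios, weights)
        if "weighted_mode" in methods:
            out["weighted_mode"] = _weighted_mode_point(ratios, weights, 1.0)
    if "bwmr" in methods:
        out["bwmr"] = bwmr(h).beta
    return out


def type1_calibration(seed: int, n_reps: int = 500, n_snps: int = 100,
                      alpha: float = 0.05) -> dict:
    """Null rejection rates of IVW, the Egger slope and Cochran's Q.

    θ=0, no pleiotropy, default (study-scale) cohort sizes. Returns the
    fraction of replicates rejecting at ``alpha`` for each test.
    """
    from .diagnostics import cochran_q

    rej = {"ivw": 0, "egger_slope": 0, "q": 0}
    for rep in range(n_reps):
        cfg = SimulationConfig(n_snps=n_snps, theta=0.0,
                               seed=_rep_seed(seed, rep))
        exposure, outcome, _, _ = simulate_pair(cfg)
        h = _harmonized_from_tables(exposure, outcome)
        if ivw(h).pvalue < alpha:
            rej["ivw"] += 1
        if egger(h).pvalue < alpha:
            rej["egger_slope"] += 1
        beta_fixed = ivw(h, model="fixed").beta
        _, _, qp = cochran_q(h, beta_fixed)
        if qp < alpha:
            rej["q"] += 1
    return {k: v / n_reps for k, v in rej.items()}


#: strong-instrument design for recovery studies (see module docstring)
RECOVERY_CONFIG = dict(n_snps=100, gamma_sd=0.2, n_exposure=500_000,
                       n_outcome=412_181, maf_range=(0.1, 0.5))


def recovery_clean(seed: int, theta: float = 0.2, n_reps: int = 200) -> dict:
    """Mean estimate and Monte-Carlo SE of the mean for all five estimators.

    All instruments valid (no pleiotropy); returns per-method
    ``{"mean": ..., "mc_se": ...}`` plus the target ``theta``.
    """
    methods = ("ivw", "egger", "weighted_median", "weighted_mode", "bwmr")
    draws: dict[str, list[float]] = {m: [] for m in methods}
    for rep in range(n_reps):
        cfg = SimulationConfig(theta=theta, seed=_rep_seed(seed, rep),
                               **RECOVERY_CONFIG)
        exposure, outcome, _, _ = simulate_pair(cfg)
        h = _harmonized_from_tables(exposure, outcome)
        for m, v in _point_estimates(h, methods).items():
            draws[m].append(v)
    out = {"theta": theta, "n_reps": n_reps}
    for m in methods:
        arr = np.asarray(draws[m])
        out[m] = {"mean": float(arr.mean()),
                  "mc_se": float(arr.std(ddof=1) / np.sqrt(n_reps))}
    return out


def recovery_contaminated(seed: int, theta: float = 0.2, n_reps: int = 200,
                          n_snps: int = 30, invalid_frac: float = 0.4,
                          pleiotropy_mean: float = 0.1) -> dict:
    """Weighted-median robustness vs IVW bias under 40% invalid instruments.

    Invalid instruments carry large positive directional pleiotropy
    (per-SNP direct effect 2.5× the per-SNP causal path θ·γ_sd);
    instrument effects are oriented positive so the pleiotropy biases
    IVW upward. At a 40% invalid count the random instrument weights
    occasionally push invalid *weight* past the median's 50% breakdown
    point, so the weighted median is not unbiased here — only far less
    biased than IVW (see docs/methods.md). Returns the replicate means
    of IVW and the weighted median, with their Monte-Carlo SEs.
    """
    ivw_d, wm_d = [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_snps=n_snps, theta=theta, gamma_sd=0.2, gamma_dist="positive",
            n_exposure=500_000, n_outcome=412_181, maf_range=(0.1, 0.5),
            pleiotropy=PleiotropyConfig(kind="directional",
                                        mean=pleiotropy_mean, sd=0.05,
                                        frac=invalid_frac),
            seed=_rep_seed(seed, rep))
        exposure, outcome, _, _ = simulate_pair(cfg)
        h = _harmonized_from_tables(exposure, outcome)
        pts = _point_estimates(h, ("ivw", "weighted_median"))
        ivw_d.append(pts["ivw"])
        wm_d.append(pts["weighted_median"])
    ivw_a, wm_a = np.asarray(ivw_d), np.asarray(wm_d)
    return {
        "theta": theta, "n_reps": n_reps,
        "ivw": {"mean": float(ivw_a.mean()),
                "mc_se": float(ivw_a.std(ddof=1) / np.sqrt(n_reps))},
        "weighted_median": {"mean": float(wm_a.mean()),
                            "mc_se": float(wm_a.std(ddof=1)
                                           / np.sqrt(n_reps))},
    }


def egger_directional(seed: int, pleiotropy_mean: float = 0.05,
                      n_reps: int = 200, n_snps: int = 150) -> dict:
    """Egger-intercept recovery of planted directional pleiotropy (θ=0).

    Instruments are selected at p < 1e-5 first, as in a real analysis:
    near-null instruments would otherwise be sign-flipped by the Egger
    orientation step and attenuate the intercept.
    """
    draws = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_snps=n_snps, theta=0.0, gamma_sd=0.2, gamma_dist="positive",
            maf_range=(0.1, 0.5),
            pleiotropy=PleiotropyConfig(kind="directional",
                                        mean=pleiotropy_mean, sd=0.02),
            seed=_rep_seed(seed, rep))
        exposure, outcome, _, _ = simulate_pair(cfg)
        sel = select_by_pvalue(exposure)
        h = _harmonized_from_tables(sel, outcome)
        draws.append(egger(h).extra["intercept"])
    arr = np.asarray(draws)
    return {"target": pleiotropy_mean, "n_reps": n_reps,
            "mean": float(arr.mean()),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(n_reps))}


def balanced_pleiotropy_calibration(seed: int, n_reps: int = 500,
                                    n_snps: int = 100, theta: float = 0.1,
                                    alpha: float = 0.05) -> dict:
    """Egger under balanced pleiotropy with InSIDE: slope recovery and
    intercept-test rejection rate (should stay near the nominal level)."""
    slopes, rejects = [], 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_snps=n_snps, theta=theta, gamma_sd=0.2, gamma_dist="positive",
            n_exposure=500_000, n_outcome=412_181, maf_range=(0.1, 0.5),
            pleiotropy=PleiotropyConfig(kind="balanced", sd=0.02),
            seed=_rep_seed(seed, rep))
        exposure, outcome, _, _ = simulate_pair(cfg)
        h = _harmonized_from_tables(exposure, outcome)
        est = egger(h)
        slopes.append(est.beta)
        if est.extra["intercept_p"] < alpha:
            rejects += 1
    arr = np.asarray(slopes)
    return {"theta": theta, "n_reps": n_reps,
            "slope_mean": float(arr.mean()),
            "slope_mc_se": float(arr.std(ddof=1) / np.sqrt(n_reps)),
            "intercept_rejection_rate": rejects / n_reps}


#: mediation recovery design: X→M→Y with β1=0.1, β2=0.25, direct 0.1,
#: hence total 0.125 and a true mediated proportion of 20%
MEDIATION_CONFIG = dict(
    n_snps=100, gamma_sd=0.2, n_exposure=500_000, n_outcome=412_181,
    maf_range=(0.1, 0.5))
MEDIATION_PARAMS = dict(beta1=0.1, beta2=0.25, direct_theta=0.1,
                        n_mediator=20_000, n_mediator_snps=100, delta_sd=0.3)


def _leg_ivw(instrument_table: TraitTable, outcome: TraitTable,
             p_threshold: float = 1e-5) -> float:
    sel = select_by_pvalue(instrument_table, p_threshold)
    h = _harmonized_from_tables(sel, outcome)
    return ivw(h).beta


def mediation_recovery(seed: int, n_reps: int = 200) -> dict:
    """Full two-step mediation recovery on simulated X→M→Y triples.

    Each replicate selects instruments at p<1e-5, estimates the total
    effect, β1 and β2 by IVW, and decomposes. Returns the mean estimated
    proportion mediated (percent) and its Monte-Carlo SE against the
    generating truth.
    """
    from .mediation import decompose

    med = MediationParams(**MEDIATION_PARAMS)
    true_prop = 100.0 * med.beta1 * med.beta2 / med.total
    props = []
    for rep in range(n_reps):
        cfg = SimulationConfig(theta=0.0, mediation=med,
                               seed=_rep_seed(seed, rep), **MEDIATION_CONFIG)
        exposure, mediator, outcome, _, _ = simulate_mediation_triple(cfg)
        total = _leg_ivw(exposure, outcome)
        b1 = _leg_ivw(exposure, mediator)
        b2 = _leg_ivw(mediator, outcome)
        res = decompose(total, b1, b2)
        if res.proportion_pct is not None:
            props.append(res.proportion_pct)
    arr = np.asarray(props)
    return {"true_proportion": true_prop, "n_reps": n_reps,
            "n_sign_consistent": int(arr.size),
            "mean": float(arr.mean()),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(arr.size))}
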