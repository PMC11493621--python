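import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrmediate.estimators import (ConvergenceError,
                                  DegenerateInstrumentError,
                                  InsufficientInstrumentsError, Z95, bwmr,
                                  egger, ivw, run_all, wald_ratio,
                                  weighted_median, weighted_mode)
from mrmediate.harmonize import from_arrays
from conftest import random_harmonized


def hset(bx, by, se_y, se_x=None):
    bx = np.asarray(bx, float)
    se_x = np.full_like(bx, 1e-3) if se_x is None else se_x
    return from_arrays(bx, se_x, by, se_y)


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        est = wald_ratio(hset([0.5], [0.25], [0.1]))
        assert est.beta == pytest.approx(0.5) and est.se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        assert wald_ratio(hset([0.5], [0.0], [0.1])).beta == 0.0

    def test_negative_ratio(self):
        est = wald_ratio(hset([0.2], [-0.1], [0.05]))
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.25)

    def test_zero_instrument_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(hset([0.0], [0.1], [0.1]))


class TestIVW:
    def test_consensus_of_identical_snps(self):
        est = ivw(hset([0.5, 0.5], [0.25, 0.25], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.5)

    def test_closed_form_beta_and_fixed_se(self):
        h = hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1, 0.1, 0.1])
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.5, rel=1e-12)
        assert est.se == pytest.approx(math.sqrt(0.01 / 0.14), rel=1e-12)

    def test_matches_zero_intercept_wls_oracle(self, rng):
        """IVW must equal the no-intercept WLS slope with weights 1/se_y²
        (independent route through statsmodels) to 10 significant digits."""
        for _ in range(50):
            h = random_harmonized(rng)
            bx, _, by, se_y = h.arrays()
            oracle = sm.WLS(by, bx[:, None], weights=1 / se_y**2).fit()
            assert ivw(h, model="fixed").beta == pytest.approx(
                float(oracle.params[0]), rel=1e-10)

    def test_random_effects_never_below_fixed_se(self, rng):
        for _ in range(20):
            h = random_harmonized(rng)
            assert ivw(h).se >= ivw(h, model="fixed").se - 1e-15

    def test_k1_delegates_to_wald(self):
        est = ivw(hset([0.5], [0.25], [0.1]))
        assert est.method == "wald_ratio"

    def test_all_null_instruments_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            ivw(hset([0.0, 0.0], [0.1, 0.1], [0.1, 0.1]))


class TestEgger:
    def test_exact_proportional_line(self, proportional_set):
        est = egger(proportional_set)
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        h = hset(bx, 0.1 + 0.3 * bx, np.full(5, 0.01))
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-9)
        assert est.extra["intercept"] == pytest.approx(0.1, abs=1e-9)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]))

    def test_orientation_invariant_to_input_signs(self, rng):
        h = random_harmonized(rng, k=8)
        bx, se_x, by, se_y = h.arrays()
        flip = rng.choice([-1.0, 1.0], size=8)
        h2 = from_arrays(bx * flip, se_x, by * flip, se_y)
        assert egger(h2).beta == pytest.approx(egger(h).beta, rel=1e-10)
        assert egger(h2).extra["intercept"] == pytest.approx(
            egger(h).extra["intercept"], rel=1e-10)


def brute_force_weighted_median(ratios, weights):
    """Independent oracle: plain-Python transcription of the centered
    cumulative-weight percentile rule (no numpy interpolation)."""
    pairs = sorted(zip([float(r) for r in ratios],
                       [float(w) for w in weights]))
    total = sum(w for _, w in pairs)
    pts, cum = [], 0.0
    for r, w in pairs:
        pts.append((r, (cum + w / 2.0) / total))
        cum += w
    if 0.5 <= pts[0][1]:
        return pts[0][0]
    for (r1, s1), (r2, s2) in zip(pts, pts[1:]):
        if s1 <= 0.5 <= s2:
            return r1 + (0.5 - s1) / (s2 - s1) * (r2 - r1)
    return pts[-1][0]


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(hset(bx, 0.4 * bx, np.full(3, 0.01)),
                              n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.4)

    def test_equal_weight_percentile(self):
        # ratios (0.1, 0.2, 0.9) with equal weights -> middle value
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        est = weighted_median(hset(bx, by, np.full(3, 0.1)), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_against_brute_force_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 10))
            bx = rng.uniform(0.5, 2.0, k)
            by = rng.normal(0, 0.5, k)
            se_y = rng.uniform(0.05, 0.2, k)
            est = weighted_median(hset(bx, by, se_y), n_boot=10, seed=1)
            oracle = brute_force_weighted_median(by / bx, (bx / se_y) ** 2)
            assert est.beta == pytest.approx(oracle, abs=1e-3)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hset([1.0, 1.0], [0.1, 0.2], [0.1, 0.1]))


def density_argmax_oracle(ratios, weights, bandwidth):
    grid = np.linspace(min(ratios) - 3 * bandwidth,
                       max(ratios) + 3 * bandwidth, 200_001)
    dens = np.zeros_like(grid)
    for r, w in zip(ratios, weights):
        dens += w * np.exp(-0.5 * ((grid - r) / bandwidth) ** 2)
    return float(grid[int(np.argmax(dens))])


class TestWeightedMode:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_mode(hset(bx, 0.4 * bx, np.full(3, 0.01)),
                            n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-6)

    def test_majority_cluster_wins(self):
        bx = np.ones(4)
        by = np.array([0.2, 0.2, 0.2, 0.9])
        est = weighted_mode(hset(bx, by, np.full(4, 0.1)), n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.2, abs=0.02)

    def test_against_density_oracle(self, rng):
        from mrmediate.estimators import _mode_bandwidth
        for _ in range(10):
            k = int(rng.integers(4, 12))
            bx = rng.uniform(0.5, 2.0, k)
            by = rng.normal(0.1, 0.3, k)
            se_y = rng.uniform(0.05, 0.2, k)
            ratios, weights = by / bx, (bx / se_y) ** 2
            est = weighted_mode(hset(bx, by, se_y), n_boot=10, seed=1)
            oracle = density_argmax_oracle(ratios, weights,
                                           _mode_bandwidth(ratios, 1.0))
            assert est.beta == pytest.approx(oracle, abs=1e-4)


class TestBWMR:
    def test_matches_fixed_ivw_on_clean_data(self, rng):
        # no overdispersion, no outliers, strong precise instruments
        k = 20
        gamma = rng.uniform(0.1, 0.3, k)
        se_y = np.full(k, 0.003)
        by = 0.25 * gamma + rng.normal(0, se_y)
        h = hset(gamma, by, se_y, se_x=np.full(k, 1e-4))
        assert bwmr(h).beta == pytest.approx(ivw(h, model="fixed").beta,
                                             abs=1e-3)

    def test_likelihood_dominates_prior_on_exact_line(self):
        bx = np.linspace(0.1, 0.3, 6)
        h = hset(bx, 0.3 * bx, np.full(6, 1e-3))
        assert bwmr(h, prior_sd_theta=100.0).beta == pytest.approx(0.3,
                                                                   abs=1e-3)

    def test_downweights_gross_outliers(self, rng):
        k, theta = 20, 0.1
        gamma = rng.uniform(0.1, 0.3, k)
        se_y = np.full(k, 0.005)
        by = theta * gamma + rng.normal(0, se_y)
        by[:2] += 0.2  # two gross outliers
        h = hset(gamma, by, se_y, se_x=np.full(k, 1e-3))
        err_bwmr = abs(bwmr(h).beta - theta)
        err_ivw = abs(ivw(h, model="fixed").beta - theta)
        assert err_bwmr < err_ivw
        assert bwmr(h).extra["min_weight"] < 0.05

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            bwmr(hset([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]))


class TestSharedInvariants:
    def all_methods(self, h, seed=3):
        return {
            "ivw": ivw(h),
            "egger": egger(h),
            "wm": weighted_median(h, n_boot=80, seed=seed),
            "mode": weighted_mode(h, n_boot=80, seed=seed),
            "bwmr": bwmr(h, seed=seed),
        }

    def test_allele_reorientation_leaves_estimates_unchanged(self, rng):
        # flipping the effect allele negates bx and by together; every
        # per-SNP ratio, hence every estimator, must be unchanged
        h = random_harmonized(rng, k=8)
        bx, se_x, by, se_y = h.arrays()
        flipped = from_arrays(-bx, se_x, -by, se_y)
        for name, est in self.all_methods(h).items():
            est2 = self.all_methods(flipped)[name]
            assert est2.beta == pytest.approx(est.beta, rel=1e-6), name

    def test_outcome_sign_flip_negates_beta_keeps_se(self, rng):
        h = random_harmonized(rng, k=8)
        bx, se_x, by, se_y = h.arrays()
        flipped = from_arrays(bx, se_x, -by, se_y)
        for name, est in self.all_methods(h).items():
            est2 = self.all_methods(flipped)[name]
            assert est2.beta == pytest.approx(-est.beta, rel=1e-6), name
            # bootstrap SEs see different resampling noise after the flip
            rel = 0.25 if name in ("wm", "mode") else 1e-6
            assert est2.se == pytest.approx(est.se, rel=rel), name

    def test_outcome_scaling_equivariance(self, rng):
        c = 3.0
        h = random_harmonized(rng, k=8)
        bx, se_x, by, se_y = h.arrays()
        scaled = from_arrays(bx, se_x, c * by, c * se_y)
        for name, est in self.all_methods(h).items():
            est2 = self.all_methods(scaled)[name]
            # bwmr's prior on the causal effect has a fixed scale, so its
            # equivariance is only approximate on weakly informative data
            rel = 5e-2 if name == "bwmr" else 1e-8
            assert est2.beta == pytest.approx(c * est.beta, rel=rel), name
            assert est2.se == pytest.approx(c * est.se, rel=rel), name

    def test_estimate_derived_fields_consistent(self, rng):
        h = random_harmonized(rng, k=6)
        for est in self.all_methods(h).values():
            assert est.or_ == pytest.approx(math.exp(est.beta), rel=1e-12)
            assert est.ci_low == pytest.approx(
                math.exp(est.beta - Z95 * est.se), rel=1e-12)
            assert est.ci_low < est.or_ < est.ci_high
            if est.method in ("ivw", "egger", "wald_ratio"):
                expect = 2 * stats.norm.sf(abs(est.beta) / est.se)
                assert est.pvalue == pytest.approx(max(expect, 1e-300),
                                                   rel=1e-6)


class TestRunAll:
    def test_arity_rules(self, rng):
        h1 = hset([0.5], [0.25], [0.1])
        h2 = hset([0.5, 0.4], [0.25, 0.2], [0.1, 0.1])
        h5 = random_harmonized(rng, k=5)
        assert [e.method for e in run_all(h1)] == ["wald_ratio"]
        assert [e.method for e in run_all(h2)] == ["ivw"]
        assert len(run_all(h5, n_boot=20)) == 5

    def test_method_failure_recorded_not_fatal(self):
        # bx=0 in a k=1 set: wald ratio fails, batch survives
        h = hset([0.0], [0.1], [0.1])
        failures = []
        out = run_all(h, failures=failures)
        assert out == [] and failures[0][0] == "wald_ratio"
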