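"""One exposure-outcome MR analysis on synthetic summary statistics.

Simulates a gut-microbiota-scale exposure GWAS (N=7,738) and a biobank
outcome GWAS (N=412,181) with a true causal effect theta = 0.2, selects
instruments (p < 1e-5, LD clumping, F >= 10), harmonizes alleles and
runs all five estimators plus the sensitivity battery.
"""

from mrmediate import (RunConfig, SimulationConfig, build_instrument_set,
                       harmonize, run_all, sensitivity_report, simulate_pair)

cfg = SimulationConfig(n_snps=100, theta=0.2, gamma_sd=0.15, seed=7)
exposure, outcome, ld, truth = simulate_pair(cfg)

iv = build_instrument_set(exposure, ld)
print(f"instruments: k={iv.k}, summed R2={iv.r2_total:.4f}, "
      f"F={iv.f_stat:.1f}")

h = harmonize(iv.table, outcome)
print(f"harmonized SNPs: {h.k} (drops: {h.drops})")

for est in run_all(h, seed=1, n_boot=500):
    print(f"{est.method:16s} beta={est.beta:+.4f} se={est.se:.4f} "
          f"OR={est.or_:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}] "
          f"p={est.pvalue:.2e}")

rep = sensitivity_report(h)
print(f"Cochran Q={rep.q_ivw:.1f} (df={rep.q_df}, p={rep.q_p:.3f}); "
      f"Egger intercept={rep.egger_intercept:+.4f} "
      f"(p={rep.egger_intercept_p:.3f})")
print(f"influential SNPs (leave-one-out): {rep.influential_snps or 'none'}")
print(f"\ntrue causal effect was theta={cfg.theta}: every estimator above "
      "should land near it and the Egger intercept test should be quiet. "
      "Cochran's Q may flag mild heterogeneity here — with a modest "
      "exposure GWAS the first-order ratio weights understate the true "
      "ratio variance; the random-effects IVW already absorbs this.")
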