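"""Bidirectional batch screening of many exposures against one outcome.

Ten synthetic exposure traits — the first with a real effect on the
outcome, nine null — are screened forward (tiering on the IVW p-value),
checked for reverse causality, and Bayes-validated. The printed table
mirrors the per-trait screen report the pipeline writes to screen.tsv.
"""

from mrmediate import (LDInfo, RunConfig, SimulationConfig, TraitTable,
                       bayes_validate, forward_screen, reverse_screen,
                       screen_table, simulate_pair)

config = RunConfig(n_boot=100)
exposures, outcome = [], None
for i in range(10):
    theta = 0.25 if i == 0 else 0.0  # only the first trait is causal
    e, o, _, _ = simulate_pair(
        SimulationConfig(n_snps=60, theta=theta, seed=400 + i))
    exposures.append(TraitTable(f"trait{i:02d}", "exposure", e.df))
    outcome = outcome or TraitTable("outcome", "outcome", o.df)

records = forward_screen(exposures, outcome, LDInfo(), config)
records = reverse_screen(outcome, {t.trait_id: t for t in exposures},
                         records, LDInfo(), config)
records = bayes_validate(records, config)

cols = ["exposure", "nsnp", "beta", "pvalue", "tier", "reverse_clear",
        "bayes_confirmed"]
print(screen_table(records)[cols].to_string(index=False))
print("\ntrait00 carries a true effect (theta=0.25) and should be tiered "
      "significant and Bayes-confirmed; the null traits should mostly be "
      "rejected (a ~5% false-suggestive rate is expected). trait00's "
      "reverse check is expectedly NOT clear: this synthetic outcome's "
      "only associated variants are the exposure's own instruments, so "
      "the reverse leg inherits the forward signal — real analyses rely "
      "on the outcome trait having instruments of its own.")
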