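"""End-to-end orchestration: screen + mediate + manifest.

``run_pipeline`` ties the stages together and writes a reproducible
artifact directory:

    screen.tsv       per-exposure forward screen (tier, reverse, Bayes)
    estimates.tsv    every per-method estimate for every tested pair
    mediation.tsv    mediation candidates and decompositions
    diagnostics.json heterogeneity/pleiotropy tests per exposure
    manifest.json    inputs, thresholds, seeds, package version

Reruns with the same inputs, config and seeds are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import RunConfig
from .mediation import find_mediators, write_mediation_table
from .screening import (bayes_validate, forward_screen, reverse_screen,
                        write_screen_table)
from .sumstats import LDInfo, TraitTable, write_results


def run_pipeline(exposures: list[TraitTable], outcome: TraitTable,
                 ld: LDInfo, out_dir: str | Path,
                 config: RunConfig | None = None,
                 mediator_panel: list[TraitTable] | None = None,
                 input_paths: dict[str, str] | None = None) -> Path:
    """Run screen (+ optional mediation) and write the artifact directory."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = forward_screen(exposures, outcome, ld, config)
    exposure_map = {t.trait_id: t for t in exposures}
    records = reverse_screen(outcome, exposure_map, records, ld, config)
    records = bayes_validate(records, config)

    write_screen_table(records, out_dir / "screen.tsv")
    all_estimates = [e for r in records for e in r.estimates]
    write_results(all_estimates, out_dir / "estimates.tsv")

    diag = {r.exposure_id: r.diagnostics.to_dict()
            for r in records if r.diagnostics is not None}
    (out_dir / "diagnostics.json").write_text(json.dumps(diag, indent=1,
                                                         sort_keys=True))

    candidates = []
    if mediator_panel:
        passed = [r for r in records
                  if r.tier != "rejected" and r.reverse_clear]
        candidates = find_mediators(passed, exposure_map, mediator_panel,
                                    outcome, ld, config)
        write_mediation_table(candidates, out_dir / "mediation.tsv")

    manifest = {
        "package": "mrmediate",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": input_paths or {
            "exposures": [t.trait_id for t in exposures],
            "outcome": outcome.trait_id,
            "mediators": [t.trait_id for t in (mediator_panel or [])],
        },
        "n_exposures": len(exposures),
        "n_mediators": len(mediator_panel or []),
        "n_candidates": len(candidates),
        "tiers": {t: sum(r.tier == t for r in records)
                  for t in ("rejected", "suggestive", "significant")},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return out_dir
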