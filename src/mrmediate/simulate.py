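"""Synthetic GWAS summary statistics with known causal truth.

The generator emulates the two-sample setting of a microbiome/immune-
trait screen: an exposure GWAS of modest size (default N=7,738, the
scale of published gut-microbiota GWAS), a large binary-outcome GWAS
(default N=412,181, a biobank endpoint), per-SNP instrument effects of
known size, an optional horizontal-pleiotropy regime, optional LD blocks
and an optional exposure → mediator → outcome chain.

Generating model, per SNP j with minor-allele frequency maf_j:

    γ_j  ~ N(0, gamma_sd²)              (true instrument effect)
    se_xj = 1 / sqrt(2·maf_j·(1−maf_j)·N_exposure)
    bx_j  = γ_j + N(0, se_xj²)
    α_j   per pleiotropy regime          (direct path to outcome)
    se_yj = 1 / sqrt(2·maf_j·(1−maf_j)·N_outcome)
    by_j  = θ·γ_j + α_j + N(0, se_yj²)

p-values are two-sided normal. The SE model is the standardized-trait
approximation; case–control imbalance of a binary outcome is not
modelled (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import COLUMNS, LDInfo, TraitTable


@dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy regime for the invalid fraction of SNPs.

    ``none``: all α_j = 0. ``balanced``: α_j ~ N(0, sd²) (InSIDE holds).
    ``directional``: α_j ~ N(mean, sd²). ``frac`` is the fraction of
    SNPs that are invalid (carry a nonzero α). ``gamma_corr`` adds
    gamma_corr·γ_j to α_j, violating InSIDE when nonzero.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    frac: float = 1.0
    gamma_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0 or not 0.0 <= self.frac <= 1.0:
            raise ValueError("invalid pleiotropy parameters")


@dataclass
class MediationParams:
    """True effects of an X → M → Y chain.

    ``beta1``: exposure→mediator; ``beta2``: mediator→outcome;
    ``direct_theta``: direct exposure→outcome path. The total effect is
    direct_theta + beta1·beta2. ``n_mediator`` is the mediator GWAS
    sample size (default 3,757, the scale of immune-trait GWAS);
    ``n_mediator_snps`` counts mediator-specific instruments.
    """

    beta1: float
    beta2: float
    direct_theta: float
    n_mediator: int = 3757
    n_mediator_snps: int = 100
    delta_sd: float = 0.2

    @property
    def total(self) -> float:
        return self.direct_theta + self.beta1 * self.beta2


@dataclass
class SimulationConfig:
    n_snps: int = 100
    n_exposure: int = 7738
    n_outcome: int = 412_181
    theta: float = 0.0
    gamma_sd: float = 0.15
    gamma_dist: str = "normal"  # "positive" takes |N(0, gamma_sd²)|
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    mediation: MediationParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.gamma_sd < 0:
            raise ValueError("gamma_sd must be >= 0")
        if self.gamma_dist not in {"normal", "positive"}:
            raise ValueError(f"unknown gamma_dist {self.gamma_dist!r}")


@dataclass
class SimulationTruth:
    """Realized generating values — the ground truth recovery is tested against."""

    config: SimulationConfig
    snp_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    mediator_snp_ids: list[str] = field(default_factory=list)
    delta: np.ndarray | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        cfg = dataclasses.asdict(self.config)
        if cfg["mediation"] is None:
            cfg.pop("mediation")
        payload = {
            "config": cfg,
            "snp_ids": self.snp_ids,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "maf": self.maf.tolist(),
            "mediator_snp_ids": self.mediator_snp_ids,
            "delta": self.delta.tolist() if self.delta is not None else None,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig,
                gamma: np.ndarray) -> np.ndarray:
    p = cfg.pleiotropy
    alpha = np.zeros(cfg.n_snps)
    if p.kind == "none":
        return alpha
    n_invalid = int(round(p.frac * cfg.n_snps))
    idx = rng.choice(cfg.n_snps, size=n_invalid, replace=False)
    mean = 0.0 if p.kind == "balanced" else p.mean
    alpha[idx] = rng.normal(mean, p.sd, size=n_invalid)
    if p.gamma_corr:
        alpha[idx] += p.gamma_corr * gamma[idx]
    return alpha


def _positions(n: int, start_chrom: int = 1) -> tuple[list[str], list[int]]:
    """Place SNPs 20 Mb apart cycling over autosomes: farther than any
    clumping window, so unlinked SNPs never compete."""
    chroms, poss = [], []
    for j in range(n):
        chroms.append(str((j + start_chrom - 1) % 22 + 1))
        poss.append(1_000_000 + 20_000_000 * ((j + start_chrom - 1) // 22))
    return chroms, poss


def _trait_frame(snp_ids, chroms, poss, maf, beta, se, n) -> pd.DataFrame:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    p = np.clip(p, 1e-300, 1.0)
    return pd.DataFrame({
        "snp": snp_ids, "chrom": chroms, "pos": pd.array(poss, dtype="Int64"),
        "ea": "A", "oa": "G", "eaf": maf, "beta": beta, "se": se, "p": p,
        "n": pd.array([n] * len(snp_ids), dtype="Int64"),
    })[COLUMNS]


def _se_model(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_pair(config: SimulationConfig
                  ) -> tuple[TraitTable, TraitTable, LDInfo, SimulationTruth]:
    """Generate one exposure/outcome summary-statistic pair with truth.

    LD blocks (``config.ld_blocks`` entries ``(size, r2)``) are carved
    from the leading SNPs: block members share the lead SNP's γ, sit
    10 kb apart on one chromosome and carry pairwise r² as configured —
    duplicated association signal that clumping should reduce to one
    representative. Output is byte-reproducible from (config, seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    snp_ids = [f"rs{j + 1}" for j in range(n)]
    maf = rng.uniform(*cfg.maf_range, size=n)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n)
    if cfg.gamma_dist == "positive":
        gamma = np.abs(gamma)
    alpha = _draw_alpha(rng, cfg, gamma)

    chroms, poss = _positions(n)
    ld = LDInfo()
    cursor = 0
    for b, (size, r2) in enumerate(cfg.ld_blocks):
        members = list(range(cursor, min(cursor + size, n)))
        for i, j in enumerate(members):
            chroms[j] = str(b % 22 + 1)
            poss[j] = 50_000_000 + 10_000 * i
            gamma[j] = gamma[members[0]]  # shared causal signal
        for a in members:
            for c in members:
                if a < c:
                    ld.set_r2(snp_ids[a], snp_ids[c], r2)
        cursor += size
    for j, s in enumerate(snp_ids):
        ld.positions[s] = (chroms[j], poss[j])

    se_x = _se_model(maf, cfg.n_exposure)
    bx = gamma + rng.normal(0.0, se_x)
    se_y = _se_model(maf, cfg.n_outcome)
    by = cfg.theta * gamma + alpha + rng.normal(0.0, se_y)

    exposure = TraitTable("sim_exposure", "exposure",
                          _trait_frame(snp_ids, chroms, poss, maf, bx, se_x,
                                       cfg.n_exposure))
    outcome = TraitTable("sim_outcome", "outcome",
                         _trait_frame(snp_ids, chroms, poss, maf, by, se_y,
                                      cfg.n_outcome))
    truth = SimulationTruth(cfg, snp_ids, gamma, alpha, maf)
    return exposure, outcome, ld, truth


def simulate_mediation_triple(config: SimulationConfig
                              ) -> tuple[TraitTable, TraitTable, TraitTable,
                                         LDInfo, SimulationTruth]:
    """Generate an exposure/mediator/outcome triple with a known chain.

    Exposure SNPs affect the mediator through β1·γ_j and the outcome
    through (direct_theta + β1·β2)·γ_j. Mediator-specific SNPs (effects
    δ_l ~ N(0, delta_sd²)) drive the mediator directly and reach the
    outcome as β2·δ_l — they are the instruments of the M → Y leg. The
    mediator and outcome tables carry both SNP groups; the exposure
    table carries only exposure SNPs.
    """
    cfg = config
    if cfg.mediation is None:
        raise ValueError("config.mediation must be set")
    med = cfg.mediation
    rng = np.random.default_rng(cfg.seed)

    n_x, n_m = cfg.n_snps, med.n_mediator_snps
    x_ids = [f"rs{j + 1}" for j in range(n_x)]
    m_ids = [f"rs{n_x + l + 1}" for l in range(n_m)]
    maf_x = rng.uniform(*cfg.maf_range, size=n_x)
    maf_m = rng.uniform(*cfg.maf_range, size=n_m)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n_x)
    if cfg.gamma_dist == "positive":
        gamma = np.abs(gamma)
    delta = rng.normal(0.0, med.delta_sd, size=n_m)
    alpha = _draw_alpha(rng, cfg, gamma)

    chroms_x, poss_x = _positions(n_x)
    chroms_m, poss_m = _positions(n_m, start_chrom=n_x + 1)

    se_x = _se_model(maf_x, cfg.n_exposure)
    bx = gamma + rng.normal(0.0, se_x)

    all_ids = x_ids + m_ids
    maf_all = np.concatenate([maf_x, maf_m])
    chroms_all, poss_all = chroms_x + chroms_m, poss_x + poss_m

    se_m = _se_model(maf_all, med.n_mediator)
    true_m = np.concatenate([med.beta1 * gamma, delta])
    bm = true_m + rng.normal(0.0, se_m)

    se_y = _se_model(maf_all, cfg.n_outcome)
    true_y = np.concatenate([med.total * gamma + alpha, med.beta2 * delta])
    by = true_y + rng.normal(0.0, se_y)

    exposure = TraitTable("sim_exposure", "exposure",
                          _trait_frame(x_ids, chroms_x, poss_x, maf_x, bx,
                                       se_x, cfg.n_exposure))
    mediator = TraitTable("sim_mediator", "mediator",
                          _trait_frame(all_ids, chroms_all, poss_all, maf_all,
                                       bm, se_m, med.n_mediator))
    outcome = TraitTable("sim_outcome", "outcome",
                         _trait_frame(all_ids, chroms_all, poss_all, maf_all,
                                      by, se_y, cfg.n_outcome))
    truth = SimulationTruth(cfg, x_ids, gamma, alpha, maf_x,
                            mediator_snp_ids=m_ids, delta=delta)
    return exposure, mediator, outcome, LDInfo(), truth
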