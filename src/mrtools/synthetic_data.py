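"""Summary-level two-sample GWAS simulator with known ground truth.

Statistics are simulated directly at the summary level (no individual
genotypes): each instrument k has a true exposure effect γ_k and a
direct (pleiotropic) outcome effect α_k, and the observed associations
are noisy versions

    X_k ~ Normal(γ_k, se_X_k)
    Y_k ~ Normal(β·γ_k + α_k, se_Y_k)

with independent noise on the two sides (no sample overlap).
Instruments are generated independent, matching the post-clumping state
of a real analysis.  The emitted records use the same types and TSV
layout the readers consume, so pipeline tests can run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .harmonize import HarmonizedSet, build_harmonized_set
from .summary_io import GwasRecord

__all__ = ["SimConfig", "SimTruth", "simulate_study", "simulate_harmonized", "scenario_suite"]

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic two-sample study.

    ``gamma_low``/``gamma_high`` bound the uniform distribution of true
    instrument strengths.  ``pleiotropy`` selects how the direct effects
    α_k are drawn: ``none`` (all zero), ``balanced`` (mean-zero normal)
    or ``directional`` (normal with non-zero mean).  With
    ``inside_violation`` the α_k are made proportional to γ_k plus
    noise, breaking the InSIDE assumption.  ``invalid_fraction`` limits
    pleiotropy to a leading subset of instruments (1.0 = all), used for
    minority-invalid scenarios.
    """

    K: int = 10
    beta_causal: float = 0.0
    gamma_low: float = 0.05
    gamma_high: float = 0.3
    se_X_level: float = 0.004
    se_Y_level: float = 0.05
    se_jitter: float = 0.2  # relative SE spread; 0 = constant SEs
    pleiotropy: str = "none"  # none | balanced | directional
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    invalid_fraction: float = 1.0
    inside_violation: bool = False
    maf_low: float = 0.01
    maf_high: float = 0.5
    palindromic_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if not (self.se_X_level > 0 and self.se_Y_level > 0):
            raise ConfigurationError("SE levels must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.pleiotropy == "none" and (self.alpha_mean != 0 or self.alpha_sd != 0):
            raise ConfigurationError("pleiotropy='none' requires alpha_mean = alpha_sd = 0")
        if self.pleiotropy == "balanced" and self.alpha_mean != 0:
            raise ConfigurationError("balanced pleiotropy requires alpha_mean = 0")
        if not (0 <= self.invalid_fraction <= 1):
            raise ConfigurationError("invalid_fraction must be in [0, 1]")
        if not (0 < self.gamma_low <= self.gamma_high):
            raise ConfigurationError("need 0 < gamma_low <= gamma_high")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated study."""

    beta_causal: float
    gamma: np.ndarray
    alpha: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    eaf: np.ndarray


def _draw_alleles(rng: np.random.Generator, k: int, palindromic_fraction: float):
    eff, oth = [], []
    for _ in range(k):
        if rng.random() < palindromic_fraction:
            pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            pair = _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        eff.append(pair[0])
        oth.append(pair[1])
    return eff, oth


def simulate_study(
    cfg: SimConfig, seed: int | None = None
) -> tuple[list[GwasRecord], list[GwasRecord], SimTruth]:
    """Draw one synthetic exposure/outcome summary-statistic pair.

    Returns exposure records, outcome records (same SNPs and allele
    coding, independent noise) and the generating truth.  Fully
    reproducible: the same config and seed give bit-identical output.
    ``seed`` overrides ``cfg.seed`` when given.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.K
    gamma = rng.uniform(cfg.gamma_low, cfg.gamma_high, k)

    alpha = np.zeros(k)
    n_invalid = int(round(cfg.invalid_fraction * k))
    if cfg.pleiotropy != "none" and n_invalid > 0:
        if cfg.inside_violation:
            # direct effect proportional to instrument strength + noise
            c = cfg.alpha_mean / np.mean(gamma[:n_invalid]) if cfg.alpha_mean else 1.0
            alpha[:n_invalid] = c * gamma[:n_invalid] + rng.normal(0, cfg.alpha_sd, n_invalid)
        else:
            alpha[:n_invalid] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, n_invalid)

    jit = cfg.se_jitter
    se_x = cfg.se_X_level * (1 + jit * rng.uniform(-1, 1, k)) if jit else np.full(k, cfg.se_X_level)
    se_y = cfg.se_Y_level * (1 + jit * rng.uniform(-1, 1, k)) if jit else np.full(k, cfg.se_Y_level)

    x = rng.normal(gamma, se_x)
    y = rng.normal(cfg.beta_causal * gamma + alpha, se_y)
    eaf = rng.uniform(cfg.maf_low, cfg.maf_high, k)
    eff, oth = _draw_alleles(rng, k, cfg.palindromic_fraction)

    p_x = np.maximum(2 * stats.norm.sf(np.abs(x / se_x)), 5e-324)
    p_y = np.maximum(2 * stats.norm.sf(np.abs(y / se_y)), 5e-324)

    width = len(str(k))
    exposure, outcome = [], []
    for i in range(k):
        snp = f"rs{i + 1:0{width}d}"
        exposure.append(
            GwasRecord(snp, eff[i], oth[i], float(x[i]), float(se_x[i]), float(p_x[i]),
                       eaf=float(eaf[i]), chrom=str(1 + i % 22), pos=(i + 1) * 2_000_000)
        )
        outcome.append(
            GwasRecord(snp, eff[i], oth[i], float(y[i]), float(se_y[i]), float(p_y[i]),
                       eaf=float(eaf[i]), chrom=str(1 + i % 22), pos=(i + 1) * 2_000_000)
        )
    truth = SimTruth(cfg.beta_causal, gamma, alpha, eff, oth, eaf)
    return exposure, outcome, truth


def simulate_harmonized(cfg: SimConfig, seed: int | None = None) -> tuple[HarmonizedSet, SimTruth]:
    """One simulated study already merged into a :class:`HarmonizedSet`.

    Convenience for estimator calibration loops; equivalent to running
    :func:`simulate_study` through ``build_harmonized_set`` with the
    paper-style ``keep`` palindromic policy.
    """
    exposure, outcome, truth = simulate_study(cfg, seed=seed)
    h = build_harmonized_set(
        exposure, outcome, exposure_name="sim_exposure", outcome_name="sim_outcome",
        palindromic_mode="keep",
    )
    return h, truth


def scenario_suite() -> dict[str, SimConfig]:
    """Fixed, seeded scenarios covering the estimators' assumption space."""
    return {
        "null": SimConfig(K=10, beta_causal=0.0, seed=101),
        "causal_no_pleiotropy": SimConfig(K=7, beta_causal=-0.46, seed=102),
        "balanced": SimConfig(
            K=30, beta_causal=0.2, pleiotropy="balanced", alpha_mean=0.0, alpha_sd=0.03,
            seed=103,
        ),
        "directional_inside_ok": SimConfig(
            K=100, beta_causal=0.1, pleiotropy="directional", alpha_mean=0.05,
            alpha_sd=0.02, seed=104,
        ),
        "directional_inside_violated": SimConfig(
            K=100, beta_causal=0.1, pleiotropy="directional", alpha_mean=0.05,
            alpha_sd=0.02, inside_violation=True, seed=105,
        ),
        "minority_invalid": SimConfig(
            K=10, beta_causal=0.2, pleiotropy="directional", alpha_mean=0.25,
            alpha_sd=0.02, invalid_fraction=0.3, seed=106,
        ),
    }
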