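"""Heterogeneity, leave-one-out and per-SNP diagnostic tables.

These tables are the canonical artifacts behind scatter, forest and
leave-one-out plots; any plotting is derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MrEstimate, ivw, mr_egger, to_odds_scale, wald_ratio, weighted_median
from .harmonize import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutTable",
    "cochran_q",
    "leave_one_out",
    "single_snp_table",
    "flag_outliers",
]

ALL_SNP_ROW = "__all__"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q of the Wald ratios about the IVW estimate."""

    Q: float
    df: int
    pvalue: float


@dataclass
class LeaveOneOutTable:
    """IVW re-estimates with each SNP omitted, plus the all-SNP reference row."""

    rows: dict[str, MrEstimate]  # keyed by omitted snp_id; ALL_SNP_ROW = full set
    degenerate: bool = False  # K=2 input: omission rows are single-SNP Wald ratios

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for key, est in self.rows.items():
            recs.append(
                {
                    "omitted_snp": "(none)" if key == ALL_SNP_ROW else key,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "OR": est.odds_ratio,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pvalue": est.pvalue,
                }
            )
        return pd.DataFrame(recs)


def cochran_q(h: HarmonizedSet) -> HeterogeneityResult:
    """Q = Σ w_k (r_k − β̂_IVW)² with r_k = Y_k/X_k and w_k = (X_k/σ_Yk)².

    p is the upper tail of chi-square with K−1 degrees of freedom.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError(f"cochran_q requires K >= 2, got {h.n_snp}")
    beta = ivw(h).beta
    r = h.Y / h.X
    w = (h.X / h.se_Y) ** 2
    q = float(np.sum(w * (r - beta) ** 2))
    df = h.n_snp - 1
    return HeterogeneityResult(Q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def leave_one_out(h: HarmonizedSet) -> LeaveOneOutTable:
    """IVW on every K−1 subset, keyed by the omitted SNP, plus the full set."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError(f"leave_one_out requires K >= 2, got {h.n_snp}")
    hs = h.sorted_by_snp()
    rows: dict[str, MrEstimate] = {}
    for i, snp in enumerate(hs.snp_ids):
        keep = [j for j in range(hs.n_snp) if j != i]
        rows[snp] = ivw(hs.subset(keep))
    rows[ALL_SNP_ROW] = ivw(hs)
    return LeaveOneOutTable(rows=rows, degenerate=h.n_snp == 2)


def single_snp_table(
    h: HarmonizedSet,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-SNP Wald-ratio estimates plus the combined-method rows.

    One row per SNP in canonical snp-id order, then ``ivw``,
    ``weighted_median`` (when K ≥ 3) and ``mr_egger`` (when K ≥ 3)
    summary rows.
    """
    hs = h.sorted_by_snp()
    recs = []
    for i, snp in enumerate(hs.snp_ids):
        beta, se = wald_ratio(hs.X[i], hs.se_X[i], hs.Y[i], hs.se_Y[i], snp_id=snp)
        or_, lo, hi = to_odds_scale(beta, se, level=level)
        p = 2 * stats.norm.sf(abs(beta / se))
        recs.append(
            {"snp": snp, "method": "wald", "beta": beta, "se": se, "OR": or_,
             "ci_low": lo, "ci_high": hi, "pvalue": p}
        )
    combined = [ivw(hs)]
    if hs.n_snp >= 3:
        combined.append(weighted_median(hs, n_boot=n_boot, seed=seed))
        combined.append(mr_egger(hs).slope)
    for est in combined:
        recs.append(
            {"snp": "(combined)", "method": est.method, "beta": est.beta, "se": est.se,
             "OR": est.odds_ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
             "pvalue": est.pvalue}
        )
    return pd.DataFrame(recs)


def flag_outliers(h: HarmonizedSet, alpha: float = 0.05) -> list[str]:
    """Report (never remove) potential outlier SNPs.

    A SNP is flagged when omitting it moves the IVW beta by more than
    one full-set SE, or when its individual Q contribution exceeds the
    chi-square(1) critical value at ``alpha`` Bonferroni-adjusted by K.
    This is the package's own reproducible screen for what is usually an
    eyeball judgement on the plots.
    """
    if h.n_snp < 3:
        return []
    full = ivw(h)
    loo = leave_one_out(h)
    r = h.Y / h.X
    w = (h.X / h.se_Y) ** 2
    q_contrib = {snp: float(w[i] * (r[i] - full.beta) ** 2) for i, snp in enumerate(h.snp_ids)}
    crit = stats.chi2.isf(alpha / h.n_snp, 1)
    flagged = set()
    for snp, est in loo.rows.items():
        if snp == ALL_SNP_ROW:
            continue
        if abs(est.beta - full.beta) > full.se:
            flagged.add(snp)
    for snp, qc in q_contrib.items():
        if qc > crit:
            flagged.add(snp)
    return sorted(flagged)
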