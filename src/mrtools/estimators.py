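"""Causal-effect estimators on harmonized summary statistics.

All estimators are pure functions of a :class:`~mrtools.harmonize.HarmonizedSet`
with per-SNP exposure effects ``X``, outcome effects ``Y`` (log-OR for a
binary outcome) and their standard errors.  Three combiners are provided:

``ivw``
    Fixed-effect inverse-variance weighting with first-order weights
    (outcome variance only): beta = Σ X_k Y_k σ_Yk⁻² / Σ X_k² σ_Yk⁻²,
    se = sqrt(1 / Σ X_k² σ_Yk⁻²).  Equivalent to weighted least squares
    of Y on X through the origin.

``weighted_median``
    Interpolated median of the weighted empirical distribution of the
    per-SNP Wald ratios, consistent when valid instruments carry more
    than half the weight; SE via seeded parametric bootstrap.

``mr_egger``
    Weighted regression of Y on X with a free intercept; the intercept
    tests for directional pleiotropy, the slope is the adjusted causal
    estimate.  Instruments are oriented to non-negative exposure effects
    first, since the fit is not invariant to allele recoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .harmonize import HarmonizedSet

__all__ = [
    "MrEstimate",
    "EggerEstimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "weighted_median_point",
    "mr_egger",
    "to_odds_scale",
    "labelled",
]

_TINY_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate on the log-OR scale with its OR-scale interval."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    exposure: str = ""
    outcome: str = ""


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger fit: pleiotropy-adjusted slope plus intercept test."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def labelled(est: MrEstimate, exposure: str, outcome: str) -> MrEstimate:
    """Copy of an estimate carrying exposure/outcome labels for reporting."""
    return replace(est, exposure=exposure, outcome=outcome)


def wald_ratio(X: float, se_X: float, Y: float, se_Y: float, snp_id: str = "?") -> tuple[float, float]:
    """Single-SNP causal estimate ``Y/X`` with first-order SE ``se_Y/|X|``.

    The exposure-side uncertainty ``se_X`` is deliberately ignored
    (first-order approximation); it is accepted so callers can pass a
    harmonized row unchanged.
    """
    if X == 0:
        raise UndefinedRatioError(f"wald ratio undefined for {snp_id}: exposure beta is 0")
    if not se_Y > 0:
        raise ValueError(f"se_Y must be > 0, got {se_Y}")
    return Y / X, se_Y / abs(X)


def _normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def _t_p(t: float, df: int) -> float:
    return max(2.0 * stats.t.sf(abs(t), df), _TINY_P)


def to_odds_scale(
    beta: float, se: float, level: float = 0.95, df: int | None = None
) -> tuple[float, float, float]:
    """Exponentiate a log-OR and its level-(1-α) interval.

    Normal quantile by default; Student-t with ``df`` degrees of freedom
    when given (used for the MR-Egger slope).
    """
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    q = (1 + level) / 2
    crit = stats.norm.ppf(q) if df is None else stats.t.ppf(q, df)
    return math.exp(beta), math.exp(beta - crit * se), math.exp(beta + crit * se)


def _estimate(method: str, n_snp: int, beta: float, se: float, df: int | None = None) -> MrEstimate:
    p = _normal_p(beta / se) if df is None else _t_p(beta / se, df)
    or_, lo, hi = to_odds_scale(beta, se, df=df)
    return MrEstimate(method, n_snp, beta, se, p, or_, lo, hi)


def ivw(h: HarmonizedSet, overdispersion: str = "none") -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    ``beta = Σ X_k Y_k σ_Yk⁻² / Σ X_k² σ_Yk⁻²`` and
    ``se = sqrt(1 / Σ X_k² σ_Yk⁻²)`` — first-order weights, no
    over-dispersion scaling, the printed fixed-effect formulas.  Set
    ``overdispersion="multiplicative"`` for the multiplicative
    random-effects variant (SE scaled by max(1, sqrt(Q/(K-1)));
    non-default, provided for comparison only).
    """
    if h.n_snp < 1:
        raise InsufficientInstrumentsError("ivw requires K >= 1")
    w = h.se_Y**-2.0
    denom = float(np.sum(h.X**2 * w))
    if denom == 0:
        raise DegenerateDesignError("all exposure effects are zero")
    beta = float(np.sum(h.X * h.Y * w) / denom)
    se = math.sqrt(1.0 / denom)
    if overdispersion == "multiplicative" and h.n_snp > 1:
        resid = h.Y - beta * h.X
        q = float(np.sum(w * resid**2))
        se *= max(1.0, math.sqrt(q / (h.n_snp - 1)))
    elif overdispersion not in ("none", "multiplicative"):
        raise ValueError(f"unknown overdispersion mode {overdispersion!r}")
    return _estimate("ivw", h.n_snp, beta, se)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated median of a weighted empirical distribution.

    Weights are normalized to sum 1; with sorted values the cumulative
    weight of the k-th value is taken midpoint-style,
    ``s_k = Σ_{j<=k} w_j − w_k/2``, and the estimate is the linear
    interpolation of value against ``s`` at 0.5 (clamped to the extreme
    values outside the ``s`` range).
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Point estimate: weighted empirical median of the Wald ratios with
    inverse-variance weights ``w_k ∝ (X_k/σ_Yk)²``.  SE: standard
    deviation of the point estimate over ``n_boot`` resamples drawing
    ``X_k ~ N(X_k, σ_Xk)`` and ``Y_k ~ N(Y_k, σ_Yk)``.  The set is put
    in canonical snp-id order before resampling so the result is
    invariant to input permutation at a fixed seed.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median requires K >= 3, got {h.n_snp}"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    hs = h.sorted_by_snp()
    ratios = hs.Y / hs.X
    weights = (hs.X / hs.se_Y) ** 2
    beta = weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(hs.X, hs.se_X)
        yb = rng.normal(hs.Y, hs.se_Y)
        boot[b] = weighted_median_point(yb / xb, (xb / hs.se_Y) ** 2)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")
    if not se > 0:
        raise DegenerateDesignError("bootstrap produced zero spread; cannot form SE")
    return _estimate("weighted_median", h.n_snp, beta, se)


def mr_egger(h: HarmonizedSet, fit_intercept: bool = True) -> EggerEstimate:
    """MR-Egger weighted regression with over-dispersion-robust errors.

    Each SNP is first oriented so its exposure effect is non-negative
    (negating both X and Y where X < 0).  Then ``Y = a + b·X`` is fit by
    weighted least squares with weights ``σ_Yk⁻²``; both standard errors
    are scaled by ``max(1, sqrt(RSS_w/(K−2)))`` and p-values use
    t(K−2).  ``fit_intercept=False`` is an internal test mode that
    constrains ``a = 0`` (the fit then reproduces the IVW slope).
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(f"mr_egger requires K >= 3, got {h.n_snp}")
    sign = np.where(h.X < 0, -1.0, 1.0)
    x = sign * h.X
    y = sign * h.Y
    w = h.se_Y**-2.0

    if np.ptp(x) == 0:
        raise DegenerateDesignError("no variance in exposure effects after orientation")

    design = np.column_stack([np.ones_like(x), x]) if fit_intercept else x[:, None]
    wd = design * w[:, None]
    xtwx = design.T @ wd
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular weighted design") from exc
    coef = cov_unscaled @ (design.T @ (w * y))
    resid = y - design @ coef
    df = h.n_snp - design.shape[1]
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, rss_w / df) if df > 0 else 1.0
    cov = cov_unscaled * scale
    ses = np.sqrt(np.diag(cov))

    df_t = h.n_snp - 2  # reporting df fixed at K-2 regardless of test mode
    if fit_intercept:
        intercept, slope = float(coef[0]), float(coef[1])
        intercept_se, slope_se = float(ses[0]), float(ses[1])
    else:
        intercept, intercept_se = 0.0, float("nan")
        slope, slope_se = float(coef[0]), float(ses[0])

    slope_est = _estimate("mr_egger_slope", h.n_snp, slope, slope_se, df=df_t)
    intercept_p = (
        _t_p(intercept / intercept_se, df_t) if fit_intercept else 1.0
    )
    return EggerEstimate(
        slope=slope_est,
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_pvalue=intercept_p,
    )
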