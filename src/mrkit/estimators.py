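"""Causal-effect estimators for two-sample MR on summary statistics.

Given J harmonized instruments with exposure effects ``beta_exp_j`` (se
ignored at first order) and outcome effects ``beta_out_j`` (se ``se_out_j``):

* **Wald ratio** — per-SNP estimate ``beta_out/beta_exp`` with first-order
  se ``se_out/|beta_exp|``.
* **IVW, multiplicative random effects** — weighted regression of outcome on
  exposure effects through the origin with weights ``1/se_out^2``; the
  fixed-effect se is inflated by ``phi = max(1, sqrt(Q/(J-1)))`` so residual
  over-dispersion widens, and never narrows, the interval.  Cochran's Q and
  I^2 quantify heterogeneity.
* **Weighted median** — the 50% point of the cumulative distribution of
  sorted Wald ratios under weights ``(beta_exp/se_out)^2``; consistent when
  more than half of the weight comes from valid instruments.  Its se is a
  seeded parametric bootstrap.
* **MR-Egger** — the same weighted regression with a free intercept after
  orienting all instruments to non-negative exposure effects; the intercept
  estimates average directional pleiotropy and its t-test (J-2 df) is the
  pleiotropy diagnostic, while the slope is a pleiotropy-adjusted effect
  under the InSIDE assumption.

All betas are log odds ratios of the outcome per 1-log-unit increase in
exposure liability; ``to_odds_ratio`` exponentiates for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .harmonize import HarmonizedInstrument

Z_95 = 1.96  # CI half-width multiplier on the log-OR scale


@dataclass(frozen=True)
class MrEstimate:
    """A method-labelled causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, I^2 and the multiplicative over-dispersion scale."""

    q: float
    df: int
    p_q: float
    i2: float
    phi: float


@dataclass(frozen=True)
class EggerResult:
    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _normal_estimate(method: str, beta: float, se: float, n_snps: int) -> MrEstimate:
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pval=float(max(p, np.nextafter(0, 1))),
        n_snps=n_snps,
    )


def _arrays(hs: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in hs], dtype=float)
    by = np.array([h.beta_out for h in hs], dtype=float)
    sy = np.array([h.se_out for h in hs], dtype=float)
    sx = np.array([h.se_exp for h in hs], dtype=float)
    return bx, by, sy, sx


def wald_ratio(h: HarmonizedInstrument) -> MrEstimate:
    """Single-instrument ratio estimate with first-order se."""
    if h.beta_exp == 0:
        raise EstimationError(f"{h.snp_id}: zero exposure effect, Wald ratio undefined")
    beta = h.beta_out / h.beta_exp
    se = h.se_out / abs(h.beta_exp)
    return _normal_estimate("wald_ratio", beta, se, 1)


def heterogeneity(q: float, df: int) -> HeterogeneityStats:
    """Package Q into I^2 (percentage), its chi-square p, and phi."""
    q = float(q)
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    p_q = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    phi = max(1.0, math.sqrt(q / df)) if df >= 1 else 1.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2, phi=phi)


def ivw_mre(hs: Sequence[HarmonizedInstrument]) -> tuple[MrEstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate, multiplicative random effects.

    Weighted regression through the origin of beta_out on beta_exp with
    weights 1/se_out^2; se = fixed-effect se times phi = max(1, sqrt(Q/(J-1))).
    """
    if len(hs) < 2:
        raise EstimationError(f"IVW requires at least 2 instruments, got {len(hs)}")
    bx, by, sy, _ = _arrays(hs)
    if np.all(bx == 0):
        raise EstimationError("all exposure effects are zero; IVW undefined")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fe = math.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    het = heterogeneity(q, len(hs) - 1)
    est = _normal_estimate("ivw_mre", beta, se_fe * het.phi, len(hs))
    return est, het


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical distribution.

    ``theta`` may be 1-D (one estimate) or 2-D (rows = bootstrap replicates);
    weights are matched row-wise and normalized to sum 1.
    """
    theta = np.atleast_2d(theta)
    w = np.atleast_2d(w)
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    s = np.cumsum(ww, axis=1) - ww / 2.0
    out = np.empty(th.shape[0])
    for i in range(th.shape[0]):
        out[i] = np.interp(0.5, s[i], th[i])
    return out if out.size > 1 else float(out[0])


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median estimator with a seeded parametric-bootstrap se.

    Per-SNP ratios are weighted by ``(beta_exp/se_out)^2`` (the inverse
    first-order variance of each Wald ratio).  The bootstrap resamples both
    betas from normals centred at the observed values with their reported
    ses; ``seed`` must be supplied for a reproducible se.
    """
    if len(hs) < 3:
        raise EstimationError(f"weighted median requires at least 3 instruments, got {len(hs)}")
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed for its bootstrap se")
    bx, by, sy, sx = _arrays(hs)
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect among instruments; ratios undefined")
    theta = by / bx
    w = (bx / sy) ** 2
    beta = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    bxb = rng.normal(bx, sx, size=(n_boot, len(hs)))
    byb = rng.normal(by, sy, size=(n_boot, len(hs)))
    bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
    boots = _weighted_median(byb / bxb, (bxb / sy) ** 2)
    se = float(np.std(np.atleast_1d(boots), ddof=1))
    return _normal_estimate("weighted_median", beta, se, len(hs))


def mr_egger(hs: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger weighted regression with intercept (pleiotropy test).

    Instruments are first oriented so every exposure effect is non-negative
    (both betas negated together), making the result invariant to arbitrary
    per-SNP sign conventions.  Standard errors use the estimated residual
    scale of the weighted regression (no floor), so the intercept t-test
    (J-2 df) is exactly calibrated under the generating model; flooring the
    scale at 1 would make the pleiotropy diagnostic markedly conservative at
    small J.
    """
    if len(hs) < 3:
        raise EstimationError(f"MR-Egger requires at least 3 instruments, got {len(hs)}")
    bx, by, sy, _ = _arrays(hs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise EstimationError("no variation in exposure effects after orientation; Egger collinear")

    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    df = len(hs) - 2
    q = float(np.sum(w * resid**2))
    sigma2 = q / df  # estimated residual scale, unfloored: exact t inference
    cov = np.linalg.inv(xtwx) * sigma2
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))

    def t_p(coef_value: float, se: float) -> float:
        # exact-fit data has zero residual scale; a zero coefficient is then
        # indistinguishable from noise (p=1), a non-zero one is exact (p->0)
        if se == 0:
            return 1.0 if coef_value == 0 else float(np.nextafter(0, 1))
        return float(2.0 * stats.t.sf(abs(coef_value / se), df))

    p_slope = t_p(slope, se_slope)
    p_int = t_p(intercept, se_int)
    slope_est = MrEstimate(
        method="mr_egger_slope",
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - Z_95 * se_slope),
        ci_high=float(slope + Z_95 * se_slope),
        pval=max(p_slope, np.nextafter(0, 1)),
        n_snps=len(hs),
    )
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=max(p_int, np.nextafter(0, 1)),
    )


def to_odds_ratio(est: MrEstimate) -> tuple[float, tuple[float, float], float]:
    """Exponentiate a log-OR estimate: (OR, (CI low, CI high), p)."""
    return math.exp(est.beta), (math.exp(est.ci_low), math.exp(est.ci_high)), est.pval
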