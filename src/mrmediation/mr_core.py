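"""Single-exposure causal estimators and sensitivity analyses.

The main analysis is the fixed-effects inverse-variance-weighted (IVW)
pool of per-SNP Wald ratios,

    beta_IVW = sum_k X_k Y_k / sigmaY_k^2  /  sum_k X_k^2 / sigmaY_k^2
    se(beta_IVW) = ( sum_k X_k^2 / sigmaY_k^2 )^(-1/2)

where X_k is the variant-exposure effect and (Y_k, sigmaY_k) the
variant-outcome effect and SE. The sensitivity battery covers MR-Egger
(directional pleiotropy via an unconstrained intercept), simple and
weighted median (robust to <50% invalid weight), MR-RAPS (weak-instrument
robust profile score), MR-PRESSO (simulation-based outlier detection),
leave-one-out and single-SNP analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .gwas_io import InputDataError
from .harmonization import HarmonizedPair

logger = logging.getLogger("mrmediation")


class DegenerateInstrumentError(InputDataError):
    """An instrument has a zero variant-exposure effect where a ratio is needed."""


class InsufficientInstrumentsError(InputDataError):
    """Fewer SNPs than the estimator's minimum."""


class NumericalError(RuntimeError):
    """An iterative estimator failed to converge."""


class MRMethod(str, Enum):
    WALD = "wald"
    IVW = "ivw"
    EGGER = "egger"
    EGGER_INTERCEPT = "egger_intercept"
    SIMPLE_MEDIAN = "simple_median"
    WEIGHTED_MEDIAN = "weighted_median"
    RAPS = "raps"
    PRESSO_CORRECTED = "presso_corrected"
    MVMR = "mvmr"


@dataclass(frozen=True)
class MREstimate:
    """A pooled causal-effect estimate on the log/linear scale.

    ``beta`` is log-odds per exposure unit when the outcome is binary, so
    ``or_`` = exp(beta) is the odds ratio per unit increase. The CI is a
    normal approximation except where a method documents a t reference.
    """

    method: MRMethod
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    label: str = ""

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method.value, "label": self.label,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or": self.or_, "or_low": self.or_low, "or_high": self.or_high,
            "pval": self.pval, "n_snp": self.n_snp,
        }


def _normal_estimate(method, beta, se, n_snp, alpha=0.05, label="") -> MREstimate:
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate(method, float(beta), float(se),
                      float(beta - z * se), float(beta + z * se), float(p), n_snp, label)


def beta_to_or(beta: float, se: float = 0.0, alpha: float = 0.05):
    """Exponentiate a log-odds effect to an odds ratio with normal CI bounds.

    Returns ``(or, or_low, or_high)`` where the bounds are
    exp(beta ± z_{1−alpha/2}·se).
    """
    if se < 0:
        raise InputDataError("se must be non-negative")
    if not (0 < alpha < 1):
        raise InputDataError("alpha must be in (0,1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, by: float, se_y: float) -> tuple[float, float]:
    """Per-SNP causal ratio by/bx with first-order delta-method SE se_y/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError("variant-exposure effect is zero")
    if se_y <= 0:
        raise InputDataError("se_y must be positive")
    return by / bx, se_y / abs(bx)


def ivw_fixed(
    h: HarmonizedPair, alpha: float = 0.05, random_effects: bool = False,
    label: str = "",
) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate.

    Implements the closed-form pool of Wald ratios weighted by the inverse
    outcome variance; algebraically the weighted least-squares slope of by
    on bx through the origin. With ``random_effects`` the SE is inflated
    multiplicatively by the residual standard error when it exceeds 1
    (never the default here: the main analysis is fixed-effects).
    """
    if h.n_snp < 1:
        raise InsufficientInstrumentsError("IVW needs at least 1 SNP")
    w = h.se_y ** -2
    denom = np.sum(h.bx ** 2 * w)
    if denom == 0:
        raise DegenerateInstrumentError("all variant-exposure effects are zero")
    beta = np.sum(h.bx * h.by * w) / denom
    se = denom ** -0.5
    if random_effects and h.n_snp > 1:
        resid = (h.by - beta * h.bx) * np.sqrt(w)
        rse = np.sqrt(np.sum(resid ** 2) / (h.n_snp - 1))
        se *= max(1.0, rse)
    return _normal_estimate(MRMethod.IVW, beta, se, h.n_snp, alpha, label)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(h: HarmonizedPair, alpha: float = 0.05) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted regression of by on bx with intercept.

    SNPs are first oriented so every variant-exposure effect is
    non-negative (the estimate must be invariant to which allele is called
    the effect allele; Egger is not, without this convention). The slope is
    the causal estimate, the intercept the average directional pleiotropy.
    SEs use the multiplicative random-effects convention — scaled by the
    residual standard error when > 1 — and inference uses a t reference
    with K−2 degrees of freedom.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 SNPs")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by = h.bx * sign, h.by * sign
    w = h.se_y ** -2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    k = h.n_snp
    rse2 = fit.ssr / (k - 2)
    # max(1, RSE) convention on the unit-scale SEs (robust to zero residuals)
    bse = np.sqrt(np.diag(fit.normalized_cov_params)) * max(1.0, np.sqrt(rse2))
    tdist = stats.t(k - 2)

    def _est(method, b, s):
        tq = tdist.ppf(1 - alpha / 2)
        p = 2 * tdist.sf(abs(b / s))
        return MREstimate(method, float(b), float(s),
                          float(b - tq * s), float(b + tq * s), float(p), k)

    slope = _est(MRMethod.EGGER, fit.params[1], bse[1])
    intercept = _est(MRMethod.EGGER_INTERCEPT, fit.params[0], bse[0])
    return slope, intercept


# ---------------------------------------------------------------------------
# median estimators
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th percentile of the weighted empirical CDF of ratios."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cdf = np.cumsum(w) - 0.5 * w  # midpoint convention
    if 0.5 <= cdf[0]:
        return float(r[0])
    if 0.5 >= cdf[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cdf, r))


def _median_estimate(
    h: HarmonizedPair, method: MRMethod, n_boot: int, seed: int, alpha: float,
) -> MREstimate:
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("median estimators need at least 3 SNPs")
    if (h.bx == 0).any():
        raise DegenerateInstrumentError("zero variant-exposure effect in median input")
    if n_boot < 100:
        logger.warning("n_boot=%d is below 100; bootstrap SE will be unstable", n_boot)
    ratios = h.by / h.bx
    if method is MRMethod.WEIGHTED_MEDIAN:
        weights = (h.bx / h.se_y) ** 2  # inverse delta-method ratio variance
    else:
        weights = np.ones_like(ratios)
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(h.bx, h.se_x)
        by_b = rng.normal(h.by, h.se_y)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b = by_b / bx_b
        w_b = (bx_b / h.se_y) ** 2 if method is MRMethod.WEIGHTED_MEDIAN else weights
        boot[b] = _weighted_median_point(r_b, w_b)
    se = float(np.std(boot, ddof=1))
    return _normal_estimate(method, point, se, h.n_snp, alpha)


def weighted_median(
    h: HarmonizedPair, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios; consistent when less than half
    the total inverse-variance weight comes from invalid instruments. SE by
    parametric bootstrap."""
    return _median_estimate(h, MRMethod.WEIGHTED_MEDIAN, n_boot, seed, alpha)


def simple_median(
    h: HarmonizedPair, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> MREstimate:
    """Equal-weight median of per-SNP Wald ratios (50% breakdown in SNP count)."""
    return _median_estimate(h, MRMethod.SIMPLE_MEDIAN, n_boot, seed, alpha)


# ---------------------------------------------------------------------------
# MR-RAPS
# ---------------------------------------------------------------------------

def mr_raps(
    h: HarmonizedPair, overdispersion: bool = False, alpha: float = 0.05,
    max_iter: int = 100,
) -> MREstimate:
    """Robust adjusted profile score estimate, accounting for measurement
    error in the variant-exposure effects (weak-instrument robustness).

    Solves the profile score equation

        sum_k (by_k − β·bx_k)·bx_k / (se_y_k² + β²·se_x_k² + τ²) = 0

    for β (τ² = 0, or a method-of-moments overdispersion parameter when
    enabled), bracketing the root around the IVW estimate. The SE comes
    from the observed information of the profile score.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("RAPS needs at least 3 SNPs")
    if (h.se_x <= 0).any():
        raise InputDataError("RAPS requires positive exposure SEs")

    def score(beta: float, tau2: float) -> float:
        v = h.se_y ** 2 + beta ** 2 * h.se_x ** 2 + tau2
        return float(np.sum((h.by - beta * h.bx) * h.bx / v))

    def solve_beta(tau2: float) -> float:
        center = ivw_fixed(h).beta
        half = max(1.0, 10 * abs(center))
        lo, hi = center - half, center + half
        for _ in range(60):
            if score(lo, tau2) * score(hi, tau2) < 0:
                break
            lo, hi = center - 2 * (center - lo), center + 2 * (hi - center)
        else:
            raise NumericalError(
                f"RAPS: no sign change in [{lo:.3g},{hi:.3g}]; "
                f"score({lo:.3g})={score(lo, tau2):.3g}"
            )
        return optimize.brentq(score, lo, hi, args=(tau2,), xtol=1e-12)

    tau2 = 0.0
    beta = solve_beta(tau2)
    if overdispersion:
        for _ in range(max_iter):
            v = h.se_y ** 2 + beta ** 2 * h.se_x ** 2
            resid2 = (h.by - beta * h.bx) ** 2
            tau2_new = max(0.0, float(np.mean(resid2 - v)))
            beta_new = solve_beta(tau2_new)
            if abs(beta_new - beta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
                beta, tau2 = beta_new, tau2_new
                break
            beta, tau2 = beta_new, tau2_new
        else:
            raise NumericalError("RAPS overdispersion iteration did not converge")
    v = h.se_y ** 2 + beta ** 2 * h.se_x ** 2 + tau2
    info = float(np.sum(h.bx ** 2 / v))
    se = info ** -0.5
    return _normal_estimate(MRMethod.RAPS, beta, se, h.n_snp, alpha)


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO global and outlier tests."""

    global_rss: float
    global_pval: float
    outlier_flags: np.ndarray
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, capped at 1
    corrected: MREstimate | None = None
    variant_ids: list[str] = field(default_factory=list)

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn, vectorized over SNPs.

    ``by`` may be 2-D (n_sim, K) to evaluate many simulated datasets at once.
    """
    by = np.atleast_2d(by)
    sxx = np.sum(bx ** 2 * w)
    sxy = (bx * w * by).sum(axis=-1, keepdims=True)
    num = sxy - bx * w * by
    den = sxx - bx ** 2 * w
    return num / den


def mr_presso(
    h: HarmonizedPair, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares test for horizontal pleiotropy.

    Global test: each SNP's outcome effect is predicted from the IVW fit of
    the remaining SNPs; the observed RSS of these leave-one-out residuals is
    compared against its null distribution from ``n_sim`` parametric
    simulations (by* ~ N(beta_loo·bx, se_y), bx* ~ N(bx, se_x)). Outlier
    test: each SNP's observed squared residual against its simulated
    distribution, Bonferroni-corrected across SNPs at ``alpha``. When
    outliers are flagged the IVW estimate is recomputed without them.
    """
    if h.n_snp < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 SNPs")
    if n_sim < 1000:
        logger.warning("MR-PRESSO n_sim=%d < 1000; p-values will be coarse", n_sim)
    rng = np.random.default_rng(seed)
    k = h.n_snp
    w = h.se_y ** -2

    beta_loo = _loo_betas(h.bx, h.by, w)[0]
    obs_resid2 = (h.by - beta_loo * h.bx) ** 2
    global_rss = float(obs_resid2.sum())

    bx_sim = rng.normal(h.bx, h.se_x, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * h.bx, h.se_y, size=(n_sim, k))
    # leave-one-out IVW slopes per simulated dataset, vectorized over sims
    sxx_sim = np.sum(bx_sim ** 2 * w, axis=1, keepdims=True)
    sxy_sim = np.sum(bx_sim * w * by_sim, axis=1, keepdims=True)
    beta_loo_sim = (sxy_sim - bx_sim * w * by_sim) / (sxx_sim - bx_sim ** 2 * w)
    sim_resid2 = (by_sim - beta_loo_sim * bx_sim) ** 2
    sim_rss = sim_resid2.sum(axis=1)

    global_pval = float((np.sum(sim_rss >= global_rss) + 1) / (n_sim + 1))
    outlier_pvals_raw = (np.sum(sim_resid2 >= obs_resid2, axis=0) + 1) / (n_sim + 1)
    outlier_pvals = np.minimum(outlier_pvals_raw * k, 1.0)
    flags = outlier_pvals < alpha

    corrected = None
    if flags.any():
        if (~flags).sum() < 2:
            raise InputDataError("MR-PRESSO flagged all but <2 SNPs; no corrected estimate")
        keep = ~flags
        h_kept = HarmonizedPair(
            [v for v, kf in zip(h.variant_ids, keep) if kf],
            h.bx[keep], h.se_x[keep], h.by[keep], h.se_y[keep],
        )
        corrected = replace(
            ivw_fixed(h_kept), method=MRMethod.PRESSO_CORRECTED
        )
    return PressoResult(global_rss, global_pval, flags, outlier_pvals,
                        corrected, list(h.variant_ids))


# ---------------------------------------------------------------------------
# per-SNP batteries
# ---------------------------------------------------------------------------

def leave_one_out(h: HarmonizedPair, alpha: float = 0.05) -> list[MREstimate]:
    """IVW estimate with each instrument omitted in turn, labeled by the
    omitted variant."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs at least 2 SNPs")
    return [
        replace(ivw_fixed(h.drop(v), alpha=alpha), label=v)
        for v in h.variant_ids
    ]


def single_snp(h: HarmonizedPair, alpha: float = 0.05) -> list[MREstimate]:
    """Per-instrument Wald-ratio estimates, labeled by variant."""
    out = []
    for v, bx, by, se_y in zip(h.variant_ids, h.bx, h.by, h.se_y):
        r, r_se = wald_ratio(bx, by, se_y)
        out.append(_normal_estimate(MRMethod.WALD, r, r_se, 1, alpha, label=v))
    return out


def estimates_to_frame(estimates: Sequence[MREstimate]):
    """Tidy DataFrame of estimates (one row per analysis/method)."""
    import pandas as pd

    return pd.DataFrame([e.to_dict() for e in estimates])
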