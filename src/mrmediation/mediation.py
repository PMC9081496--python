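"""Two-step MR mediation: multivariable adjustment, products of
coefficients, and mediation proportions.

Step 1 estimates the exposure→mediator effect by fixed-effects IVW over
the exposure's instruments. Step 2 estimates the mediator→outcome effect
adjusted for the exposure by regression-based multivariable MR: a weighted
regression of the variant-outcome effects on the variant-exposure and
variant-mediator effects jointly, without intercept. The indirect effect
through a mediator is the product of the two step estimates, and the
proportion mediated is that product divided by the total exposure→outcome
effect (in percent). Mediators are screened by a p-value gate at each step
and optionally by a minimum absolute proportion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gwas_io import InputDataError
from .harmonization import HarmonizedTriple
from .mr_core import InsufficientInstrumentsError, MREstimate, MRMethod

logger = logging.getLogger("mrmediation")


class CollinearityError(InputDataError):
    """Exposure and mediator instrument effects are (near-)collinear."""


class UndefinedProportionError(ZeroDivisionError):
    """Proportion mediated is undefined for a zero total effect."""


def mvmr_adjusted_effect(
    t: HarmonizedTriple, alpha: float = 0.05, cond_limit: float = 1e8,
) -> tuple[MREstimate, MREstimate]:
    """Two-exposure multivariable MR by weighted regression.

    Regresses ``by`` on ``(bx, bm)`` without intercept, weighted by the
    inverse outcome variance. The ``bm`` coefficient is the mediator→outcome
    effect adjusted for the exposure; the ``bx`` coefficient is the direct
    exposure effect. SEs follow the multiplicative random-effects
    convention (scaled by the residual standard error when it exceeds 1),
    with normal inference.

    Returns ``(direct_exposure_effect, adjusted_mediator_effect)``.
    """
    k = t.n_snp
    if k < 3:
        raise InsufficientInstrumentsError(
            "multivariable MR needs at least 3 instruments for 2 exposures"
        )
    X = np.column_stack([t.bx, t.bm])
    w = t.se_y ** -2
    Xw = X * np.sqrt(w)[:, None]
    cond = np.linalg.cond(Xw)
    if not np.isfinite(cond) or cond > cond_limit:
        raise CollinearityError(
            f"exposure and mediator effects are collinear (condition number {cond:.3g})"
        )
    fit = sm.WLS(t.by, X, weights=w).fit()
    rse2 = fit.ssr / (k - 2)
    bse = np.sqrt(np.diag(fit.normalized_cov_params)) * max(1.0, np.sqrt(rse2))
    z = stats.norm.ppf(1 - alpha / 2)

    def _est(b, s, label):
        p = 2 * stats.norm.sf(abs(b / s))
        return MREstimate(MRMethod.MVMR, float(b), float(s),
                          float(b - z * s), float(b + z * s), float(p), k, label)

    direct = _est(fit.params[0], bse[0], "exposure_direct")
    adjusted = _est(fit.params[1], bse[1], "mediator_adjusted")
    return direct, adjusted


def indirect_effect(step1_beta: float, step2_beta: float) -> float:
    """Product-of-coefficients indirect effect a·b."""
    if not (np.isfinite(step1_beta) and np.isfinite(step2_beta)):
        raise InputDataError("step betas must be finite")
    return float(step1_beta * step2_beta)


def proportion_mediated(indirect_beta: float, total_beta: float) -> float:
    """Indirect effect as a percentage of the total effect.

    Full precision is returned; summaries round to 1 decimal place. Values
    outside [0, 100] (inconsistent mediation) are legitimate and reported
    signed, with a warning, never clamped.
    """
    if total_beta == 0:
        raise UndefinedProportionError("total effect is zero")
    prop = 100.0 * indirect_beta / total_beta
    if not (0.0 <= prop <= 100.0):
        logger.warning("proportion mediated %.1f%% outside [0, 100]%%", prop)
    return float(prop)


@dataclass
class MediatorResult:
    """One mediator's step estimates, indirect effect and screening outcome."""

    mediator_label: str
    step1: MREstimate              # exposure -> mediator (IVW over exposure instruments)
    step2: MREstimate              # mediator -> outcome, adjusted for exposure (MVMR)
    indirect_beta: float
    proportion: float              # percent of total effect
    included: bool
    exclusion_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator_label,
            "step1_beta": self.step1.beta, "step1_se": self.step1.se,
            "step1_pval": self.step1.pval,
            "step2_beta": self.step2.beta, "step2_se": self.step2.se,
            "step2_pval": self.step2.pval,
            "indirect_beta": self.indirect_beta,
            "proportion_pct": self.proportion,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
        }


@dataclass
class MediationDecomposition:
    """Total effect, per-mediator indirect effects, and combined proportion.

    ``combined_indirect`` is the exact sum of the included mediators'
    indirect effects and ``combined_proportion`` that sum over the total
    effect, in percent (the transparent sum rule).
    """

    total_effect: MREstimate
    mediators: list[MediatorResult] = field(default_factory=list)

    @property
    def included(self) -> list[MediatorResult]:
        return [m for m in self.mediators if m.included]

    @property
    def combined_indirect(self) -> float:
        return float(sum(m.indirect_beta for m in self.included))

    @property
    def combined_proportion(self) -> float:
        if not self.included:
            return 0.0
        return proportion_mediated(self.combined_indirect, self.total_effect.beta)

    def report_frame(self) -> pd.DataFrame:
        """Mediation table: one row per mediator plus total-effect and
        combined rows (betas and proportions, the published-table layout)."""
        rows = [{
            "mediator": "(total effect)", "indirect_beta": self.total_effect.beta,
            "proportion_pct": 100.0, "included": True, "exclusion_reason": None,
            "step1_beta": np.nan, "step1_se": np.nan, "step1_pval": np.nan,
            "step2_beta": np.nan, "step2_se": np.nan, "step2_pval": np.nan,
        }]
        rows += [m.to_dict() for m in self.mediators]
        rows.append({
            "mediator": "(combined)", "indirect_beta": self.combined_indirect,
            "proportion_pct": self.combined_proportion,
            "included": bool(self.included), "exclusion_reason": None,
            "step1_beta": np.nan, "step1_se": np.nan, "step1_pval": np.nan,
            "step2_beta": np.nan, "step2_se": np.nan, "step2_pval": np.nan,
        })
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_effect": self.total_effect.to_dict(),
            "mediators": [m.to_dict() for m in self.mediators],
            "combined_indirect": self.combined_indirect,
            "combined_proportion_pct": self.combined_proportion,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def combined_mediation(decomp: MediationDecomposition) -> float:
    """Combined proportion mediated, percent: Σ included indirect / total × 100."""
    if not decomp.included:
        raise InputDataError("no mediators included in decomposition")
    return decomp.combined_proportion


def screen_mediators(
    results: list[MediatorResult],
    p_gate: float = 0.05,
    min_proportion: float = 0.0,
) -> list[MediatorResult]:
    """Apply the two p-value gates and the optional proportion floor.

    A mediator is retained iff step-1 p < ``p_gate`` (the exposure affects
    it), step-2 p < ``p_gate`` (it affects the outcome given the exposure),
    and |proportion| ≥ ``min_proportion`` percent. Exclusions are logged
    with the triggering rule and recorded on the result.
    """
    if not (0 < p_gate < 1):
        raise InputDataError(f"p_gate must be in (0,1), got {p_gate}")
    screened = []
    for m in results:
        reason = None
        if not (m.step1.pval < p_gate):
            reason = f"step1 p={m.step1.pval:.3g} >= gate {p_gate}"
        elif not (m.step2.pval < p_gate):
            reason = f"step2 p={m.step2.pval:.3g} >= gate {p_gate}"
        elif abs(m.proportion) < min_proportion:
            reason = (
                f"|proportion| {abs(m.proportion):.2f}% < floor {min_proportion}%"
            )
        if reason:
            logger.info("mediator %s excluded: %s", m.mediator_label, reason)
        screened.append(replace(m, included=reason is None, exclusion_reason=reason))
    return screened
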