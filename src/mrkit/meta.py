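"""Cross-source fixed-effects meta-analysis and multiple-testing labels.

Each cardiovascular outcome is measured in up to two independent sources
(a dedicated consortium GWAS and FinnGen); per-source IVW estimates are
pooled with inverse-variance fixed-effect weights.  Significance follows a
Bonferroni rule over the number of outcomes tested: with alpha = 0.05 over
8 outcomes, p < 0.00625 is significant and 0.00625 <= p < 0.05 suggestive.
Classification compares against the exact quotient, never its rounded
presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import EstimationError
from .estimators import MrEstimate, Z_95

DEFAULT_ALPHA = 0.05
DEFAULT_N_OUTCOMES = 8


@dataclass(frozen=True)
class MetaResult:
    outcome: str
    inputs: tuple[MrEstimate, ...]
    beta: float
    se: float
    pval: float
    significance: str


def fixed_effect_meta(
    estimates: Sequence[MrEstimate],
    outcome: str = "",
    alpha: float = DEFAULT_ALPHA,
    n_outcomes: int = DEFAULT_N_OUTCOMES,
) -> MetaResult:
    """Pool per-source estimates with weights 1/se^2.

    A single input is returned unchanged (up to classification).  Pooling
    never widens: the pooled se is at most the smallest input se.
    """
    if not estimates:
        raise EstimationError("fixed_effect_meta requires at least one estimate")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise EstimationError(f"cannot pool estimates from different methods: {sorted(methods)}")
    wsum = sum(1.0 / e.se**2 for e in estimates)
    beta = sum(e.beta / e.se**2 for e in estimates) / wsum
    se = math.sqrt(1.0 / wsum)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MetaResult(
        outcome=outcome,
        inputs=tuple(estimates),
        beta=float(beta),
        se=float(se),
        pval=max(p, 5e-324),
        significance=classify_significance(p, n_outcomes=n_outcomes, alpha=alpha),
    )


def classify_significance(
    pval: float,
    n_outcomes: int = DEFAULT_N_OUTCOMES,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Bonferroni classification: significant / suggestive / null.

    Significant iff p < alpha/n_outcomes (exact quotient); suggestive iff
    alpha/n_outcomes <= p < alpha; null otherwise.
    """
    threshold = alpha / n_outcomes
    if pval < threshold:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


def meta_ci(result: MetaResult) -> tuple[float, float]:
    """Symmetric normal 95% CI on the log-OR scale."""
    return result.beta - Z_95 * result.se, result.beta + Z_95 * result.se
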