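"""Inverse-variance random-effects meta-analysis (DerSimonian-Laird).

Pools log odds ratios across studies with inverse-variance weights, using
the DerSimonian-Laird moment estimator for the between-study variance tau².
Heterogeneity is summarised by Cochran's Q, its chi-square p-value, and the
I² index.  All pooling happens on the log-OR scale; confidence intervals
are back-transformed by exponentiation with z = 1.959964.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z95 = 1.959964


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    pooled_log_or: float
    pooled_se: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    weights: tuple[float, ...]

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.pooled_log_or - Z95 * self.pooled_se),
            math.exp(self.pooled_log_or + Z95 * self.pooled_se),
        )

    @property
    def p_pooled(self) -> float:
        if self.pooled_se == 0:
            return 0.0 if self.pooled_log_or != 0 else 1.0
        z = self.pooled_log_or / self.pooled_se
        return float(2 * stats.norm.sf(abs(z)))


def or_ci_to_effect(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Invert an ``OR (95% CI)`` presentation to (log_or, se).

    The standard error is recovered from the Wald interval width:
    ``se = (ln hi - ln lo) / (2 * 1.959964)``.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError(
            f"need 0 < low <= point <= high on the OR scale, got "
            f"({or_point}, {ci_low}, {ci_high})"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    if se == 0:
        warnings.warn("degenerate CI: zero-width interval gives se = 0", stacklevel=2)
    return math.log(or_point), se


def cochran_q(effects: Sequence[tuple[float, float]]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q, its df, and the chi-square p-value.

    ``effects`` is a sequence of (log_or, se) pairs, one per study.
    Q is the inverse-variance weighted sum of squared deviations from the
    fixed-effect mean; under homogeneity Q ~ chi²(k-1).
    """
    if len(effects) < 2:
        raise ValueError("Cochran Q needs at least two studies")
    theta = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    fe_mean = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - fe_mean) ** 2))
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def i_squared(q: float, df: int) -> float:
    """I² heterogeneity index in percent: ``max(0, (Q - df)/Q) * 100``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def dersimonian_laird(effects: Sequence[tuple[float, float]]) -> MetaResult:
    """Random-effects pooling of (log_or, se) pairs.

    tau² is the DerSimonian-Laird moment estimate
    ``max(0, (Q - df) / (Σw - Σw²/Σw))`` with fixed-effect weights
    ``w = 1/se²``; the pooled mean uses random-effects weights
    ``w* = 1/(se² + tau²)``.  With a single study the input is returned
    unchanged (Q = 0, df = 0).  When tau² = 0 the result coincides with
    the fixed-effect inverse-variance pooled estimate.
    """
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    if len(effects) == 1:
        log_or, se = effects[0]
        if se <= 0:
            raise ValueError("standard error must be positive")
        return MetaResult(log_or, se, 0.0, 0, 1.0, 0.0, 0.0, (1.0,))

    q, df, p_q = cochran_q(effects)
    se = np.array([e[1] for e in effects], dtype=float)
    theta = np.array([e[0] for e in effects], dtype=float)
    w = 1.0 / se**2
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        q=q,
        df=df,
        p_q=p_q,
        i2=i_squared(q, df),
        tau2=tau2,
        weights=tuple(float(x) for x in w_star),
    )


def pool_published(rows: Sequence[tuple[float, float, float]]) -> MetaResult:
    """Pool printed ``(OR, ci_low, ci_high)`` rows directly."""
    return dersimonian_laird([or_ci_to_effect(*r) for r in rows])
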