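"""Model discrimination: ROC AUC, paired AUC contrasts, and the risk-model suite.

The AUC is the Mann-Whitney two-sample statistic (probability that a random
case's score exceeds a random control's, ties half-credited).  Paired
contrasts between models fitted on the same individuals use DeLong's
non-parametric covariance of placement values, the standard method behind
"ROC contrast" output in commercial packages.

The suite fits the five nested/overlapping logistic risk models compared in
the analysis: (1) the single index SNP, (2) the PRS alone, (3) sex and age,
(4) sex, age and pigmentation, (5) sex, age, pigmentation and PRS — all on
the identical complete-case subset so every contrast is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fit_logistic, _covariate_design
from .panel import SnpPanel
from .prs import PrsResult

Z95 = 1.959964

MODEL_NAMES = ("single_snp", "prs_only", "sex_age", "sex_age_pigment", "sex_age_pigment_prs")


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC; requires both classes present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both cases and controls to compute an AUC")
    ranks = stats.rankdata(s)  # midranks handle ties with half credit
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.r_[pos, neg])
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-case placement
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-control placement
    return v10, v01, float(auc)


def auc_with_ci(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong-variance Wald 95% CI, truncated to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    v10, v01, auc = _placements(s, y)
    var = _delong_cov(np.c_[v10], np.c_[v01])[0, 0]
    half = Z95 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _delong_cov(v10: np.ndarray, v01: np.ndarray) -> np.ndarray:
    """Covariance of AUC estimates from stacked placement columns."""
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10, rowvar=False, ddof=1).reshape(v10.shape[1], v10.shape[1])
    s01 = np.cov(v01, rowvar=False, ddof=1).reshape(v01.shape[1], v01.shape[1])
    return s10 / m + s01 / n


def auc_contrast(scores_a, scores_b, labels) -> dict:
    """Paired AUC difference (b minus a) with DeLong variance, CI, and p.

    Both score vectors must refer to the same individuals in the same order.
    Identical score vectors give a zero difference with p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired contrast needs equal-length score and label vectors")
    va10, va01, auc_a = _placements(a, y)
    vb10, vb01, auc_b = _placements(b, y)
    cov = _delong_cov(np.c_[va10, vb10], np.c_[va01, vb01])
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    delta = auc_b - auc_a
    if var_diff <= 0:
        p = 1.0 if delta == 0 else 0.0
        half = 0.0
    else:
        z = delta / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
        half = Z95 * np.sqrt(var_diff)
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delta_auc": delta,
        "ci95": (delta - half, delta + half),
        "p": p,
    }


@dataclass
class RiskModelSuite:
    """Fitted probabilities and AUCs for the five risk models, paired."""

    probabilities: pd.DataFrame  # one column per model, complete-case index
    outcome: pd.Series
    auc: dict[str, float] = field(default_factory=dict)
    auc_ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def contrast(self, model_a: str, model_b: str) -> dict:
        """Paired DeLong contrast of ``model_b`` minus ``model_a``."""
        return auc_contrast(
            self.probabilities[model_a], self.probabilities[model_b], self.outcome
        )


def build_model_suite(
    cohort: pd.DataFrame,
    prs_result: PrsResult,
    panel: SnpPanel,
    index_snp: str = "rs12913832",
    scheme: str = "mdacc",
) -> RiskModelSuite:
    """Fit the five risk models on the shared complete-case subset.

    Requires the full pigmentation covariate scheme (sex, age, skin, eye,
    hair, tanning); raises ``ValueError`` naming the missing covariate
    otherwise, so models 4/5 are never silently dropped.
    """
    if index_snp not in cohort.columns:
        raise KeyError(f"index SNP {index_snp} not in cohort")
    design_cov = _covariate_design(cohort, scheme)
    frame = pd.concat(
        [
            cohort[["case", index_snp]],
            prs_result.weighted_score.rename("prs"),
            design_cov,
        ],
        axis=1,
    ).dropna()
    y = frame["case"]
    const = pd.DataFrame({"const": 1.0}, index=frame.index)
    sex_age_cols = [c for c in design_cov.columns if c == "age" or c.startswith("sex")]
    pigment_cols = [
        c
        for c in design_cov.columns
        if c.startswith(("skin_color", "eye_color", "hair_color", "tanning"))
    ]
    designs = {
        "single_snp": pd.concat([const, frame[[index_snp]]], axis=1),
        "prs_only": pd.concat([const, frame[["prs"]]], axis=1),
        "sex_age": pd.concat([const, frame[sex_age_cols]], axis=1),
        "sex_age_pigment": pd.concat([const, frame[sex_age_cols + pigment_cols]], axis=1),
        "sex_age_pigment_prs": pd.concat(
            [const, frame[sex_age_cols + pigment_cols + ["prs"]]], axis=1
        ),
    }
    probs = {}
    for name, X in designs.items():
        _, res = fit_logistic(y, X, model_spec=f"suite:{name}")
        probs[name] = pd.Series(res.predict(X.astype(float)), index=frame.index)
    prob_df = pd.DataFrame(probs)
    suite = RiskModelSuite(probabilities=prob_df, outcome=y)
    for name in MODEL_NAMES:
        auc, ci = auc_with_ci(prob_df[name], y)
        suite.auc[name] = auc
        suite.auc_ci[name] = ci
    return suite


def roc_coordinates(scores, labels) -> pd.DataFrame:
    """FPR/TPR pairs across all thresholds (for external plotting)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # collapse tied thresholds to their last index
    distinct = np.r_[np.where(np.diff(s[order]))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / y.sum()]
    fpr = np.r_[0.0, fps[distinct] / (len(y) - y.sum())]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
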