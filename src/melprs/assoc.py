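"""Logistic association models: per-SNP, PRS, and covariate adjustment.

Per-SNP models are additive in dosage and unadjusted; PRS models come in
four forms (continuous per-unit score, top-vs-bottom tertile, allele-count
band, 95th-percentile split) with optional study-scheme covariate
adjustment.  Estimation is maximum-likelihood logistic regression
(statsmodels); effects are reported as odds ratios with Wald 95% intervals
and two-sided Wald p-values, the presentation the meta-analysis layer
inverts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import SnpPanel
from .prs import PrsResult
from .synth import SCHEME_COVARIATES

Z95 = 1.959964

PRS_FORMS = ("continuous", "tertile31", "band", "top5pct")


class SeparationError(RuntimeError):
    """Raised when the logistic MLE does not exist or did not converge."""


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect with Wald interval, p-value and provenance."""

    label: str
    log_or: float
    se: float
    n_used: int
    model_spec: str = ""

    @property
    def or_point(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.log_or - Z95 * self.se),
            math.exp(self.log_or + Z95 * self.se),
        )

    @property
    def p(self) -> float:
        if self.se == 0:
            return 1.0 if self.log_or == 0 else 0.0
        return float(2 * stats.norm.sf(abs(self.log_or / self.se)))

    def as_effect(self) -> tuple[float, float]:
        """(log_or, se) pair for meta-analysis."""
        return self.log_or, self.se


def fit_logistic(outcome, design_matrix: pd.DataFrame, model_spec: str = ""):
    """ML logistic fit; returns (per-coefficient EffectEstimates, result).

    ``design_matrix`` must already contain the intercept column if one is
    wanted.  Separation or non-convergence raises :class:`SeparationError`
    rather than returning a silent result.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    X = design_matrix.astype(float)
    try:
        with warnings.catch_warnings():
            # convergence is verified explicitly below and surfaced as an error
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("non-finite standard errors: possible separation")
    estimates = {
        name: EffectEstimate(
            label=name,
            log_or=float(res.params[name]),
            se=float(res.bse[name]),
            n_used=int(len(y)),
            model_spec=model_spec,
        )
        for name in X.columns
    }
    return estimates, res


def single_snp_association(
    cohort: pd.DataFrame, snp_id: str, panel: SnpPanel | None = None
) -> EffectEstimate:
    """Unadjusted additive per-allele model: ``case ~ dosage``."""
    if panel is not None and snp_id not in panel:
        raise KeyError(f"{snp_id} not in panel")
    if snp_id not in cohort.columns:
        raise KeyError(f"{snp_id} not in cohort table")
    sub = cohort[["case", snp_id]].dropna()
    dose = sub[snp_id].astype(float)
    if dose.nunique() < 2:
        raise SeparationError(f"{snp_id} is monomorphic in this cohort")
    X = pd.DataFrame({"const": 1.0, snp_id: dose})
    spec = f"case ~ {snp_id} (additive, unadjusted)"
    est, _ = fit_logistic(sub["case"], X, model_spec=spec)
    return est[snp_id]


def _covariate_design(cohort: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Adjustment columns for a scheme: age linear, categoricals as indicators."""
    cols = {}
    for cov in SCHEME_COVARIATES[scheme]:
        if cov not in cohort.columns or cohort[cov].isna().all():
            raise ValueError(
                f"covariate {cov!r} required by scheme {scheme!r} is unavailable "
                "in this cohort"
            )
        s = cohort[cov]
        if cov == "age":
            cols["age"] = s.astype(float)
        elif cov in ("family_history",):
            cols["family_history"] = s.astype(float)
        elif cov == "sex":
            vals = s.astype(str)
            if vals.nunique() > 1:
                cols["sex_male"] = (vals == "male").astype(float)
        else:  # ordinal pigmentation traits entered as category indicators
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
    return pd.DataFrame(cols, index=cohort.index)


def prs_association(
    cohort: pd.DataFrame,
    prs_result: PrsResult,
    form: str = "continuous",
    adjust: bool = False,
    scheme: str | None = None,
) -> EffectEstimate:
    """PRS-melanoma association in one of the reporting forms.

    * ``continuous`` — per-unit-PRS odds ratio;
    * ``tertile31`` — top vs bottom tertile (middle tertile kept in the fit
      via indicator coding, only the T3-vs-T1 contrast reported);
    * ``band`` — >=15 vs <=6 total risk alleles (middle band retained);
    * ``top5pct`` — above vs below the 95th percentile of the score.

    With ``adjust=True`` the study scheme's covariates are entered exactly
    (mdacc: sex, age, skin, eye, hair, tanning; nhs: age, hair, tanning,
    family history; hpfs: age, eye, hair, family history).
    """
    if form not in PRS_FORMS:
        raise ValueError(f"unknown PRS form {form!r}; options: {PRS_FORMS}")
    scheme = scheme or str(cohort["study"].iloc[0])

    if form == "continuous":
        pred = pd.DataFrame({"prs": prs_result.weighted_score})
        report = "prs"
    elif form == "tertile31":
        t = prs_result.tertile.astype(str)
        pred = pd.DataFrame(
            {"prs_T2": (t == "T2").astype(float), "prs_T3": (t == "T3").astype(float)}
        )
        pred[t == "nan"] = np.nan
        report = "prs_T3"
    elif form == "band":
        b = prs_result.allele_band.astype(str)
        pred = pd.DataFrame(
            {"band_mid": (b == "7-14").astype(float), "band_high": (b == ">=15").astype(float)}
        )
        pred[b == "nan"] = np.nan
        report = "band_high"
    else:
        pred = pd.DataFrame({"top5pct": prs_result.top5pct.astype(float)})
        report = "top5pct"

    pred.index = cohort.index
    parts = [pd.DataFrame({"const": 1.0}, index=cohort.index), pred]
    adj_desc = "unadjusted"
    if adjust:
        parts.append(_covariate_design(cohort, scheme))
        adj_desc = f"adjusted ({scheme} scheme)"
    X = pd.concat(parts, axis=1)
    keep = X.notna().all(axis=1) & cohort["case"].notna()
    spec = f"case ~ PRS[{form}] {adj_desc}"
    est, _ = fit_logistic(cohort.loc[keep, "case"], X.loc[keep], model_spec=spec)
    return est[report]


def variance_explained(prs_scores: pd.Series, ordinal_trait: pd.Series) -> float:
    """Squared Pearson correlation between the score and an ordinal trait coding.

    Categorical traits must be passed already coded to their ordinal levels
    (1..k, fairest first, matching the study questionnaires).
    """
    df = pd.DataFrame({"s": prs_scores.astype(float), "t": pd.to_numeric(ordinal_trait)}).dropna()
    if df["t"].nunique() < 2:
        raise ValueError("trait is constant: variance explained undefined")
    r = np.corrcoef(df["s"], df["t"])[0, 1]
    return float(r**2)


def ordinal_code(trait: pd.Series, levels: tuple[str, ...]) -> pd.Series:
    """Map a categorical trait to 1..k following the given level order."""
    mapping = {lev: i + 1 for i, lev in enumerate(levels)}
    return trait.astype(str).map(mapping).astype("Float64")
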