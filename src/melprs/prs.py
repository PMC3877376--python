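"""Risk-allele counting, weighted polygenic risk score, and groupings.

The weighted PRS of individual *i* is the inner product of their risk-allele
dosages with the panel's log-odds weights, ``score_i = Σ_j w_j g_ij``.
Groupings reproduce the study's reporting conventions: tertiles of the score
within a reference sample, total-allele-count bands (<=6 / 7-14 / >=15), and
a split at the 95th percentile of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SnpPanel

ALLELE_BANDS = ("<=6", "7-14", ">=15")
TERTILES = ("T1", "T2", "T3")


@dataclass
class PrsResult:
    """Per-individual scores and group labels, aligned to the input index."""

    total_risk_alleles: pd.Series  # integer count over non-missing SNPs
    weighted_score: pd.Series
    n_missing_snps: pd.Series
    tertile: pd.Series  # categorical T1/T2/T3
    allele_band: pd.Series  # categorical <=6 / 7-14 / >=15
    top5pct: pd.Series  # 0/1 indicator
    missing_policy: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total_risk_alleles": self.total_risk_alleles,
                "weighted_score": self.weighted_score,
                "n_missing_snps": self.n_missing_snps,
                "tertile": self.tertile,
                "allele_band": self.allele_band,
                "top5pct": self.top5pct,
            }
        )


def _dosage_frame(dosages: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    missing = [s for s in panel.snp_ids if s not in dosages.columns]
    if missing:
        raise KeyError(f"dosage table lacks panel SNPs: {missing}")
    d = dosages[panel.snp_ids].astype(float)
    vals = d.to_numpy()
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage outside {{0,1,2}} at individual {d.index[i]!r}, SNP {d.columns[j]!r}: "
            f"{vals[i, j]}"
        )
    return d


def count_risk_alleles(dosages: pd.DataFrame, panel: SnpPanel) -> pd.Series:
    """Total risk alleles per individual, summed over non-missing SNPs."""
    d = _dosage_frame(dosages, panel)
    return d.sum(axis=1, skipna=True).astype(int)


def weighted_prs(
    dosages: pd.DataFrame, panel: SnpPanel, missing_policy: str = "mean"
) -> tuple[pd.Series, pd.Series]:
    """Weighted score per individual and the count of missing SNPs.

    missing_policy:
      * ``"mean"`` — missing dosages imputed by the panel expectation
        ``2 * risk_allele_freq`` before the inner product;
      * ``"drop"`` — individuals with any missing SNP get a NaN score
        (flagged, to be excluded from model fits downstream).

    An individual missing every SNP is always NaN, never silently zero.
    """
    if missing_policy not in {"mean", "drop"}:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    d = _dosage_frame(dosages, panel)
    n_missing = d.isna().sum(axis=1)
    w = np.asarray(panel.weights, dtype=float)
    if missing_policy == "mean":
        fill = 2.0 * np.asarray(panel.freqs, dtype=float)
        filled = d.fillna(pd.Series(fill, index=d.columns))
        score = pd.Series(filled.to_numpy() @ w, index=d.index, name="weighted_score")
        score[n_missing == len(panel)] = np.nan
    else:
        score = pd.Series(d.to_numpy() @ w, index=d.index, name="weighted_score")
        # matrix product with NaN propagates: any missing SNP -> NaN score
    return score, n_missing


def tertile_cutpoints(reference_scores: pd.Series | np.ndarray) -> tuple[float, float]:
    """1/3 and 2/3 quantiles (linear interpolation between order statistics)."""
    ref = np.asarray(reference_scores, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("empty reference sample")
    if np.min(ref) == np.max(ref):
        raise ValueError("constant reference scores: tertiles are degenerate")
    q1, q2 = np.quantile(ref, [1 / 3, 2 / 3], method="linear")
    return float(q1), float(q2)


def categorize_tertiles(
    scores: pd.Series, reference_scores: pd.Series | np.ndarray | None = None
) -> pd.Series:
    """T1/T2/T3 labels; cutpoints from ``reference_scores`` (default: scores).

    A score <= the lower cutpoint is T1, <= the upper cutpoint T2, else T3;
    scores outside the reference range fall in the outer tertiles.
    """
    if reference_scores is None:
        reference_scores = scores
    q1, q2 = tertile_cutpoints(reference_scores)
    s = scores.astype(float)
    labels = np.where(s <= q1, "T1", np.where(s <= q2, "T2", "T3"))
    out = pd.Series(labels, index=scores.index, name="tertile")
    out[s.isna()] = np.nan
    return pd.Series(pd.Categorical(out, categories=list(TERTILES)), index=scores.index, name="tertile")


def band_by_allele_count(counts: pd.Series, low: int = 6, high: int = 15) -> pd.Series:
    """Band total allele counts: <=low, middle, >=high."""
    c = counts.astype(float)
    if (c.dropna() < 0).any():
        raise ValueError("allele counts must be non-negative")
    labels = np.where(c <= low, ALLELE_BANDS[0], np.where(c >= high, ALLELE_BANDS[2], ALLELE_BANDS[1]))
    out = pd.Series(labels, index=counts.index, name="allele_band")
    out[c.isna()] = np.nan
    return pd.Series(
        pd.Categorical(out, categories=list(ALLELE_BANDS)), index=counts.index, name="allele_band"
    )


def split_at_percentile(
    scores: pd.Series, q: float = 0.95, reference_scores: pd.Series | np.ndarray | None = None
) -> pd.Series:
    """0/1 indicator of scores strictly above the q-quantile of the sample.

    The quantile is taken over ``reference_scores`` when supplied, else over
    ``scores`` itself.
    """
    s = scores.astype(float)
    ref = np.asarray(reference_scores if reference_scores is not None else s, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("no scores to split")
    cut = np.quantile(ref, q, method="linear")
    out = (s > cut).astype("Int64")
    out[s.isna()] = pd.NA
    out.name = f"top{round((1 - q) * 100)}pct"
    return out


def compute_prs(
    dosages: pd.DataFrame,
    panel: SnpPanel,
    missing_policy: str = "mean",
    reference_scores: pd.Series | None = None,
) -> PrsResult:
    """Full per-individual PRS result: counts, score, and all groupings.

    Tertile and 95th-percentile cutpoints come from ``reference_scores`` when
    given (e.g. to pool cutpoints across studies); by default each sample is
    its own reference.
    """
    counts = count_risk_alleles(dosages, panel)
    score, n_missing = weighted_prs(dosages, panel, missing_policy)
    ref = reference_scores if reference_scores is not None else score
    return PrsResult(
        total_risk_alleles=counts,
        weighted_score=score,
        n_missing_snps=n_missing,
        tertile=categorize_tertiles(score, ref),
        allele_band=band_by_allele_count(counts),
        top5pct=split_at_percentile(score, reference_scores=ref),
        missing_policy=missing_policy,
    )
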