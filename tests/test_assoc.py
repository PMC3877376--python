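"""Logistic association models: closed forms, oracles, calibration, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melprs.assoc import (
    SeparationError,
    fit_logistic,
    ordinal_code,
    prs_association,
    single_snp_association,
    variance_explained,
)
from melprs.panel import SnpPanel, SnpRecord
from melprs.prs import compute_prs
from melprs.synth import SKIN_LEVELS, CohortConfig, simulate_case_control


def two_by_two_cohort(a, b, c, d):
    """a exposed cases, b exposed controls, c unexposed cases, d unexposed controls."""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1] * (a + b) + [0] * (c + d)
    return pd.Series(y, name="case"), pd.Series(x, dtype=float)


def grid_search_mle(y, x, passes=6, half_width=3.0, points=41):
    """Iteratively refined grid search of the two-parameter log-likelihood."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def ll(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    c0, c1, hw = 0.0, 0.0, half_width
    for _ in range(passes):
        b0s = np.linspace(c0 - hw, c0 + hw, points)
        b1s = np.linspace(c1 - hw, c1 + hw, points)
        vals = np.array([[ll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        hw = 2 * hw / (points - 1) * 2  # shrink around the best cell
    return c0, c1


class TestFitLogistic:
    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(0, 2, 400))
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(400)})
        est, _ = fit_logistic(y, X)
        lo, hi = est["x"].ci95
        assert lo < 1.0 < hi

    def test_two_by_two_closed_form_or(self):
        y, x = two_by_two_cohort(a=30, b=10, c=20, d=40)
        est, _ = fit_logistic(y, pd.DataFrame({"const": 1.0, "exposed": x}))
        assert est["exposed"].or_point == pytest.approx(6.0, abs=1e-6)
        # Woolf SE of the log odds ratio matches the Wald SE
        assert est["exposed"].se == pytest.approx(
            math.sqrt(1 / 30 + 1 / 10 + 1 / 20 + 1 / 40), abs=1e-6
        )

    def test_grid_search_likelihood_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 500).astype(float)
        p = 1 / (1 + np.exp(-(-0.4 + 0.5 * x)))
        y = pd.Series((rng.random(500) < p).astype(int))
        est, _ = fit_logistic(y, pd.DataFrame({"const": 1.0, "dosage": x}))
        _, b1 = grid_search_mle(y, x)
        assert est["dosage"].log_or == pytest.approx(b1, abs=1e-4)

    def test_separation_raises_not_silent(self):
        y = pd.Series([0] * 20 + [1] * 20)
        x = pd.Series([0.0] * 20 + [1.0] * 20)
        with pytest.raises((SeparationError, ValueError)):
            fit_logistic(y, pd.DataFrame({"const": 1.0, "x": x}))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_logistic(pd.Series([1, 1, 1]), pd.DataFrame({"const": [1.0] * 3}))


class TestSingleSnpAssociation:
    def test_monomorphic_snp_diagnostic(self, panel):
        coh = pd.DataFrame({"case": [0, 1] * 20, "rs7412746": [1] * 40})
        with pytest.raises(SeparationError, match="monomorphic"):
            single_snp_association(coh, "rs7412746")

    def test_orientation_flip_inverts_or(self, panel, mdacc_cohort):
        est = single_snp_association(mdacc_cohort, "rs12913832", panel)
        flipped = mdacc_cohort.copy()
        flipped["rs12913832"] = 2 - flipped["rs12913832"]
        est_flip = single_snp_association(flipped, "rs12913832", panel)
        assert est_flip.or_point == pytest.approx(1 / est.or_point, rel=1e-6)

    def test_null_snp_p_values_uniform_and_calibrated(self):
        """Type-I error ~5% and uniform p under the null, across replicates."""
        panel = SnpPanel([SnpRecord("nullsnp", "A", 0.0, 0.3)])
        pvals = []
        for rep in range(400):
            cfg = CohortConfig(
                n_cases=250, n_controls=250, panel=panel,
                per_snp_log_or=np.array([0.0]), seed=50_000 + rep,
            )
            coh = simulate_case_control(cfg)
            pvals.append(single_snp_association(coh, "nullsnp", panel).p)
        pvals = np.array(pvals)
        assert abs((pvals < 0.05).mean() - 0.05) < 0.02
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPrsAssociation:
    def test_null_simulation_per_unit_ci_covers_one(self, panel):
        cfg = CohortConfig(
            n_cases=800, n_controls=800, panel=panel,
            per_snp_log_or=np.zeros(len(panel)), seed=77,
        )
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        est = prs_association(coh, prs, "continuous")
        lo, hi = est.ci95
        assert lo < 1.0 < hi

    def test_calibrated_simulation_gives_material_effect(self, panel, mdacc_cohort, mdacc_prs):
        est = prs_association(mdacc_cohort, mdacc_prs, "continuous", adjust=True)
        assert est.or_point > 1.05

    def test_band_contrast_matches_collapsed_two_by_two(self, panel):
        """High-band carriers oversampled by construction; OR equals the 2x2."""
        rng = np.random.default_rng(17)
        low = rng.integers(0, 1, size=(200, len(panel)))  # totals <= 6
        mid = rng.integers(1, 2, size=(150, len(panel)))  # totals 11
        high = np.full((120, len(panel)), 2)
        high[:, :3] = rng.integers(1, 3, size=(120, 3))  # totals >= 15
        dosages = pd.DataFrame(np.vstack([low, mid, high]), columns=panel.snp_ids)
        y = pd.Series(
            np.r_[rng.random(200) < 0.2, rng.random(150) < 0.35, rng.random(120) < 0.55]
        ).astype(int)
        coh = dosages.copy()
        coh.insert(0, "case", y)
        coh.insert(0, "study", "mdacc")
        prs = compute_prs(dosages, panel)
        est = prs_association(coh, prs, "band", adjust=False)
        b = prs.allele_band.astype(str)
        a = int(((b == ">=15") & (y == 1)).sum())
        bb = int(((b == ">=15") & (y == 0)).sum())
        c = int(((b == "<=6") & (y == 1)).sum())
        d = int(((b == "<=6") & (y == 0)).sum())
        assert min(a, bb, c, d) > 0
        assert est.or_point == pytest.approx((a * d) / (bb * c), rel=1e-5)

    def test_estimates_invariant_to_row_order_and_affine_covariates(
        self, panel, mdacc_cohort, mdacc_prs
    ):
        est = prs_association(mdacc_cohort, mdacc_prs, "continuous", adjust=True)
        perm = np.random.default_rng(1).permutation(len(mdacc_cohort))
        coh2 = mdacc_cohort.iloc[perm].reset_index(drop=True)
        prs2 = compute_prs(coh2[panel.snp_ids], panel)
        est2 = prs_association(coh2, prs2, "continuous", adjust=True)
        assert est2.log_or == pytest.approx(est.log_or, abs=1e-6)
        # rescaling age (years -> decades) must not move the PRS coefficient
        coh3 = mdacc_cohort.copy()
        coh3["age"] = coh3["age"] / 10.0
        est3 = prs_association(coh3, mdacc_prs, "continuous", adjust=True)
        assert est3.log_or == pytest.approx(est.log_or, abs=1e-6)

    def test_unavailable_covariate_names_scheme(self, panel):
        cfg = CohortConfig(n_cases=80, n_controls=80, panel=panel,
                           covariate_scheme="nhs", seed=8)
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        with pytest.raises(ValueError, match="mdacc"):
            prs_association(coh, prs, "continuous", adjust=True, scheme="mdacc")

    def test_tertile_contrast_reported_with_middle_retained(self, panel, mdacc_cohort, mdacc_prs):
        est = prs_association(mdacc_cohort, mdacc_prs, "tertile31")
        assert est.label == "prs_T3"
        assert est.n_used == len(mdacc_cohort)  # T2 rows stay in the fit


class TestVarianceExplained:
    def test_affine_trait_gives_one(self):
        s = pd.Series(np.linspace(-1, 2, 50))
        assert variance_explained(s, 3 * s + 1) == pytest.approx(1.0)

    def test_independent_trait_near_zero(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.standard_normal(5000))
        t = pd.Series(rng.integers(1, 5, 5000).astype(float))
        assert variance_explained(s, t) < 0.002

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            variance_explained(pd.Series([1.0, 2.0]), pd.Series([3.0, 3.0]))

    def test_simulator_round_trip_near_calibration(self, panel):
        cfg = CohortConfig(n_cases=2000, n_controls=2000, panel=panel,
                           pigmentation_r2=0.03, seed=31)
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        r2 = variance_explained(
            prs.weighted_score, ordinal_code(coh["skin_color"], SKIN_LEVELS)
        )
        assert r2 == pytest.approx(0.03, abs=0.02)
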