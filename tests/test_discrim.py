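"""ROC AUC, DeLong contrasts, and the five-model risk suite."""

import numpy as np
import pandas as pd
import pytest

from melprs.discrim import (
    auc_contrast,
    auc_with_ci,
    build_model_suite,
    roc_auc,
    roc_coordinates,
)
from melprs.prs import compute_prs
from melprs.synth import CohortConfig, simulate_case_control


def exhaustive_auc(scores, labels):
    """All-pairs comparison oracle: ties count one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_tied_example_pair_count(self):
        # cases {2, 3} vs controls {1, 2}: wins 1 + 1 + 1 and one tie at 1/2
        assert roc_auc([1, 2, 2, 3], [0, 1, 0, 1]) == pytest.approx(3.5 / 4)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(20_000)
        y = rng.integers(0, 2, 20_000)
        assert roc_auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        s = rng.integers(0, 12, n).astype(float)  # many ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert roc_auc(s, y) == pytest.approx(exhaustive_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        s = rng.standard_normal(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-s))).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(300)
        y = rng.integers(0, 2, 300)
        assert roc_auc(np.exp(s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)


class TestAucContrast:
    def test_identical_scores_zero_delta_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(80)
        y = rng.integers(0, 2, 80)
        res = auc_contrast(s, s, y)
        assert res["delta_auc"] == 0.0 and res["p"] == 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            auc_contrast([1, 2], [1, 2, 3], [0, 1, 1])

    def test_null_added_predictor_does_not_overreject(self, panel):
        """Nested-model contrast with a pure-noise addition stays conservative.

        For nested in-sample logistic fits the apparent AUC can only grow, so
        the paired DeLong test is conservative rather than uniform under the
        null; the operational requirement is that it does not over-reject.
        """
        from melprs.assoc import fit_logistic

        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(120):
            n = 300
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-x))).astype(int))
            Xa = pd.DataFrame({"const": 1.0, "x": x})
            Xb = pd.DataFrame({"const": 1.0, "x": x, "noise": noise})
            _, ra = fit_logistic(y, Xa)
            _, rb = fit_logistic(y, Xb)
            pvals.append(auc_contrast(ra.predict(Xa), rb.predict(Xb), y)["p"])
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() <= 0.07
        assert np.median(pvals) > 0.2

    def test_delong_p_matches_bootstrap_oracle(self):
        """Small paired case: DeLong p within the MC error of a 10k bootstrap."""
        rng = np.random.default_rng(42)
        n = 120
        signal = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.2 * signal))).astype(int)
        a = signal + rng.standard_normal(n) * 1.0
        b = signal + rng.standard_normal(n) * 0.6
        res = auc_contrast(a, b, y)

        boot = np.empty(10_000)
        idx = np.arange(n)
        for i in range(10_000):
            take = rng.choice(idx, n, replace=True)
            if y[take].sum() in (0, n):
                boot[i] = np.nan
                continue
            boot[i] = roc_auc(b[take], y[take]) - roc_auc(a[take], y[take])
        boot = boot[~np.isnan(boot)]
        from scipy import stats

        z = res["delta_auc"] / boot.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        assert res["p"] == pytest.approx(p_boot, abs=0.05)


class TestModelSuite:
    @pytest.fixture(scope="class")
    def suite(self, panel):
        cfg = CohortConfig(n_cases=700, n_controls=700, panel=panel, seed=301)
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        return build_model_suite(coh, prs, panel)

    def test_probabilities_in_unit_interval_and_paired(self, suite):
        probs = suite.probabilities
        assert ((probs >= 0) & (probs <= 1)).all().all()
        assert probs.notna().all().all()
        assert len(set(map(len, [probs[c] for c in probs]))) == 1

    def test_null_simulation_all_aucs_near_half(self, panel):
        cfg = CohortConfig(
            n_cases=600, n_controls=600, panel=panel,
            per_snp_log_or=np.zeros(len(panel)), pigmentation_r2=0.0, seed=55,
        )
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        suite = build_model_suite(coh, prs, panel)
        for name, auc in suite.auc.items():
            assert auc == pytest.approx(0.5, abs=0.06), name

    def test_enriched_models_dominate(self, suite):
        assert suite.auc["sex_age_pigment_prs"] >= suite.auc["sex_age_pigment"]
        assert suite.auc["prs_only"] > suite.auc["single_snp"]

    def test_nested_fit_never_loses_in_sample_auc(self, suite):
        assert suite.auc["sex_age_pigment"] >= suite.auc["sex_age"] - 1e-12

    def test_prs_probabilities_share_auc_with_raw_score(self, panel):
        # model probabilities are a monotone transform of the lone predictor
        cfg = CohortConfig(n_cases=300, n_controls=300, panel=panel, seed=60)
        coh = simulate_case_control(cfg)
        prs = compute_prs(coh[panel.snp_ids], panel)
        suite = build_model_suite(coh, prs, panel)
        direct = roc_auc(prs.weighted_score, coh["case"])
        assert suite.auc["prs_only"] == pytest.approx(direct, abs=1e-10)

    def test_auc_ci_brackets_estimate(self, suite):
        for name, (lo, hi) in suite.auc_ci.items():
            assert lo <= suite.auc[name] <= hi


class TestRocCoordinates:
    def test_curve_endpoints_and_area(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(400)
        y = (rng.random(400) < 1 / (1 + np.exp(-s))).astype(int)
        curve = roc_coordinates(s, y)
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]
        area = np.trapezoid(curve["tpr"], curve["fpr"])
        assert area == pytest.approx(roc_auc(s, y), abs=1e-10)
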