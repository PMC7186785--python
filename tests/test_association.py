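import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from linkdiv import association as assoc


class TestSpearman:
    def test_monotone_is_one(self):
        r = assoc.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        r = assoc.spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert r.rho == pytest.approx(-1.0)

    def test_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 60))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = x * 0.5 + rng.normal(0, 1, n)
            r = assoc.spearman(x, y)
            # independent midrank computation
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert r.rho == pytest.approx(oracle, abs=1e-12)

    def test_large_sample_p_matches_t_approximation(self, rng):
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        r = assoc.spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert r.rho == pytest.approx(ref_rho, abs=1e-12)
        assert r.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_small_sample_exact_permutation_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        r = assoc.spearman(x, y)
        # independent enumeration over all 120 permutations
        rx = stats.rankdata(x)
        count = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            rho = np.corrcoef(rx, perm)[0, 1]
            if abs(rho) >= abs(r.rho) - 1e-12:
                count += 1
        assert r.p_value == pytest.approx(count / 120)

    def test_constant_input_flagged_undefined(self):
        r = assoc.spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(r.rho) and np.isnan(r.p_value)

    def test_nan_pairs_dropped(self):
        r = assoc.spearman([1, 2, 3, 4, np.nan], [1, 2, 3, 4, 5])
        assert r.n_windows == 4 and r.rho == pytest.approx(1.0)


class TestWilcoxonRanksum:
    def test_identical_groups_u_is_half_product(self):
        r = assoc.wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(4.5)

    def test_exact_one_sided_p_one_sixth(self):
        # {3,4} vs {1,2}: the most extreme of C(4,2)=6 rank assignments
        r = assoc.wilcoxon_ranksum([3, 4], [1, 2], alternative="greater")
        assert r.p_value == pytest.approx(1 / 6)

    def test_two_sided_doubles_smaller_tail_in_exact_regime(self):
        one = assoc.wilcoxon_ranksum([3, 4], [1, 2], alternative="greater")
        two = assoc.wilcoxon_ranksum([3, 4], [1, 2], alternative="two-sided")
        assert two.p_value == pytest.approx(min(1.0, 2 * one.p_value))

    def test_exact_regime_matches_scipy(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(1.0, 1.0, size=6)
        r = assoc.wilcoxon_ranksum(a, b, alternative="two-sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_matches_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(0.4, 1.0, size=55)
        r = assoc.wilcoxon_ranksum(a, b, alternative="greater")
        ref = stats.mannwhitneyu(a, b, alternative="greater",
                                 method="asymptotic", use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_corrected_against_scipy(self, rng):
        a = rng.integers(0, 4, 30).astype(float)
        b = rng.integers(0, 4, 30).astype(float)
        r = assoc.wilcoxon_ranksum(a, b, alternative="two-sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.wilcoxon_ranksum([], [1, 2])


def records_frame(n, rng, beta=None, noise=0.0):
    """Window records with theta_pi = linear combination of covariates."""
    rec = pd.DataFrame({
        "rate": rng.uniform(0.1, 1.2, n),
        "jc_div": rng.uniform(0.1, 0.2, n),
        "cpg_count": rng.uniform(5000, 20000, n),
        "tx_prop": rng.uniform(0.1, 0.6, n),
    })
    beta = beta or {}
    y = (beta.get("intercept", 2e-3)
         + beta.get("rate", 0.0) * rec["rate"]
         + beta.get("jc_div", 0.0) * rec["jc_div"]
         + beta.get("cpg_count", 0.0) * rec["cpg_count"]
         + beta.get("tx_prop", 0.0) * rec["tx_prop"]
         + beta.get("cpg_x_tx", 0.0) * rec["cpg_count"] * rec["tx_prop"])
    rec["theta_pi"] = y + rng.normal(0, noise, n)
    return rec


class TestLinearModel:
    def test_exact_fit_on_noiseless_response(self, rng):
        rec = records_frame(50, rng, beta={"intercept": 0.0, "rate": 2.0})
        fit = assoc.fit_linear_model(rec)
        assert fit.terms.loc["rate", "estimate"] == pytest.approx(2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        rec = records_frame(50, rng, beta={"rate": 1e-4, "tx_prop": -5e-4},
                            noise=1e-4)
        fit = assoc.fit_linear_model(rec)
        x, _ = assoc.build_design(rec)
        y = rec["theta_pi"].to_numpy()
        beta_hat = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(fit.terms["estimate"].to_numpy(), beta_hat, atol=1e-8)
        # standard errors from the unbiased residual variance
        resid = y - x @ beta_hat
        s2 = resid @ resid / (len(y) - x.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.inv(x.T @ x)))
        assert np.allclose(fit.terms["std_error"].to_numpy(), se, rtol=1e-8)

    def test_planted_coefficients_recovered_within_3_se(self, rng):
        beta = {"intercept": 3.2e-3, "rate": 1.55e-4, "jc_div": 3.16e-3,
                "cpg_count": -8.53e-8, "tx_prop": -6.1e-4, "cpg_x_tx": -2.94e-8}
        rec = records_frame(2000, rng, beta=beta, noise=5e-5)
        fit = assoc.fit_linear_model(rec)
        for term, truth in beta.items():
            est = fit.terms.loc[term, "estimate"]
            se = fit.terms.loc[term, "std_error"]
            assert abs(est - truth) < 3 * se

    def test_rank_deficiency_names_collinear_terms(self, rng):
        rec = records_frame(40, rng)
        rec["jc_div"] = 2.0 * rec["rate"]  # exact collinearity
        with pytest.raises(ValueError, match="jc_div|rate"):
            assoc.fit_linear_model(rec)

    def test_complete_case_counting(self, rng):
        rec = records_frame(30, rng, beta={"rate": 1e-4}, noise=1e-5)
        rec.loc[:4, "rate"] = np.nan
        fit = assoc.fit_linear_model(rec)
        assert fit.n == 25


class TestContrasts:
    def make_classed(self, rng, effect=0.0, n=200):
        rec = pd.DataFrame({"theta_pi": rng.normal(2e-3, 2e-4, n),
                            "rate_class": ["mid"] * n})
        rec.iloc[:20, rec.columns.get_loc("rate_class")] = "low"
        rec.iloc[-20:, rec.columns.get_loc("rate_class")] = "high"
        rec.loc[rec["rate_class"] == "high", "theta_pi"] += effect
        return rec

    def test_planted_effect_detected(self, rng):
        rec = self.make_classed(rng, effect=5e-4)
        r = assoc.percentile_contrast(rec)
        med_high = rec.loc[rec.rate_class == "high", "theta_pi"].median()
        med_low = rec.loc[rec.rate_class == "low", "theta_pi"].median()
        assert med_high > med_low
        assert r.p_value < 0.01

    def test_two_sided_p_symmetric_under_class_swap(self, rng):
        rec = self.make_classed(rng, effect=3e-4)
        swapped = rec.copy()
        swapped["rate_class"] = swapped["rate_class"].map(
            {"low": "high", "high": "low", "mid": "mid"})
        p1 = assoc.percentile_contrast(rec).p_value
        p2 = assoc.percentile_contrast(swapped).p_value
        assert p1 == pytest.approx(p2)

    def test_empty_class_rejected(self, rng):
        rec = self.make_classed(rng)
        rec["rate_class"] = "mid"
        with pytest.raises(ValueError):
            assoc.percentile_contrast(rec)

    def test_hotspot_contrast_is_one_sided_greater(self, rng):
        n = 300
        rec = pd.DataFrame({"theta_pi": rng.normal(2e-3, 2e-4, n),
                            "hotspot_presence": [False] * n})
        rec.iloc[:30, rec.columns.get_loc("hotspot_presence")] = True
        rec.loc[rec["hotspot_presence"], "theta_pi"] += 4e-4
        r = assoc.hotspot_contrast(rec)
        assert r.alternative == "greater"
        assert r.p_value < 0.01
        # reversing the planted direction should give a large p
        rec.loc[rec["hotspot_presence"], "theta_pi"] -= 8e-4
        assert assoc.hotspot_contrast(rec).p_value > 0.5
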