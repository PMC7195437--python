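"""Tests for the two-sample MR estimators, heterogeneity and decision logic."""

import numpy as np
import pytest

from lifemr.instruments import InstrumentSet
from lifemr.mr import (
    MRResult,
    adjust_pvalues,
    bonferroni_threshold,
    classify_causal,
    cochran_q,
    egger,
    ivw,
    wald_ratio,
)
from lifemr.simulate import sim_mr_dataset
from conftest import make_pair


def iset_from(pairs, gene="G1"):
    return InstrumentSet(gene, pairs, p_thresh=1.0, r2_thresh=1.0)


class TestWaldRatio:
    def test_hand_example(self):
        theta, se = wald_ratio(make_pair(0.5, 0.05, 0.05, 0.02))
        assert theta == pytest.approx(0.1) and se == pytest.approx(0.04)

    def test_null_numerator(self):
        theta, se = wald_ratio(make_pair(1.0, 0.1, 0.0, 0.1))
        assert theta == 0.0 and se == pytest.approx(0.1)

    def test_sign_symmetry(self):
        t1, s1 = wald_ratio(make_pair(0.5, 0.05, 0.05, 0.02))
        t2, s2 = wald_ratio(make_pair(-0.5, 0.05, 0.05, 0.02))
        assert t2 == pytest.approx(-t1) and s2 == pytest.approx(s1)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair(0.0, 0.05, 0.05, 0.02))


class TestIVW:
    def test_two_pair_hand_computation(self, simple_pairs):
        res = ivw(iset_from(simple_pairs))
        assert res.theta == pytest.approx(0.1, abs=1e-15)
        assert res.se == pytest.approx(1 / np.sqrt(2000), rel=1e-12)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.model == "random"  # inflation floored at 1, se equals fixed

    def test_single_pair_reduces_to_wald(self):
        pair = make_pair(0.5, 0.05, 0.05, 0.02)
        res = ivw(iset_from([pair]))
        theta, se = wald_ratio(pair)
        assert res.method == "Wald"
        assert res.theta == pytest.approx(theta) and res.se == pytest.approx(se)

    def test_matches_weighted_regression_oracle(self, rng):
        """IVW equals WLS through the origin (statsmodels) to 1e-10."""
        import statsmodels.api as sm

        for _ in range(200):
            j = rng.integers(2, 30)
            bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
            by = rng.normal(0.1 * bx, 0.05)
            sy = rng.uniform(0.01, 0.1, j)
            pairs = [make_pair(bx[i], 0.01, by[i], sy[i], f"iv{i}") for i in range(j)]
            res = ivw(iset_from(pairs), model="fixed")
            fit = sm.WLS(by, bx[:, None], weights=sy**-2.0).fit()
            assert res.theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_invariant_to_jointly_negating_an_instrument(self, rng):
        bx = rng.uniform(0.05, 0.5, 10)
        by = rng.normal(0.05 * bx, 0.02)
        sy = rng.uniform(0.01, 0.05, 10)
        pairs = [make_pair(bx[i], 0.01, by[i], sy[i], f"iv{i}") for i in range(10)]
        flipped = [make_pair(-bx[i], 0.01, -by[i], sy[i], f"iv{i}") if i % 3 == 0
                   else pairs[i] for i in range(10)]
        assert ivw(iset_from(pairs)).theta == pytest.approx(
            ivw(iset_from(flipped)).theta, rel=1e-12
        )

    def test_requires_two_instruments_for_q(self):
        with pytest.raises(ValueError):
            cochran_q(iset_from([make_pair(0.1, 0.01, 0.01, 0.01)]), 0.1)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self, simple_pairs):
        res = ivw(iset_from(simple_pairs))
        q, df, p = cochran_q(iset_from(simple_pairs), res.theta)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 1 and p == pytest.approx(1.0)

    def test_null_calibration(self):
        """Homogeneous null: empirical P(Q_p < 0.05) inside the binomial
        99% CI around 0.05 (J=26, 2000 replicates)."""
        hits = 0
        reps = 2000
        for rep in range(reps):
            iset, _ = sim_mr_dataset(26, 0.0, seed=810_000 + rep)
            res = ivw(iset)
            hits += res.Q_p < 0.05
        half = 2.5758 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half < hits / reps < 0.05 + half


class TestEgger:
    def test_exact_line_recovered(self):
        pairs = [make_pair(bx, 0.01, 0.01 + 0.2 * bx, 0.01, f"iv{i}")
                 for i, bx in enumerate([0.1, 0.2, 0.4])]
        res = egger(iset_from(pairs))
        assert res.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert res.theta == pytest.approx(0.2, abs=1e-10)
        assert res.Q == pytest.approx(0.0, abs=1e-16)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        bx = rng.uniform(0.05, 0.5, 12)
        by = rng.normal(0.02 + 0.1 * bx, 0.03)
        sy = rng.uniform(0.01, 0.08, 12)
        pairs = [make_pair(bx[i], 0.01, by[i], sy[i], f"iv{i}") for i in range(12)]
        res = egger(iset_from(pairs))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=sy**-2.0).fit()
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.theta == pytest.approx(fit.params[1], abs=1e-10)

    def test_orientation_makes_result_flip_invariant(self, rng):
        bx = rng.uniform(0.05, 0.5, 8)
        by = rng.normal(0.02 + 0.1 * bx, 0.03)
        sy = rng.uniform(0.01, 0.08, 8)
        pairs = [make_pair(bx[i], 0.01, by[i], sy[i], f"iv{i}") for i in range(8)]
        flipped = [make_pair(-bx[i], 0.01, -by[i], sy[i], f"iv{i}") if i < 4 else pairs[i]
                   for i in range(8)]
        a, b = egger(iset_from(pairs)), egger(iset_from(flipped))
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)

    def test_slope_agrees_with_ivw_without_pleiotropy(self):
        """Zero-intercept data: Egger slope within ~1 joint SE of IVW."""
        agree = 0
        reps = 300
        for rep in range(reps):
            iset, _ = sim_mr_dataset(26, 0.05, seed=20_000 + rep)
            e, i = egger(iset), ivw(iset)
            agree += abs(e.theta - i.theta) < 2 * np.hypot(e.se, i.se)
        assert agree / reps > 0.9

    def test_directional_pleiotropy_recovered_in_mean(self):
        ints = []
        reps = 400
        for rep in range(reps):
            iset, _ = sim_mr_dataset(26, 0.05, pleiotropy_mean=0.02,
                                     pleiotropy_sd=0.005, seed=40_000 + rep)
            ints.append(egger(iset).egger_intercept)
        ints = np.array(ints)
        mc_se = ints.std(ddof=1) / np.sqrt(reps)
        assert abs(ints.mean() - 0.02) < 3 * mc_se

    def test_too_few_or_degenerate_instruments(self):
        with pytest.raises(ValueError):
            egger(iset_from([make_pair(0.1, 0.01, 0.01, 0.01, "a"),
                             make_pair(0.2, 0.01, 0.02, 0.01, "b")]))
        same = [make_pair(0.2, 0.01, 0.02, 0.01, f"iv{i}") for i in range(4)]
        with pytest.raises(ValueError, match="unidentifiable"):
            egger(iset_from(same))


class TestMultipleTesting:
    def test_published_family_thresholds(self):
        assert bonferroni_threshold(0.05, 116) == pytest.approx(4.3103448e-4, rel=1e-6)
        assert bonferroni_threshold(0.05, 392) == pytest.approx(1.2755102e-4, rel=1e-6)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_adjustment_methods(self):
        p = np.array([0.01, 0.04, 0.5])
        assert adjust_pvalues(p, "bonferroni") == pytest.approx([0.03, 0.12, 1.0])
        bh = adjust_pvalues(p, "bh")
        assert np.all(np.diff(bh[np.argsort(p)]) >= 0)
        with pytest.raises(ValueError):
            adjust_pvalues([], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm")


class TestClassifyCausal:
    def _res(self, gene, p, q_p):
        return MRResult(gene, "IVW", 0.1, 0.02, 0.06, 0.14, p, 10, Q=1.0, Q_df=9, Q_p=q_p)

    class _Presso:
        def __init__(self, verdict, gate=None):
            self.verdict = verdict
            self.failed_gate = gate

    def test_homogeneous_significant_is_causal(self):
        calls = classify_causal([self._res("g", 1e-6, 0.4)], m=116)
        assert calls["causal"].iloc[0]
        assert calls["evidence_path"].iloc[0] == "ivw_homogeneous"

    def test_failed_rescue_is_not_causal(self):
        calls = classify_causal([self._res("g", 1e-6, 0.01)],
                                {"g": self._Presso("not_rescued", "distortion")}, m=116)
        assert not calls["causal"].iloc[0]
        assert "not_rescued" in calls["evidence_path"].iloc[0]

    def test_successful_rescue_is_causal(self):
        calls = classify_causal([self._res("g", 1e-6, 0.01)],
                                {"g": self._Presso("rescued")}, m=116)
        assert calls["causal"].iloc[0]
        assert calls["evidence_path"].iloc[0] == "presso_rescued"

    def test_bonferroni_gate_dominates(self):
        calls = classify_causal([self._res("g", 0.01, 0.9)], m=116)
        assert not calls["causal"].iloc[0]
        assert calls["evidence_path"].iloc[0] == "not_significant"

    def test_missing_presso_flagged_incomplete(self):
        calls = classify_causal([self._res("g", 1e-6, 0.01)], m=116)
        assert not calls["causal"].iloc[0]
        assert calls["evidence_path"].iloc[0] == "incomplete_presso_missing"


class TestCalibrationAndRecovery:
    def test_type_one_error_under_null(self):
        """Fixed-effect IVW p is exactly uniform under the homogeneous null;
        the empirical rejection rate at 0.05 sits in the binomial 99% CI."""
        hits = 0
        reps = 2000
        for rep in range(reps):
            iset, _ = sim_mr_dataset(26, 0.0, seed=910_000 + rep)
            hits += ivw(iset, model="fixed").p < 0.05
        half = 2.5758 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half < hits / reps < 0.05 + half

    def test_theta_recovery_in_mean(self):
        thetas = []
        reps = 1000
        for rep in range(reps):
            iset, truth = sim_mr_dataset(26, 0.05, seed=50_000 + rep)
            thetas.append(ivw(iset).theta)
        thetas = np.array(thetas)
        mc_se = thetas.std(ddof=1) / np.sqrt(reps)
        assert abs(thetas.mean() - 0.05) < 3 * mc_se
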