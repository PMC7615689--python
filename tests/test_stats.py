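"""Inferential contracts, effect sizes and design planning."""

import numpy as np
import pandas as pd
import pytest

from streetnav import stats as S
from streetnav.errors import (
    DegenerateDesignError,
    InvalidParameterError,
    NoSolutionError,
    UndefinedCorrelationError,
)


class TestChangeScores:
    def test_constant_series_has_zero_change(self):
        cs = S.change_scores([1.0] * 30, [1.0] * 5, [1.0] * 5)
        assert cs.training_change == 0.0
        assert cs.transfer_change == 0.0

    def test_simple_means(self):
        cs = S.change_scores([1.0] * 10 + [0.0] * 10 + [1.5] * 10,
                             [0.8] * 5, [1.1] * 5)
        assert cs.early_pi == pytest.approx(1.0)
        assert cs.late_pi == pytest.approx(1.5)
        assert cs.training_change == pytest.approx(0.5)
        assert cs.transfer_change == pytest.approx(0.3)

    def test_linear_ramp(self):
        # PI ramp 1..100 rescaled to [0, 1]: change = 90/99
        pi = (np.arange(1.0, 101.0) - 1.0) / 99.0
        cs = S.change_scores(pi, [0.5] * 5, [0.5] * 5)
        assert cs.training_change == pytest.approx(90.0 / 99.0)
        assert cs.training_change == pytest.approx(0.909, abs=1e-3)

    def test_insufficient_trials(self):
        with pytest.raises(InvalidParameterError):
            S.change_scores([1.0] * 15, [1.0] * 5, [1.0] * 5)


class TestTTests:
    def test_printed_toy_two_sample(self):
        res = S.two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.cohens_d == pytest.approx(-3.0)
        assert res.df == 4

    def test_paired_t_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + np.array([0.5, 0.7, 0.6, 0.6])
        res = S.paired_t(x, y)
        diff = x - y
        assert res.t == pytest.approx(
            diff.mean() / (diff.std(ddof=1) / 2.0))
        assert res.cohens_d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_bonferroni_never_below_raw(self):
        res = S.two_sample_t([1.0, 2.0, 3.0], [1.5, 2.5, 3.5], family_size=10)
        assert res.p_adjusted >= res.p
        assert res.p_adjusted == pytest.approx(min(1.0, res.p * 10))

    def test_family_defaults_to_all_pairs(self):
        df = pd.DataFrame({
            "g": np.repeat(list("abcde"), 4),
            "y": np.arange(20.0),
        })
        fol = S.pairwise_followups(df, "y", "g")
        assert len(fol) == 10  # 5 choose 2
        assert all(f.p_adjusted == pytest.approx(min(1.0, f.p * 10)) for f in fol)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "y": [1.0, 2.0, 3.0] * 2})
        eff = S.one_way_anova(df, "y", "g").effect("g")
        assert eff.F == pytest.approx(0.0, abs=1e-12)
        assert eff.partial_eta2 == pytest.approx(0.0, abs=1e-12)

    def test_against_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 10),
            "y": rng.normal(0, 1, 30) + np.repeat([0.0, 0.4, 0.9], 10),
        })
        ours = S.one_way_anova(df, "y", "g").effect("g")
        ref = pg.anova(data=df, dv="y", between="g", detailed=True)
        assert ours.F == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert ours.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-8)
        assert ours.partial_eta2 == pytest.approx(float(ref["np2"][0]), rel=1e-8)

    def test_ancova_against_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 12),
            "cov": rng.normal(0, 1, 36),
        })
        df["y"] = 0.8 * df["cov"] + rng.normal(0, 1, 36) \
            + np.repeat([0.0, 0.5, 1.0], 12)
        ours = S.ancova(df, "y", "g", ["cov"])
        ref = pg.ancova(data=df, dv="y", between="g", covar="cov")
        assert ours.effect("g").F == pytest.approx(
            float(ref.loc[ref["Source"] == "g", "F"].iloc[0]), rel=1e-8)
        assert ours.effect("cov").F == pytest.approx(
            float(ref.loc[ref["Source"] == "cov", "F"].iloc[0]), rel=1e-8)

    def test_brute_force_projection_oracle(self):
        """F and partial eta^2 agree with explicit least-squares sums of
        squares on a small instance."""
        rng = np.random.default_rng(2)
        g = np.repeat([0, 1, 2], 8)
        y = rng.normal(0, 1, 24) + 0.5 * g
        df = pd.DataFrame({"g": g.astype(str), "y": y})
        eff = S.one_way_anova(df, "y", "g").effect("g")
        grand = y.mean()
        ss_b = sum(8 * (y[g == k].mean() - grand) ** 2 for k in range(3))
        ss_w = sum(((y[g == k] - y[g == k].mean()) ** 2).sum() for k in range(3))
        F = (ss_b / 2) / (ss_w / 21)
        assert eff.F == pytest.approx(F, rel=1e-8)
        assert eff.partial_eta2 == pytest.approx(ss_b / (ss_b + ss_w), rel=1e-8)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 6, "y": np.arange(6.0)})
        with pytest.raises(DegenerateDesignError):
            S.one_way_anova(df, "y", "g")


class TestEffectSizesAndPower:
    def test_study_eta2_converts_to_medium_f(self):
        assert round(S.eta2_to_f(0.054), 2) == 0.24

    @pytest.mark.parametrize("eta2, f", [(0.0, 0.0), (0.5, 1.0)])
    def test_conversion_anchors(self, eta2, f):
        assert S.eta2_to_f(eta2) == pytest.approx(f)

    def test_roundtrip(self):
        for f in (0.1, 0.24, 0.5, 1.3):
            assert S.eta2_to_f(S.f_to_eta2(f)) == pytest.approx(f, abs=1e-12)

    def test_eta2_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            S.eta2_to_f(1.0)

    def test_study_planning_inputs_give_420(self):
        f = S.eta2_to_f(0.054)
        n = S.required_sample_size(f, alpha=0.05, power=0.95, n_groups=15,
                                   n_measurements=2, corr_repeated=0.663)
        assert n == 420

    def test_larger_effect_needs_fewer_subjects(self):
        kw = dict(alpha=0.05, power=0.95, n_groups=15,
                  n_measurements=2, corr_repeated=0.663)
        assert S.required_sample_size(0.48, **kw) < S.required_sample_size(0.24, **kw)

    def test_lower_power_needs_fewer_subjects(self):
        f = S.eta2_to_f(0.054)
        kw = dict(alpha=0.05, n_groups=15, n_measurements=2, corr_repeated=0.663)
        assert S.required_sample_size(f, power=0.80, **kw) < 420

    def test_returned_n_is_minimal_multiple(self):
        f = S.eta2_to_f(0.054)
        kw = dict(alpha=0.05, n_groups=15, n_measurements=2, corr_repeated=0.663)
        n = S.required_sample_size(f, power=0.95, **kw)
        assert n % 15 == 0
        assert S.between_factors_power(n, f, 15, 2, 0.663) >= 0.95
        assert S.between_factors_power(n - 15, f, 15, 2, 0.663) < 0.95

    def test_unreachable_power(self):
        with pytest.raises(NoSolutionError):
            S.required_sample_size(1e-4, n_groups=15, max_n=1500)


class TestCorrelation:
    def test_identity_is_perfect(self):
        cohort = pd.DataFrame({
            "training_change": [0.1, 0.5, 0.9, 1.3],
            "transfer_change": [0.1, 0.5, 0.9, 1.3],
        })
        r, p = S.training_transfer_correlation(cohort)
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            S.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_changes_stay_small(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            r, _ = S.pearson_r(rng.normal(0, 1, 450), rng.normal(0, 1, 450))
            hits += abs(r) < 0.1
        assert hits >= 36  # |r| < 0.1 in ~95% of null replicates

    def test_shared_learning_factor_recovered_as_positive(self):
        rng = np.random.default_rng(4)
        positives = 0
        lam = np.sqrt(0.3)  # shared-factor loading; implied r = 0.3
        for _ in range(200):
            shared = rng.normal(0, 1, 450)
            train = lam * shared + np.sqrt(1 - lam ** 2) * rng.normal(0, 1, 450)
            trans = lam * shared + np.sqrt(1 - lam ** 2) * rng.normal(0, 1, 450)
            r, _ = S.pearson_r(train, trans)
            positives += r > 0
        assert positives >= 190  # >= 95% of replicates
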