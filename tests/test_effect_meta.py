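"""Effect sizes and pooling versus independently coded oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirmeta import (EffectSize, StudySummary, cohen_d, effects_from_studies,
                     egger_test, hedges_g, leave_one_out, pool, subgroup_pool)
from mirmeta.effect_meta import InsufficientDataError


def summary(n1, m1, s1, n2, m2, s2, key="X", specimen="tissue"):
    return StudySummary(key, "", "NSCLC", specimen, n1, m1, s1, n2, m2, s2)


def dl_oracle(g, v):
    """Brute-force DerSimonian-Laird pooling written from the defining
    formulas, independent of the implementation under test."""
    g, v = np.asarray(g, float), np.asarray(v, float)
    w = 1 / v
    mu_f = (w * g).sum() / w.sum()
    q = (w * (g - mu_f) ** 2).sum()
    df = len(g) - 1
    tau2 = max(0.0, (q - df) / (w.sum() - (w**2).sum() / w.sum())) if df else 0.0
    wr = 1 / (v + tau2)
    mu = (wr * g).sum() / wr.sum()
    se = (1 / wr.sum()) ** 0.5
    return mu, se, q, tau2


class TestHedgesG:
    def test_small_chip_study_frozen_values(self):
        # (6, 12.643, 0.704) vs (6, 11.099, 2.171): sp = 1.6140, d = 0.9566,
        # J = 1 - 3/39; evaluated by hand from the defining formulas
        e = hedges_g(summary(6, 12.643, 0.704, 6, 11.099, 2.171))
        assert e.g == pytest.approx(0.883, abs=1e-3)
        assert e.var_g == pytest.approx(0.317, abs=1e-3)

    def test_zero_when_means_equal(self):
        assert hedges_g(summary(10, 5.0, 1.0, 12, 5.0, 2.0)).g == 0.0

    def test_correction_shrinks_toward_zero(self):
        s = summary(6, 2.0, 1.0, 6, 1.0, 1.0)
        assert abs(hedges_g(s).g) < abs(cohen_d(s).g)
        m = s.n_case + s.n_control - 2
        assert hedges_g(s).g == pytest.approx(cohen_d(s).g * (1 - 3 / (4 * m - 1)))

    @settings(deadline=None, max_examples=100)
    @given(n1=st.integers(2, 100), n2=st.integers(2, 100),
           m1=st.floats(-10, 10), m2=st.floats(-10, 10),
           s1=st.floats(0.1, 5), s2=st.floats(0.1, 5))
    def test_swapping_arms_negates_g(self, n1, n2, m1, m2, s1, s2):
        fwd = hedges_g(summary(n1, m1, s1, n2, m2, s2))
        rev = hedges_g(summary(n2, m2, s2, n1, m1, s1))
        assert fwd.g == pytest.approx(-rev.g, rel=1e-12, abs=1e-12)
        assert fwd.var_g == pytest.approx(rev.var_g, rel=1e-12)

    def test_sign_matches_mean_difference(self, chips):
        for s in chips:
            e = hedges_g(s)
            assert math.copysign(1, e.g) == math.copysign(
                1, s.mean_case - s.mean_control)

    def test_small_arm_rejected(self):
        with pytest.raises(InsufficientDataError):
            hedges_g(summary(1, 0.0, 1.0, 10, 0.0, 1.0))


class TestPool:
    def test_single_study_is_degenerate(self):
        e = EffectSize("A", 0.4, 0.04)
        res = pool([e])
        assert res.pooled == pytest.approx(0.4)
        assert res.q == 0.0 and res.tau2 == 0.0 and res.i2 == 0.0
        assert res.ci_low == pytest.approx(0.4 - 1.959963984540054 * 0.2)

    def test_two_identical_studies(self):
        es = [EffectSize("A", 0.5, 0.04), EffectSize("B", 0.5, 0.04)]
        res = pool(es)
        assert res.pooled == pytest.approx(0.5)
        assert res.q == pytest.approx(0.0)
        assert res.tau2 == 0.0

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            pool([])

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("model", ["fixed", "random_dl"])
    def test_matches_brute_force_oracle_on_small_sets(self, seed, model):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        g = rng.normal(0.5, 0.6, size=k)
        v = rng.uniform(0.01, 0.4, size=k)
        res = pool([EffectSize(str(i), g[i], v[i]) for i in range(k)], model=model)
        mu, se, q, tau2 = dl_oracle(g, v)
        if model == "fixed":
            w = 1 / v
            mu, se = (w * g).sum() / w.sum(), (1 / w.sum()) ** 0.5
        assert res.pooled == pytest.approx(mu, rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)
        assert res.q == pytest.approx(q, rel=1e-12)
        assert res.tau2 == pytest.approx(tau2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_model_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(2, 12))
        es = [EffectSize(str(i), rng.normal(0, 1), rng.uniform(0.01, 0.5))
              for i in range(k)]
        fixed, random = pool(es, model="fixed"), pool(es, model="random_dl")
        # order invariance
        shuffled = list(es)
        rng.shuffle(shuffled)
        assert pool(shuffled, model="fixed").pooled == pytest.approx(
            fixed.pooled, rel=1e-12)
        # random CI never narrower than fixed CI
        assert (random.ci_high - random.ci_low) >= (
            fixed.ci_high - fixed.ci_low) - 1e-12
        assert 0 <= random.i2 <= 100
        assert random.tau2 >= 0
        if random.q <= random.df:
            assert random.tau2 == 0.0
            assert random.pooled == pytest.approx(fixed.pooled, rel=1e-12)
        assert sum(random.weights) == pytest.approx(1.0, abs=1e-9)
        assert sum(fixed.weights) == pytest.approx(1.0, abs=1e-9)
        assert random.ci_low <= random.pooled <= random.ci_high


class TestSubgroup:
    def test_split_matches_manual_partition(self, chips):
        effects = effects_from_studies(chips)
        by_spec = subgroup_pool(effects, model="random_dl")
        assert set(by_spec) == {"tissue", "serum"}
        tissue = [e for e in effects if e.subgroup == "tissue"]
        assert by_spec["tissue"].pooled == pytest.approx(
            pool(tissue).pooled, rel=1e-12)
        assert by_spec["tissue"].k == 15 and by_spec["serum"].k == 10

    def test_single_label_equals_plain_pool(self):
        es = [EffectSize(str(i), 0.1 * i, 0.05, subgroup="tissue")
              for i in range(4)]
        assert subgroup_pool(es)["tissue"].pooled == pytest.approx(
            pool(es).pooled)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="subgroup label"):
            subgroup_pool([EffectSize("A", 0.1, 0.05)])


class TestLeaveOneOut:
    def test_chip_corpus_no_eccentric_study(self, chips):
        """Omitting any single dataset leaves the pooled effect positive with
        a CI excluding zero."""
        effects = effects_from_studies(chips)
        results = leave_one_out(effects, model="random_dl")
        assert len(results) == 25
        assert all(r.pooled > 0 and r.ci_low > 0 for _, r in results)

    def test_k2_reduces_to_remaining_study(self):
        es = [EffectSize("A", 0.2, 0.04), EffectSize("B", 0.9, 0.09)]
        results = dict(leave_one_out(es))
        assert results["A"].pooled == pytest.approx(0.9)
        assert results["B"].pooled == pytest.approx(0.2)

    def test_omitting_consensus_study_stays_in_ci(self):
        rng = np.random.default_rng(5)
        es = [EffectSize(str(i), rng.normal(0.6, 0.2), rng.uniform(0.02, 0.2))
              for i in range(8)]
        full = pool(es)
        consensus = min(es, key=lambda e: abs(e.g - full.pooled))
        rest = [e for e in es if e is not consensus]
        assert full.ci_low <= pool(rest).pooled <= full.ci_high

    def test_needs_two(self):
        with pytest.raises(InsufficientDataError):
            leave_one_out([EffectSize("A", 0.1, 0.05)])


class TestEgger:
    def test_chip_corpus_shows_no_small_study_asymmetry(self, chips):
        bias = egger_test(effects_from_studies(chips))
        assert bias.p_value > 0.05
        assert len(bias.funnel_points) == 25

    def test_symmetric_funnel_gives_zero_intercept(self):
        # effects symmetric about their mean with pairwise-matched SEs
        es = [EffectSize("A", 0.3, 0.04), EffectSize("B", 0.7, 0.04),
              EffectSize("C", 0.2, 0.09), EffectSize("D", 0.8, 0.09)]
        assert egger_test(es).intercept == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        g = np.array([0.1, 0.4, 0.5, 0.9, 1.2])
        se = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        # closed-form OLS of y = g/se on x = 1/se via the normal equations
        y, x = g / se, 1 / se
        xbar, ybar = x.mean(), y.mean()
        slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
        intercept = ybar - slope * xbar
        bias = egger_test([EffectSize(str(i), g[i], se[i] ** 2)
                           for i in range(5)])
        assert bias.intercept == pytest.approx(intercept, abs=1e-9)
        assert bias.slope == pytest.approx(slope, abs=1e-9)

    def test_insufficient_or_degenerate(self):
        es = [EffectSize("A", 0.1, 0.04), EffectSize("B", 0.2, 0.04)]
        with pytest.raises(InsufficientDataError):
            egger_test(es)
        same = [EffectSize(str(i), 0.1 * i, 0.04) for i in range(4)]
        with pytest.raises(ValueError, match="identical SEs"):
            egger_test(same)
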