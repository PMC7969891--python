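"""Wald ratio, IVW, Cochran's Q, MR-Egger and weighted median."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_inst
from ironmr.estimators import (EstimationError, cochran_q, ivw, mr_egger,
                               to_odds_ratio, wald_ratio, weighted_median)


def random_instruments(rng, j):
    return [make_inst(rsid=f"s{i}",
                      bx=rng.uniform(0.05, 0.5) * rng.choice([-1, 1]),
                      se_x=rng.uniform(0.005, 0.02),
                      by=rng.normal(0, 0.05),
                      se_y=rng.uniform(0.005, 0.03))
            for i in range(j)]


class TestWaldRatio:
    def test_fixture_worked_example(self):
        # strongest iron instrument against its outcome association
        r = wald_ratio(make_inst(bx=0.33, se_x=0.02, by=0.02, se_y=0.03))
        assert r.beta == pytest.approx(0.0606, abs=1e-4)
        assert r.se == pytest.approx(0.0909, abs=1e-4)
        assert r.ci_low == pytest.approx(math.exp(r.beta - 1.96 * r.se))

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_inst(by=0.0)).beta == 0.0

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(EstimationError):
            wald_ratio(make_inst(bx=0.0))

    def test_second_order_se_is_wider(self):
        inst = make_inst(bx=0.1, se_x=0.05, by=0.05, se_y=0.01)
        assert wald_ratio(inst, second_order=True).se > wald_ratio(inst).se


class TestIvw:
    def test_matches_brute_force_weighted_mean(self):
        """IVW equals the analytic weighted mean of Wald ratios."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            insts = random_instruments(rng, rng.integers(2, 12))
            r = ivw(insts)
            w = [i.bx**2 / i.se_y**2 for i in insts]
            ratios = [i.by / i.bx for i in insts]
            expect = sum(wi * bi for wi, bi in zip(w, ratios)) / sum(w)
            assert abs(r.beta - expect) < 1e-12

    def test_conservative_iron_worked_example(self, conservative_instruments):
        r = ivw(conservative_instruments["iron"], effects_model="fixed")
        assert r.beta == pytest.approx(0.0385, abs=5e-4)
        assert r.se == pytest.approx(0.0432, abs=5e-4)
        assert r.or_value == pytest.approx(1.039, abs=2e-3)

    def test_single_instrument_reduces_to_wald(self):
        inst = make_inst(bx=0.2, by=0.03)
        assert ivw([inst]).beta == wald_ratio(inst).beta
        assert ivw([inst]).se == wald_ratio(inst).se

    def test_equal_ratios_give_zero_q_and_agreeing_models(self):
        insts = [make_inst(rsid="a", bx=0.1, by=0.01),
                 make_inst(rsid="b", bx=0.2, by=0.02)]
        fe = ivw(insts, "fixed")
        mre = ivw(insts, "multiplicative_random")
        assert fe.beta == pytest.approx(0.1) == pytest.approx(mre.beta)
        assert fe.q_stat == pytest.approx(0.0, abs=1e-12)
        assert fe.se == mre.se  # scale factor capped at 1

    def test_mre_se_never_below_fixed(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            insts = random_instruments(rng, 6)
            assert ivw(insts, "multiplicative_random").se >= ivw(insts, "fixed").se

    def test_empty_errors(self):
        with pytest.raises(EstimationError):
            ivw([])

    def test_unknown_effects_model(self):
        with pytest.raises(ValueError):
            ivw([make_inst()], "additive_random")


class TestCochranQ:
    def test_conservative_iron_value(self, conservative_instruments):
        insts = conservative_instruments["iron"]
        q, df = cochran_q(insts, ivw(insts).beta)
        assert q == pytest.approx(0.90, abs=0.01)
        assert df == 2

    def test_homogeneous_ratios_give_zero(self):
        insts = [make_inst(rsid=str(i), bx=0.1 * (i + 1), by=0.02 * (i + 1))
                 for i in range(4)]
        q, _ = cochran_q(insts, 0.2)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_instrument_errors(self):
        with pytest.raises(EstimationError):
            cochran_q([make_inst()], 0.0)


class TestMrEgger:
    def test_collinear_through_origin(self):
        insts = [make_inst(rsid=str(i), bx=b, by=0.3 * b)
                 for i, b in enumerate([0.1, 0.2, 0.4, 0.5])]
        r = mr_egger(insts)
        assert r.beta == pytest.approx(0.3, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_recovered_exactly(self):
        # by = theta*bx + alpha with equal weights: exact WLS solution
        theta, alpha = 0.25, 0.01
        insts = [make_inst(rsid=str(i), bx=b, by=theta * b + alpha)
                 for i, b in enumerate([0.1, 0.15, 0.3, 0.45])]
        r = mr_egger(insts)
        assert r.beta == pytest.approx(theta, abs=1e-12)
        assert r.egger_intercept == pytest.approx(alpha, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        insts = random_instruments(rng, 8)
        x = np.array([abs(i.bx) for i in insts])
        y = np.array([i.by * np.sign(i.bx) for i in insts])
        w = np.array([1 / i.se_y**2 for i in insts])
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        r = mr_egger(insts)
        assert r.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert r.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales by sigma-hat without the lower bound at 1
        sigma = math.sqrt(fit.mse_resid)
        factor = max(1.0, sigma) / sigma
        assert r.se == pytest.approx(fit.bse[1] * factor, rel=1e-8)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(5)
        insts = random_instruments(rng, 6)
        flipped = [make_inst(rsid=i.rsid, bx=-i.bx, se_x=i.se_x, by=-i.by, se_y=i.se_y)
                   for i in insts]
        a, b = mr_egger(insts), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            mr_egger([make_inst(rsid="a"), make_inst(rsid="b")])

    def test_t_and_normal_references(self):
        rng = np.random.default_rng(11)
        insts = random_instruments(rng, 5)
        pt = mr_egger(insts, pvalue_dist="t").egger_intercept_p
        pn = mr_egger(insts, pvalue_dist="normal").egger_intercept_p
        assert pt > pn  # t with 3 df has heavier tails


class TestWeightedMedian:
    def test_equal_weight_symmetric_median(self):
        insts = [make_inst(rsid=str(i), bx=0.1, by=0.1 * r)
                 for i, r in enumerate([0.1, 0.2, 0.3])]
        assert weighted_median(insts, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_conservative_iron_interpolation(self, conservative_instruments):
        r = weighted_median(conservative_instruments["iron"], seed=0)
        assert r.beta == pytest.approx(0.0559, abs=1e-4)

    def test_seeded_bootstrap_is_deterministic(self, conservative_instruments):
        insts = conservative_instruments["iron"]
        a = weighted_median(insts, n_boot=300, seed=7)
        b = weighted_median(insts, n_boot=300, seed=7)
        assert a.se == b.se

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median([make_inst(rsid="a"), make_inst(rsid="b")])


class TestToOddsRatio:
    def test_null_case(self):
        orv, lo, hi, p = to_odds_ratio(0.0, 0.05)
        assert orv == 1.0
        assert (lo, hi) == (pytest.approx(0.907, abs=1e-3), pytest.approx(1.103, abs=1e-3))
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        orv, lo, hi, _ = to_odds_ratio(0.0385, 0.0432)
        assert orv == pytest.approx(1.039, abs=1e-3)
        assert (lo, hi) == (pytest.approx(0.955, abs=1e-3), pytest.approx(1.131, abs=1e-3))

    def test_nonpositive_se_errors(self):
        with pytest.raises(EstimationError):
            to_odds_ratio(0.1, 0.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.floats(0.05, 0.5), st.floats(-0.1, 0.1),
                          st.floats(0.005, 0.05)),
                min_size=3, max_size=10))
def test_pooled_estimates_lie_within_ratio_range(triples):
    """IVW and WM are convex combinations/quantiles of the Wald ratios."""
    insts = [make_inst(rsid=str(i), bx=bx, by=by, se_y=sy)
             for i, (bx, by, sy) in enumerate(triples)]
    ratios = [i.by / i.bx for i in insts]
    lo, hi = min(ratios), max(ratios)
    assert lo - 1e-12 <= ivw(insts).beta <= hi + 1e-12
    assert lo - 1e-12 <= weighted_median(insts, n_boot=10, seed=0).beta <= hi + 1e-12


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_sign_flip_invariance_all_estimators(seed):
    rng = np.random.default_rng(seed)
    insts = random_instruments(rng, 5)
    mask = rng.integers(0, 2, len(insts)).astype(bool)
    flipped = [make_inst(rsid=i.rsid, bx=-i.bx if m else i.bx, se_x=i.se_x,
                         by=-i.by if m else i.by, se_y=i.se_y)
               for i, m in zip(insts, mask)]
    assert ivw(flipped).beta == pytest.approx(ivw(insts).beta, abs=1e-12)
    assert mr_egger(flipped).beta == pytest.approx(mr_egger(insts).beta, abs=1e-12)
    assert (weighted_median(flipped, n_boot=10, seed=1).beta
            == pytest.approx(weighted_median(insts, n_boot=10, seed=1).beta, abs=1e-12))
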