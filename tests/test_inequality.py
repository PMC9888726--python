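import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vaxineq as vq
from vaxineq.errors import DegenerateOutcomeError, ValidationError
from vaxineq.inequality import index_inference, weighted_fractional_rank


def curve_area_concentration_index(h, wealth, weights):
    """Independent oracle: twice the signed area between the 45-degree line
    and the concentration curve, by trapezoid integration over wealth-sorted
    groups (tied wealth merged into one step)."""
    h = np.asarray(h, float)
    x = np.asarray(wealth, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    order = np.argsort(x, kind="stable")
    h, x, w = h[order], x[order], w[order]
    # merge tied wealth values into single curve steps
    uniq = np.r_[True, x[1:] != x[:-1]]
    gid = np.cumsum(uniq) - 1
    gw = np.bincount(gid, weights=w)
    gh = np.bincount(gid, weights=w * h)
    P = np.r_[0.0, np.cumsum(gw)]
    L = np.r_[0.0, np.cumsum(gh)] / (w @ h)
    area_under_curve = float(np.sum((P[1:] - P[:-1]) * (L[1:] + L[:-1]) / 2.0))
    return 2.0 * (0.5 - area_under_curve)


def random_instance(rng, n, tie_prob=0.3, weighted=True):
    wealth = rng.normal(size=n)
    if n > 1 and rng.random() < tie_prob:
        idx = rng.integers(0, n, size=max(1, n // 3))
        wealth[idx] = wealth[idx[0]]
    h = rng.integers(0, 2, size=n).astype(float)
    if h.sum() == 0:
        h[rng.integers(0, n)] = 1.0
    if h.sum() == n:
        h[rng.integers(0, n)] = 0.0
    w = rng.uniform(0.2, 3.0, size=n) if weighted else np.ones(n)
    return h, wealth, w


class TestFractionalRank:
    def test_equal_weights_midpoint_formula(self):
        r = weighted_fractional_rank([10.0, 20.0, 30.0, 40.0], np.ones(4))
        assert r == pytest.approx([0.125, 0.375, 0.625, 0.875])

    def test_single_observation_rank_half(self):
        assert weighted_fractional_rank([3.0], [2.0]) == pytest.approx([0.5])

    def test_ties_share_block_midpoint(self):
        r = weighted_fractional_rank([1.0, 1.0], [1.0, 1.0])
        assert r == pytest.approx([0.5, 0.5])

    def test_order_invariance_and_open_interval(self, rng):
        for n in (2, 5, 23):
            h, wealth, w = random_instance(rng, n)
            r = weighted_fractional_rank(wealth, w)
            perm = rng.permutation(n)
            r2 = weighted_fractional_rank(wealth[perm], w[perm])
            assert r2 == pytest.approx(r[perm])
            assert np.all((r > 0) & (r < 1))

    def test_weighted_mean_rank_is_half(self, rng):
        h, wealth, w = random_instance(rng, 31)
        r = weighted_fractional_rank(wealth, w)
        assert float((w / w.sum()) @ r) == pytest.approx(0.5, abs=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            weighted_fractional_rank([1.0, 2.0], [1.0, 0.0])


class TestConcentrationIndex:
    def test_pro_poor_sign_convention(self):
        # poorest two immunized -> concentration among the poor -> C < 0
        wealth = np.array([1.0, 2.0, 3.0, 4.0])
        h = np.array([1.0, 1.0, 0.0, 0.0])
        w = np.ones(4)
        r = weighted_fractional_rank(wealth, w)
        assert vq.concentration_index(h, r, w) < 0

    def test_alternating_case_matches_curve_area_oracle(self):
        wealth = np.array([1.0, 2.0, 3.0, 4.0])
        h = np.array([0.0, 1.0, 0.0, 1.0])
        w = np.ones(4)
        r = weighted_fractional_rank(wealth, w)
        c = vq.concentration_index(h, r, w)
        assert c == pytest.approx(
            curve_area_concentration_index(h, wealth, w), abs=1e-10
        )

    def test_covariance_formula_agrees_with_curve_area(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            h, wealth, w = random_instance(rng, n)
            r = weighted_fractional_rank(wealth, w)
            c = vq.concentration_index(h, r, w)
            oracle = curve_area_concentration_index(h, wealth, w)
            assert c == pytest.approx(oracle, abs=1e-8)

    def test_record_order_invariance(self, rng):
        h, wealth, w = random_instance(rng, 19)
        r = weighted_fractional_rank(wealth, w)
        perm = rng.permutation(19)
        assert vq.concentration_index(h[perm], r[perm], w[perm]) == pytest.approx(
            vq.concentration_index(h, r, w)
        )

    def test_degenerate_outcome_errors(self):
        w = np.ones(3)
        r = weighted_fractional_rank([1.0, 2.0, 3.0], w)
        with pytest.raises(DegenerateOutcomeError):
            vq.concentration_index(np.zeros(3), r, w)
        with pytest.raises(DegenerateOutcomeError):
            vq.concentration_index(np.ones(3), r, w)

    def test_bounds_mu_minus_one_to_one_minus_mu(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            h, wealth, w = random_instance(rng, n)
            r = weighted_fractional_rank(wealth, w)
            mu = float((w / w.sum()) @ h)
            c = vq.concentration_index(h, r, w)
            assert mu - 1.0 - 1e-12 <= c <= 1.0 - mu + 1e-12


class TestBoundsCorrections:
    # national rows of the published 43-country table: (mu, W, printed E)
    TABLE_ROWS = [
        ("Angola", 0.282, 0.410, 0.333),
        ("Armenia", 0.889, -0.162, -0.064),
        ("Pakistan", 0.675, 0.332, 0.291),
        ("Rwanda", 0.948, 0.128, 0.025),
    ]

    @pytest.mark.parametrize("name, mu, w, e_printed", TABLE_ROWS)
    def test_erreygers_from_published_mu_and_wagstaff(self, name, mu, w, e_printed):
        """Recovering C from W and applying the Erreygers correction must
        reproduce the published E (inputs are rounded to 3 dp, so agreement
        is to within one unit in the last printed digit)."""
        c = w * (1.0 - mu)
        e = vq.erreygers_index(c, mu)
        assert e == pytest.approx(e_printed, abs=1e-3)

    def test_wagstaff_zero_and_upper_bound(self):
        assert vq.wagstaff_index(0.0, 0.3) == 0.0
        mu = 0.3
        assert vq.wagstaff_index(1.0 - mu, mu) == pytest.approx(1.0)

    def test_erreygers_zero(self):
        assert vq.erreygers_index(0.0, 0.7) == 0.0

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_mean_rejected(self, mu):
        with pytest.raises(DegenerateOutcomeError):
            vq.wagstaff_index(0.1, mu)
        with pytest.raises(DegenerateOutcomeError):
            vq.erreygers_index(0.1, mu)

    @given(
        c=st.floats(-0.4, 0.4),
        mu=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, derandomize=True)
    def test_identity_e_equals_4mu_1mu_w(self, c, mu):
        w = vq.wagstaff_index(c, mu)
        e = vq.erreygers_index(c, mu)
        assert abs(e - 4.0 * mu * (1.0 - mu) * w) < 1e-10


class TestMirrorAndReversal:
    def test_mirror_property_negates_indices(self, rng):
        for _ in range(20):
            h, wealth, w = random_instance(rng, 25)
            r = weighted_fractional_rank(wealth, w)
            mu = float((w / w.sum()) @ h)
            c = vq.concentration_index(h, r, w)
            c_m = vq.concentration_index(1.0 - h, r, w)
            # binary mirror: C(1-h)*(1-mu) = -C(h)*mu, so E is exactly negated
            e = vq.erreygers_index(c, mu)
            e_m = vq.erreygers_index(c_m, 1.0 - mu)
            assert e_m == pytest.approx(-e, abs=1e-10)
            w_idx = vq.wagstaff_index(c, mu)
            w_m = vq.wagstaff_index(c_m, 1.0 - mu)
            assert w_m == pytest.approx(-w_idx, abs=1e-10)

    def test_reversing_wealth_order_negates_indices(self, rng):
        h, wealth, w = random_instance(rng, 33)
        r = weighted_fractional_rank(wealth, w)
        r_rev = weighted_fractional_rank(-wealth, w)
        c = vq.concentration_index(h, r, w)
        c_rev = vq.concentration_index(h, r_rev, w)
        assert c_rev == pytest.approx(-c, abs=1e-10)


class TestIndexInference:
    def test_perfect_pro_rich_separation_attains_one(self):
        n = 20
        wealth = np.arange(n, dtype=float)
        h = (wealth >= n / 2).astype(float)  # all rich immunized, poor not
        w = np.ones(n)
        r = weighted_fractional_rank(wealth, w)
        res = index_inference(h, r, w, psu_ids=np.arange(n) % 4)
        assert res.wagstaff == pytest.approx(1.0, abs=1e-6)
        assert res.erreygers == pytest.approx(1.0, abs=1e-6)

    def test_matches_statsmodels_cluster_robust(self, rng):
        """Cross-check the hand-rolled CR sandwich against statsmodels WLS."""
        import statsmodels.api as sm

        h, wealth, w = random_instance(rng, 200)
        psu = rng.integers(0, 12, size=200)
        r = weighted_fractional_rank(wealth, w)
        res = index_inference(h, r, w, psu)
        wn = w / w.sum()
        mu = float(wn @ h)
        var_r = float(wn @ (r - wn @ r) ** 2)
        y = (2.0 * var_r / (mu * (1.0 - mu))) * h
        X = sm.add_constant(r)
        fit = sm.WLS(y, X, weights=wn).fit(
            cov_type="cluster", cov_kwds={"groups": psu}
        )
        assert fit.params[1] == pytest.approx(res.wagstaff, abs=1e-8)
        assert fit.bse[1] == pytest.approx(res.se_w, rel=1e-6)

    def test_single_psu_falls_back_with_warning(self, caplog):
        wealth = np.arange(10.0)
        h = np.array([0, 0, 1, 0, 1, 0, 1, 1, 1, 1], float)
        w = np.ones(10)
        r = weighted_fractional_rank(wealth, w)
        with caplog.at_level(logging.WARNING):
            res = index_inference(h, r, w, psu_ids=np.zeros(10, int))
        assert "single PSU" in caplog.text
        assert np.isfinite(res.se_w) and res.se_w > 0
        assert res.n_clusters == 1

    def test_bounds_bracket_point_estimates(self, rng):
        h, wealth, w = random_instance(rng, 60)
        r = weighted_fractional_rank(wealth, w)
        res = index_inference(h, r, w, rng.integers(0, 6, 60))
        assert res.lower_w < res.wagstaff < res.upper_w
        assert res.lower_e < res.erreygers < res.upper_e
        assert abs(
            res.erreygers - 4 * res.mu * (1 - res.mu) * res.wagstaff
        ) < 1e-10


class TestTheil:
    def test_two_group_hand_example(self):
        td = vq.theil_decompose([0.2, 0.2, 0.4, 0.4], ["A", "A", "B", "B"])
        expected = 0.5 * ((2 / 3) * np.log(2 / 3) + (4 / 3) * np.log(4 / 3))
        assert td.total == pytest.approx(expected, abs=1e-12)
        assert td.total == pytest.approx(0.0566, abs=5e-4)
        assert td.within == pytest.approx(0.0, abs=1e-12)
        assert td.between == pytest.approx(td.total, abs=1e-12)

    def test_perfect_equality_is_zero(self):
        td = vq.theil_decompose([0.7, 0.7, 0.7], ["A", "A", "B"])
        assert td.total == pytest.approx(0.0, abs=1e-15)
        assert td.within == pytest.approx(0.0, abs=1e-15)
        assert td.between == pytest.approx(0.0, abs=1e-15)

    def test_single_group_all_within(self, rng):
        x = rng.uniform(0.1, 0.9, size=12)
        td = vq.theil_decompose(x, ["A"] * 12)
        assert td.between == pytest.approx(0.0, abs=1e-15)
        assert td.within == pytest.approx(td.total, abs=1e-15)

    def test_decomposition_identity_and_scale_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            x = rng.uniform(0.01, 1.0, size=n)
            g = rng.integers(0, 4, size=n)
            td = vq.theil_decompose(x, g)
            assert abs(td.total - (td.within + td.between)) < 1e-12
            td2 = vq.theil_decompose(7.3 * x, g)
            assert td2.total == pytest.approx(td.total, abs=1e-12)
            assert td.total >= -1e-15

    def test_zero_values_contribute_nothing(self):
        td = vq.theil_decompose([0.0, 0.5], ["A", "A"])
        assert np.isfinite(td.total)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            vq.theil_decompose([0.0, 0.0], ["A", "B"])
        with pytest.raises(ValidationError):
            vq.theil_decompose([-0.1, 0.5], ["A", "B"])

    def test_weighted_option_reduces_to_unweighted(self, rng):
        x = rng.uniform(0.1, 1.0, size=10)
        g = ["A"] * 5 + ["B"] * 5
        a = vq.theil_decompose(x, g)
        b = vq.theil_decompose(x, g, weights=np.full(10, 3.0))
        assert b.total == pytest.approx(a.total, abs=1e-12)
        assert b.within == pytest.approx(a.within, abs=1e-12)
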