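import numpy as np
import pytest
from scipy import stats as sps

from ivmr import (
    CollinearityError,
    EmptyInstrumentError,
    InsufficientInstrumentsError,
    MendelianRandomization,
    UndefinedRatioError,
    cochran_q,
    exclude_variants,
    harmonize,
    instrument_strength,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from ivmr.models import _weighted_median


def make_model(bx, sx, by, sy, **kw):
    return MendelianRandomization(bx, sx, by, sy, **kw)


def random_model(rng, j=None):
    j = j or rng.integers(2, 10)
    return make_model(
        rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j),
        rng.uniform(0.005, 0.05, j),
        rng.normal(0, 0.1, j),
        rng.uniform(0.005, 0.1, j),
    )


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        res = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.04)

    def test_null_numerator(self):
        assert wald_ratio(0.5, 0.05, 0.0, 0.02).beta == 0.0

    def test_negative_exposure_effect_keeps_se_positive(self):
        res = wald_ratio(-0.5, 0.05, 0.1, 0.02)
        assert res.beta == pytest.approx(-0.2)
        assert res.se == pytest.approx(0.04)

    def test_zero_exposure_effect_undefined(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_second_order_se_adds_exposure_term(self):
        first = wald_ratio(0.5, 0.05, 0.1, 0.02)
        second = wald_ratio(0.5, 0.05, 0.1, 0.02, second_order=True)
        expected = np.sqrt(0.02**2 / 0.5**2 + 0.1**2 * 0.05**2 / 0.5**4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se

    def test_ci_brackets_point_estimate(self):
        res = wald_ratio(0.5, 0.05, 0.1, 0.02)
        lo, hi = res.or_conf_int()
        assert lo == pytest.approx(np.exp(res.beta - 1.96 * res.se))
        assert hi == pytest.approx(np.exp(res.beta + 1.96 * res.se))
        assert lo <= res.odds_ratio <= hi


class TestIVW:
    def test_equal_weight_ratios_average(self):
        model = make_model([1.0, 1.0], [0.1, 0.1], [0.1, 0.3], [1.0, 1.0])
        assert model.fit("ivw_fixed").beta == pytest.approx(0.2)

    def test_single_record_collapses_to_wald(self):
        m = make_model([0.4], [0.03], [0.08], [0.015])
        fixed = m.fit("ivw_fixed")
        wald = m.fit("wald")
        assert fixed.beta == pytest.approx(wald.beta, abs=0)
        assert fixed.se == pytest.approx(wald.se, abs=0)

    def test_matches_wls_through_origin_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(200):
            m = random_model(rng)
            res = m.fit("ivw_fixed")
            wls = sm.WLS(m.beta_outcome, m.beta_exposure, weights=1 / m.se_outcome**2).fit()
            assert res.beta == pytest.approx(wls.params[0], rel=1e-10)

    def test_fixed_equals_meta_analysis_of_wald_ratios(self, rng):
        """IVW is the inverse-variance combination of per-variant ratios."""
        m = random_model(rng, j=6)
        ratios = m.ratio_estimates()
        w = m.ivw_weights()
        assert m.fit("ivw_fixed").beta == pytest.approx(np.sum(w * ratios) / np.sum(w))
        assert m.fit("ivw_fixed").se == pytest.approx(1 / np.sqrt(np.sum(w)))

    def test_random_multiplicative_inflates_never_deflates(self, rng):
        for _ in range(20):
            m = random_model(rng)
            assert m.fit("ivw_random_mult").se >= m.fit("ivw_fixed").se

    def test_random_multiplicative_needs_two(self):
        m = make_model([0.4], [0.03], [0.08], [0.015])
        with pytest.raises(InsufficientInstrumentsError):
            m.fit("ivw_random_mult")

    def test_empty_instrument_rejected(self):
        with pytest.raises(EmptyInstrumentError):
            make_model([], [], [], [])

    def test_scale_equivariance(self, rng):
        m = random_model(rng, j=5)
        c = 3.7
        scaled = make_model(
            m.beta_exposure * c, m.se_exposure * c, m.beta_outcome, m.se_outcome
        )
        for method in ("ivw_fixed", "ivw_random_mult", "egger"):
            assert scaled.fit(method).beta == pytest.approx(
                m.fit(method).beta / c, rel=1e-12
            )
        assert scaled.fit("weighted_median", seed=1).beta == pytest.approx(
            m.fit("weighted_median", seed=1).beta / c, rel=1e-12
        )

    def test_sign_equivariance(self, rng):
        m = random_model(rng, j=5)
        neg = make_model(
            m.beta_exposure, m.se_exposure, -m.beta_outcome, m.se_outcome
        )
        for method in ("ivw_fixed", "ivw_random_mult", "egger"):
            a, b = m.fit(method), neg.fit(method)
            assert b.beta == pytest.approx(-a.beta, rel=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-12)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        m = make_model([0.5, 0.5], [0.01, 0.01], [0.1, 0.1], [0.02, 0.02])
        q, p = cochran_q(m)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # ratios 0.1 and 0.3, both with weight bx^2/sy^2 = 100:
        # Q = 100*(0.1-0.2)^2 + 100*(0.3-0.2)^2 = 2.0
        m = make_model([1.0, 1.0], [0.1, 0.1], [0.1, 0.3], [0.1, 0.1])
        q, _ = cochran_q(m)
        assert q == pytest.approx(2.0)

    def test_undefined_below_two_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(make_model([0.5], [0.01], [0.1], [0.02]))

    def test_null_distribution_is_chi_square(self, rng):
        """Under a true fixed effect, Q ~ chi2(J-1) (KS on 2000 replicates)."""
        j, theta = 5, 0.1
        bx = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        sy = np.full(j, 0.02)
        qs = np.empty(2000)
        for i in range(2000):
            by = rng.normal(theta * bx, sy)
            qs[i] = cochran_q(make_model(bx, np.full(j, 1e-8), by, sy))[0]
        assert sps.kstest(qs, "chi2", args=(j - 1,)).pvalue > 0.01


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        m = make_model(
            [1.0, 1.0, 1.0], [0.1] * 3, [0.1, 0.2, 0.9], [1.0] * 3
        )
        assert m.fit("weighted_median", seed=0).beta == pytest.approx(0.2)

    def test_concentrated_weight_tracks_dominant_variant(self):
        w = np.array([0.98, 0.01, 0.01])
        # bx^2/sy^2 proportional to w with sy=1
        bx = np.sqrt(w)
        by = bx * np.array([0.5, -1.0, 2.0])  # dominant ratio 0.5
        m = make_model(bx, [0.01] * 3, by, [1.0] * 3)
        assert m.fit("weighted_median", seed=0).beta == pytest.approx(0.5, abs=0.05)

    def test_within_gap_of_l1_grid_search_oracle(self, rng):
        """The interpolated weighted median and the brute-force minimiser of
        the weighted L1 objective both lie between the order statistics
        bracketing cumulative weight 1/2."""
        for _ in range(20):
            m = random_model(rng, j=9)
            ratios, weights = m.ratio_estimates(), m.ivw_weights()
            est = _weighted_median(ratios, weights)
            grid = np.linspace(ratios.min(), ratios.max(), 4001)
            obj = [np.sum(weights * np.abs(ratios - g)) for g in grid]
            l1 = grid[int(np.argmin(obj))]
            gap = np.max(np.diff(np.sort(ratios)))
            assert abs(est - l1) <= gap + 1e-9

    def test_bootstrap_se_is_seeded(self):
        m = make_model(
            [0.3, 0.2, 0.1], [0.02] * 3, [0.06, 0.04, 0.02], [0.01] * 3
        )
        a = m.fit("weighted_median", seed=42)
        b = m.fit("weighted_median", seed=42)
        assert a.se == b.se

    def test_needs_three_variants(self):
        m = make_model([0.3, 0.2], [0.02] * 2, [0.06, 0.04], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            m.fit("weighted_median")


class TestMREgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        m = make_model(bx, [0.01] * 4, 0.5 * bx, [0.02] * 4)
        res = m.fit("egger")
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_exact_line_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        m = make_model(bx, [0.01] * 4, 0.02 + 0.5 * bx, [0.02] * 4)
        res = m.fit("egger")
        assert res.intercept == pytest.approx(0.02, abs=1e-12)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        bx = rng.uniform(0.05, 0.4, 8)
        # noise well above the nominal SEs so the overdispersion factor
        # exceeds 1 and both routes estimate the same residual scale
        by = 0.03 + 0.4 * bx + rng.normal(0, 0.05, 8)
        sy = np.full(8, 0.01)
        m = make_model(bx, np.full(8, 0.01), by, sy)
        res = m.fit("egger")
        wls = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert res.beta == pytest.approx(wls.params[1], rel=1e-10)
        assert res.intercept == pytest.approx(wls.params[0], rel=1e-10)
        assert res.se == pytest.approx(wls.bse[1], rel=1e-10)
        assert res.intercept_se == pytest.approx(wls.bse[0], rel=1e-10)

    def test_orientation_invariance(self, rng):
        m = random_model(rng, j=6)
        flip = rng.choice([-1.0, 1.0], 6)
        flipped = make_model(
            m.beta_exposure * flip, m.se_exposure, m.beta_outcome * flip, m.se_outcome
        )
        a, b = m.fit("egger"), flipped.fit("egger")
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_uses_t_distribution(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        rng = np.random.default_rng(7)
        m = make_model(bx, [0.01] * 5, 0.3 * bx + rng.normal(0, 0.05, 5), [0.02] * 5)
        res = m.fit("egger")
        expected = 2 * sps.t.sf(abs(res.beta / res.se), 3)
        assert res.pvalue == pytest.approx(expected)

    def test_collinearity_error(self):
        m = make_model([0.2, -0.2, 0.2], [0.01] * 3, [0.1, -0.1, 0.1], [0.02] * 3)
        with pytest.raises(CollinearityError):
            m.fit("egger")

    def test_needs_three_variants(self):
        m = make_model([0.3, 0.2], [0.02] * 2, [0.06, 0.04], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            m.fit("egger")


class TestInstrumentStrength:
    def test_f_is_squared_z(self):
        import pandas as pd

        df = pd.DataFrame({"beta": [0.1, 0.02], "se": [0.01, 0.02]})
        strength = instrument_strength(df)
        assert dict(strength.per_variant_f)["snp1"] == pytest.approx(100.0)
        assert dict(strength.per_variant_f)["snp2"] == pytest.approx(1.0)
        assert strength.min_f == pytest.approx(1.0)

    def test_aggregate_f_formula(self):
        import pandas as pd

        df = pd.DataFrame(
            {"beta": [0.3, 0.2], "se": [0.02, 0.02], "eaf": [0.3, 0.4]}
        )
        strength = instrument_strength(df, n=1000)
        r2 = 2 * 0.3 * 0.7 * 0.09 + 2 * 0.4 * 0.6 * 0.04
        assert strength.r2_total == pytest.approx(r2)
        assert strength.f_aggregate == pytest.approx(
            r2 * (1000 - 2 - 1) / ((1 - r2) * 2)
        )


class TestExcludeVariants:
    def _nine_variant_instrument(self, concordant=None):
        rng = np.random.default_rng(5)
        from ivmr import SummaryStats, VariantAssociation, InstrumentSpec

        ids = [f"rs{i}" for i in range(9)]
        exp = SummaryStats.from_records(
            [
                VariantAssociation(v, "A", "G", rng.uniform(0.1, 0.3), 0.02, eaf=0.3)
                for v in ids
            ]
        )
        out = SummaryStats.from_records(
            [
                VariantAssociation(v, "A", "G", rng.normal(0, 0.02), 0.01, eaf=0.3)
                for v in ids
            ]
        )
        return harmonize(InstrumentSpec("AA", tuple(ids)), exp, out)

    def test_nine_minus_one_leaves_eight(self):
        h = self._nine_variant_instrument()
        reduced = exclude_variants(h, ["rs4"])
        assert reduced.n_snps == 8
        assert ("rs4", "sensitivity_exclusion") in reduced.exclusions

    def test_absent_id_warns_and_leaves_unchanged(self):
        h = self._nine_variant_instrument()
        with pytest.warns(UserWarning, match="rs999"):
            same = exclude_variants(h, ["rs999"])
        assert same.n_snps == h.n_snps

    def test_excluding_all_is_error(self):
        h = self._nine_variant_instrument()
        with pytest.raises(EmptyInstrumentError):
            exclude_variants(h, [f"rs{i}" for i in range(9)])
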