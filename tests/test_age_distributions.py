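"""Closed-form equilibrium age mathematics and scheme conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from borealref import (
    AgeClassDistribution,
    AgeClassScheme,
    DisturbanceRegime,
    InvalidParameterError,
    RebinError,
    SchemeMismatchError,
    age_class_shares,
    average_distributions,
    interval_fraction_below_mean,
    rebin,
    survivor_fraction,
)

# independently verified by numerical integration of the Weibull density
# (scipy.integrate.quad of the mean-parameterised pdf up to t = 110)
WEIBULL2_L100_T110 = 0.3866127326862091

regimes = st.one_of(
    st.builds(
        DisturbanceRegime,
        st.just("negative_exponential"),
        st.floats(5.0, 500.0),
    ),
    st.builds(
        DisturbanceRegime,
        st.just("weibull"),
        st.floats(5.0, 500.0),
        st.floats(0.3, 6.0),
    ),
)


class TestSurvivorFraction:
    @pytest.mark.parametrize(
        "regime, t, expected",
        [
            (DisturbanceRegime("negative_exponential", 50.0), 100.0, 0.1353352832),
            (DisturbanceRegime("negative_exponential", 100.0), 0.0, 1.0),
            (DisturbanceRegime("weibull", 77.0, shape=3.0), 0.0, 1.0),
            (DisturbanceRegime("weibull", 100.0, shape=2.0), 110.0, WEIBULL2_L100_T110),
        ],
    )
    def test_known_values(self, regime, t, expected):
        assert survivor_fraction(regime, t) == pytest.approx(expected, abs=1e-9)

    def test_weibull_matches_scipy_frozen_distribution(self):
        """Cross-check against scipy.stats.weibull_min with matching mean."""
        for c in (0.8, 1.5, 2.0, 3.5):
            regime = DisturbanceRegime("weibull", 120.0, shape=c)
            ref = stats.weibull_min(c, scale=regime.weibull_scale)
            assert ref.mean() == pytest.approx(120.0, rel=1e-12)
            t = np.array([0.0, 30.0, 120.0, 250.0])
            np.testing.assert_allclose(survivor_fraction(regime, t), ref.sf(t), rtol=1e-12)

    @given(lam=st.floats(5.0, 500.0), t=st.floats(0.0, 1000.0))
    def test_weibull_shape_one_is_exponential(self, lam, t):
        exp = DisturbanceRegime("negative_exponential", lam)
        wb = DisturbanceRegime("weibull", lam, shape=1.0)
        assert survivor_fraction(wb, t) == pytest.approx(survivor_fraction(exp, t), rel=1e-12)

    @given(regime=regimes, t1=st.floats(0.0, 500.0), t2=st.floats(0.0, 500.0))
    def test_monotone_decreasing_from_one(self, regime, t1, t2):
        lo, hi = sorted((t1, t2))
        assert survivor_fraction(regime, 0.0) == 1.0
        assert survivor_fraction(regime, lo) >= survivor_fraction(regime, hi)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family": "negative_exponential", "mean_return_interval": 0.0},
            {"family": "negative_exponential", "mean_return_interval": -10.0},
            {"family": "weibull", "mean_return_interval": 100.0, "shape": 0.0},
            {"family": "lognormal", "mean_return_interval": 100.0},
        ],
    )
    def test_invalid_regimes_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DisturbanceRegime(**kwargs)

    def test_negative_age_rejected(self):
        with pytest.raises(InvalidParameterError):
            survivor_fraction(DisturbanceRegime("negative_exponential", 50.0), -1.0)


class TestIntervalFractionBelowMean:
    def test_exponential_classic_split(self):
        regime = DisturbanceRegime("negative_exponential", 123.0)
        frac = interval_fraction_below_mean(regime)
        assert frac == pytest.approx(0.6321205588, abs=1e-9)
        assert 1.0 - frac == pytest.approx(0.3678794412, abs=1e-9)

    def test_independent_of_mean(self):
        vals = {
            interval_fraction_below_mean(DisturbanceRegime("negative_exponential", lam))
            for lam in (10.0, 100.0, 400.0)
        }
        assert len(vals) == 1

    def test_weibull_concentration_monte_carlo(self):
        """As shape grows the interval distribution concentrates at its
        mean and the below-mean fraction falls from 0.632 toward the
        asymptote 1 − exp(−e^{−γ}) ≈ 0.430; check the closed form
        against a seeded sampling oracle."""
        prev = interval_fraction_below_mean(DisturbanceRegime("negative_exponential", 100.0))
        rng = np.random.default_rng(42)
        for c in (2.0, 5.0, 20.0):
            regime = DisturbanceRegime("weibull", 100.0, shape=c)
            frac = interval_fraction_below_mean(regime)
            assert frac < prev
            prev = frac
            draws = stats.weibull_min(c, scale=regime.weibull_scale).rvs(
                200_000, random_state=rng
            )
            mc = float((draws < 100.0).mean())
            assert frac == pytest.approx(mc, abs=3 * np.sqrt(0.25 / 200_000) + 1e-3)
        asymptote = 1.0 - np.exp(-np.exp(-np.euler_gamma))
        assert interval_fraction_below_mean(
            DisturbanceRegime("weibull", 100.0, shape=200.0)
        ) == pytest.approx(asymptote, abs=5e-3)


class TestAgeClassShares:
    def test_exponential_closed_forms(self):
        scheme110 = AgeClassScheme((0.0, 110.0))
        d = age_class_shares(DisturbanceRegime("negative_exponential", 100.0), scheme110)
        assert d.shares[0] == pytest.approx(1.0 - np.exp(-1.1), abs=1e-12)
        assert d.shares[1] == pytest.approx(np.exp(-1.1), abs=1e-12)

        scheme100 = AgeClassScheme((0.0, 100.0))
        d = age_class_shares(DisturbanceRegime("negative_exponential", 50.0), scheme100)
        assert round(d.shares[0], 3) == 0.865
        assert round(d.shares[1], 3) == 0.135

    def test_single_bin_collects_everything(self):
        d = age_class_shares(
            DisturbanceRegime("weibull", 80.0, shape=2.5), AgeClassScheme((0.0,))
        )
        assert d.shares == (1.0,)

    @given(
        regime=regimes,
        cuts=st.lists(st.floats(1.0, 400.0), min_size=1, max_size=6, unique=True),
    )
    def test_shares_sum_to_one(self, regime, cuts):
        scheme = AgeClassScheme(tuple([0.0] + sorted(cuts)))
        d = age_class_shares(regime, scheme)
        assert sum(d.shares) == pytest.approx(1.0, abs=1e-9)
        assert all(s >= 0 for s in d.shares)


class TestAverageDistributions:
    scheme = AgeClassScheme((0.0, 110.0))

    def test_idempotent_and_symmetric(self):
        d = AgeClassDistribution(self.scheme, (0.7, 0.3))
        assert average_distributions([d, d]).shares == pytest.approx((0.7, 0.3))
        a = AgeClassDistribution(self.scheme, (1.0, 0.0))
        b = AgeClassDistribution(self.scheme, (0.0, 1.0))
        assert average_distributions([a, b], (0.5, 0.5)).shares == pytest.approx((0.5, 0.5))

    def test_two_model_average_closed_form(self):
        """The even-aged reference construction: negative exponential and
        Weibull (shape 2), both with a 100-year cycle, averaged on the
        110-year split."""
        ne = age_class_shares(DisturbanceRegime("negative_exponential", 100.0), self.scheme)
        wb = age_class_shares(DisturbanceRegime("weibull", 100.0, shape=2.0), self.scheme)
        avg = average_distributions([ne, wb])
        expected_old = 0.5 * (np.exp(-1.1) + WEIBULL2_L100_T110)
        assert avg.shares[1] == pytest.approx(expected_old, abs=1e-9)
        assert avg.shares[0] == pytest.approx(1.0 - expected_old, abs=1e-9)

    def test_scheme_mismatch_rejected(self):
        a = AgeClassDistribution(self.scheme, (0.5, 0.5))
        b = AgeClassDistribution(AgeClassScheme((0.0, 75.0)), (0.5, 0.5))
        with pytest.raises(SchemeMismatchError):
            average_distributions([a, b])

    def test_bad_weights_rejected(self):
        a = AgeClassDistribution(self.scheme, (0.5, 0.5))
        with pytest.raises(InvalidParameterError):
            average_distributions([a, a], (0.9, 0.9))


class TestRebin:
    three_class = AgeClassScheme((0.0, 75.0, 150.0))

    def test_reference_split_at_110(self):
        """25/25/50 on the 75/150 classes re-binned at 110 gives the
        case-study 36.7/13.3/50 split (13 % mid-aged after rounding)."""
        d = AgeClassDistribution(self.three_class, (0.25, 0.25, 0.50))
        out = rebin(d, AgeClassScheme((0.0, 110.0, 150.0)))
        assert out.shares[1] == pytest.approx(0.25 * 40 / 75, abs=1e-12)
        assert round(100 * out.shares[1]) == 13
        assert out.shares[0] == pytest.approx(0.25 + 0.25 * 35 / 75, abs=1e-12)
        assert out.shares[2] == pytest.approx(0.50, abs=1e-12)

    def test_identity_and_midpoint_split(self):
        d = AgeClassDistribution(self.three_class, (0.2, 0.3, 0.5))
        assert rebin(d, self.three_class).shares == pytest.approx(d.shares)
        one = AgeClassDistribution(AgeClassScheme((0.0, 100.0)), (1.0, 0.0))
        halves = rebin(one, AgeClassScheme((0.0, 50.0, 100.0)))
        assert halves.shares == pytest.approx((0.5, 0.5, 0.0))

    def test_unbounded_bin_cannot_be_split(self):
        d = AgeClassDistribution(self.three_class, (0.25, 0.25, 0.50))
        with pytest.raises(RebinError):
            rebin(d, AgeClassScheme((0.0, 75.0, 200.0)))

    @given(
        shares=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        cut=st.floats(5.0, 145.0),
    )
    @settings(max_examples=50)
    def test_mass_conserved(self, shares, cut):
        total = sum(shares)
        d = AgeClassDistribution(self.three_class, tuple(s / total for s in shares))
        new = AgeClassScheme(tuple(sorted({0.0, float(cut), 150.0})))
        out = rebin(d, new)
        assert sum(out.shares) == pytest.approx(1.0, abs=1e-9)

    def test_superset_boundaries_roundtrip_exactly(self):
        d = AgeClassDistribution(self.three_class, (0.25, 0.25, 0.50))
        fine = AgeClassScheme((0.0, 30.0, 75.0, 110.0, 150.0))
        back = rebin(rebin(d, fine), self.three_class)
        assert back.shares == pytest.approx(d.shares, abs=1e-12)


class TestSchemeAndDistributionValidation:
    def test_scheme_invariants(self):
        with pytest.raises(InvalidParameterError):
            AgeClassScheme((10.0, 75.0))  # must start at 0
        with pytest.raises(InvalidParameterError):
            AgeClassScheme((0.0, 75.0, 75.0))  # strictly increasing
        assert AgeClassScheme((0.0, 75.0, 150.0)).labels == ("0-74", "75-149", "150+")

    def test_distribution_must_sum_to_one(self):
        scheme = AgeClassScheme((0.0, 75.0))
        with pytest.raises(InvalidParameterError):
            AgeClassDistribution(scheme, (0.5, 0.6))

    def test_share_at_or_above_splits_uniformly(self):
        d = AgeClassDistribution(AgeClassScheme((0.0, 75.0, 150.0)), (0.25, 0.25, 0.50))
        assert d.share_at_or_above(110.0) == pytest.approx(0.25 * 40 / 75 + 0.5)
        assert d.share_at_or_above(0.0) == pytest.approx(1.0)
        with pytest.raises(RebinError):
            d.share_at_or_above(200.0)
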