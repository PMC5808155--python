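"""Hill-curve evaluation, closed-form inversion, and constrained pair fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isobole import CurvePair, HillCurve, fit_pair, hill_inverse, hill_response

SQRT73 = math.sqrt(7.0 / 3.0)


curve_strategy = st.builds(
    HillCurve,
    y0=st.just(1.0),
    y_inf=st.floats(0.0, 0.4),
    e=st.floats(0.1, 10.0),
    s=st.floats(0.3, 6.0),
)


class TestHillResponse:
    @pytest.mark.parametrize(
        "params, x, expected",
        [
            ((1, 0, 1, 2), 0.0, 1.0),          # zero dose returns y0
            ((1, 0, 1, 2), 1.0, 0.5),          # x = e is half-maximal
            ((1, 0, 1, 2), SQRT73, 0.3),       # solves 1/(1+x^2) = 0.3
            ((1, 0, 1, 2), np.inf, 0.0),       # infinite dose hits asymptote
            ((1, 0.3, 1, 1), np.inf, 0.3),
        ],
    )
    def test_values(self, params, x, expected):
        curve = HillCurve(*params)
        assert hill_response(curve, x) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hill_response(HillCurve(1, 0, 1, 2), -0.5)

    def test_vectorized(self):
        curve = HillCurve(1, 0, 2, 2)
        out = hill_response(curve, np.array([0.0, 2.0, np.inf]))
        np.testing.assert_allclose(out, [1.0, 0.5, 0.0], atol=1e-12)


class TestHillInverse:
    @pytest.mark.parametrize(
        "params, y, expected",
        [
            ((1, 0, 2, 2), 0.5, 2.0),          # half-maximal maps to e
            ((1, 0, 1, 2), 0.3, SQRT73),
            ((1, 0, 1, 2), 1.0, 0.0),          # y0 maps to zero dose
            ((1, 0.3, 1, 1), 0.2, np.inf),     # below asymptote: unreachable
            ((1, 0.3, 1, 1), 0.3, np.inf),
        ],
    )
    def test_values(self, params, y, expected):
        curve = HillCurve(*params)
        assert hill_inverse(curve, y) == pytest.approx(expected, abs=1e-12)

    def test_above_y0_rejected(self):
        with pytest.raises(ValueError):
            hill_inverse(HillCurve(1, 0, 1, 2), 1.2)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(curve=curve_strategy, frac=st.floats(1e-6, 1 - 1e-6))
    def test_round_trip(self, curve, frac):
        y = curve.y_inf + frac * (curve.y0 - curve.y_inf)
        x = hill_inverse(curve, y)
        assert abs(hill_response(curve, x) - y) < 1e-10 * (curve.y0 - curve.y_inf)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(curve=curve_strategy, x=st.floats(1e-3, 50.0), bump=st.floats(1e-3, 10.0))
    def test_strictly_decreasing(self, curve, x, bump):
        assert hill_response(curve, x) > hill_response(curve, x + bump)


class TestCurveInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(y0=1, y_inf=0, e=-1, s=2),
            dict(y0=1, y_inf=0, e=1, s=0),
            dict(y0=0.2, y_inf=0.8, e=1, s=2),  # increasing orientation
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HillCurve(**kwargs)

    def test_pair_requires_shared_y0(self):
        with pytest.raises(ValueError):
            CurvePair(HillCurve(1, 0, 1, 2), HillCurve(0.9, 0, 1, 2))


class TestFitPair:
    def test_noiseless_recovery(self, fig_pair, geometric_doses):
        d = geometric_doses
        cond1 = np.column_stack([d, hill_response(fig_pair.curve1, d)])
        cond2 = np.column_stack([d, hill_response(fig_pair.curve2, d)])
        res = fit_pair(cond1, cond2)
        assert not res.excluded
        got = res.pair
        for curve, ref in ((got.curve1, fig_pair.curve1), (got.curve2, fig_pair.curve2)):
            assert curve.e == pytest.approx(ref.e, rel=1e-4)
            assert curve.s == pytest.approx(ref.s, rel=1e-4)
            assert curve.y0 == pytest.approx(ref.y0, rel=1e-4)
            assert abs(curve.y_inf - ref.y_inf) < 1e-4

    def test_increasing_series_excluded(self, geometric_doses):
        d = geometric_doses
        # four-parameter curve with s = -1 (y0=1, y_inf=0, e=1): rises with dose
        increasing = np.where(d > 0, d / (1.0 + d), 1.0)
        cond1 = np.column_stack([d, increasing])
        cond2 = np.column_stack([d, hill_response(HillCurve(1, 0, 2, 2), d)])
        res = fit_pair(cond1, cond2)
        assert res.excluded
        assert "slope" in res.reason

    def test_identical_series_fit_symmetric(self, geometric_doses):
        d = geometric_doses
        cond = np.column_stack([d, hill_response(HillCurve(1, 0.1, 1.5, 1.3), d)])
        res = fit_pair(cond, cond)
        assert res.pair.curve1.e == pytest.approx(res.pair.curve2.e, rel=1e-6)
        assert res.pair.curve1.s == pytest.approx(res.pair.curve2.s, rel=1e-6)

    def test_noisy_ec50_recovery(self, geometric_doses):
        """Median relative EC50 error stays moderate under realistic noise."""
        from isobole import make_pair

        d = geometric_doses
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pair = make_pair("both", rng)
            n1 = hill_response(pair.curve1, d) + rng.normal(0, 0.02, d.size)
            n2 = hill_response(pair.curve2, d) + rng.normal(0, 0.02, d.size)
            res = fit_pair(np.column_stack([d, n1]), np.column_stack([d, n2]))
            if res.pair is None:
                errs.append(np.nan)
                continue
            errs.append(
                max(
                    abs(res.pair.curve1.e - pair.curve1.e) / pair.curve1.e,
                    abs(res.pair.curve2.e - pair.curve2.e) / pair.curve2.e,
                )
            )
        assert np.nanmedian(errs) < 0.15

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 1.0], [1.0, 0.5], [2.0, 0.2]])
        with pytest.raises(ValueError):
            fit_pair(pts, pts)

    def test_determinism(self, geometric_doses):
        d = geometric_doses
        rng = np.random.default_rng(3)
        c1 = np.column_stack([d, hill_response(HillCurve(1, 0, 1, 2), d) + rng.normal(0, 0.02, d.size)])
        c2 = np.column_stack([d, hill_response(HillCurve(1, 0, 2, 2), d) + rng.normal(0, 0.02, d.size)])
        r1, r2 = fit_pair(c1, c2), fit_pair(c1, c2)
        assert r1.loss == r2.loss
        assert r1.pair.curve1.e == r2.pair.curve1.e
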