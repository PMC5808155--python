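"""Null reference surfaces: implicit general isobole equation, explicit
equivalent-dose surfaces, their mean, and isobole extraction."""

import numpy as np
import pytest

from isobole import (
    SolverConfig,
    SurfaceModel,
    MODEL_KINDS,
    explicit_1to2,
    explicit_2to1,
    explicit_mean,
    general_isobole,
    hill_inverse,
    hill_response,
    isoboles,
    make_pair,
    max_chord_deviation,
    surface,
    CurvePair,
    HillCurve,
)

Y_TOL = SolverConfig().y_tol


def random_grid(rng, pair, n=10):
    d1 = np.sort(np.concatenate([[0.0], rng.uniform(0, 4 * pair.curve1.e, n - 1)]))
    d2 = np.sort(np.concatenate([[0.0], rng.uniform(0, 4 * pair.curve2.e, n - 1)]))
    return d1, d2


class TestGeneralIsobole:
    def test_canonical_value(self, fig_pair):
        # proportional curves: the surface collapses to f1(x1 + x2*e1/e2)
        assert general_isobole(fig_pair, 1.0, 2.0) == pytest.approx(0.2, abs=5 * Y_TOL)

    def test_axes_exact(self, both_pair):
        assert general_isobole(both_pair, 0.0, 0.0) == both_pair.y0
        assert general_isobole(both_pair, 1.3, 0.0) == hill_response(both_pair.curve1, 1.3)
        assert general_isobole(both_pair, 0.0, 0.7) == hill_response(both_pair.curve2, 0.7)

    def test_sham_combination(self):
        """A compound combined with itself yields f1(x1 + x2)."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            c = HillCurve(1.0, float(rng.uniform(0, 0.4)),
                          float(np.exp(rng.uniform(np.log(0.25), np.log(4)))),
                          float(rng.uniform(0.5, 4)))
            pair = CurvePair(c, c)
            x1, x2 = rng.uniform(0.05, 4, 2)
            expected = hill_response(c, x1 + x2)
            assert general_isobole(pair, x1, x2) == pytest.approx(expected, abs=2 * Y_TOL)

    def test_unreachable_effect_fallback(self, max_effect_pair):
        # f2(x2) = 0.1 below y_inf,1 = 0.3: the surface equals f2(x2)
        x2 = hill_inverse(max_effect_pair.curve2, 0.1)
        for x1 in (0.0, 1.0, 5.0, 100.0):
            assert general_isobole(max_effect_pair, x1, x2) == pytest.approx(0.1, abs=1e-12)

    def test_negative_dose_rejected(self, fig_pair):
        with pytest.raises(ValueError):
            general_isobole(fig_pair, -1.0, 1.0)

    def test_matches_dense_scan(self):
        """Bisection agrees with a brute-force scan of the isobole equation."""
        rng = np.random.default_rng(7)
        scanned = 0
        while scanned < 5:
            pair = make_pair(("lacc", "slopes", "max_effect", "both")[int(rng.integers(4))], rng)
            x1, x2 = float(rng.uniform(0.01, 4)), float(rng.uniform(0.01, 4))
            if (hill_response(pair.curve2, x2) <= pair.curve1.y_inf
                    or hill_response(pair.curve1, x1) <= pair.curve2.y_inf):
                continue
            scanned += 1
            y0, floor = pair.y0, max(pair.curve1.y_inf, pair.curve2.y_inf)
            ys = np.linspace(floor + 1e-9, y0 - 1e-9, 10**5)
            g = (x1 / np.asarray(hill_inverse(pair.curve1, ys))
                 + x2 / np.asarray(hill_inverse(pair.curve2, ys)) - 1.0)
            y_scan = ys[np.argmin(np.abs(g))]
            assert general_isobole(pair, x1, x2) == pytest.approx(y_scan, abs=1e-4)

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(y_tol=0)
        with pytest.raises(ValueError):
            SolverConfig(max_iter=0)


class TestExplicitSurfaces:
    def test_canonical_values(self, fig_pair):
        assert explicit_2to1(fig_pair, 1.0, 2.0) == pytest.approx(0.2, abs=1e-12)
        assert explicit_1to2(fig_pair, 1.0, 2.0) == pytest.approx(0.2, abs=1e-12)
        assert explicit_mean(fig_pair, 1.0, 2.0) == pytest.approx(0.2, abs=1e-12)

    def test_axis_consistency(self, both_pair):
        assert explicit_2to1(both_pair, 1.4, 0.0) == pytest.approx(
            hill_response(both_pair.curve1, 1.4), abs=1e-12)
        assert explicit_mean(both_pair, 0.0, 0.0) == pytest.approx(both_pair.y0, abs=1e-12)

    def test_unreachable_effect_fallbacks(self, max_effect_pair):
        x2 = hill_inverse(max_effect_pair.curve2, 0.1)
        assert explicit_2to1(max_effect_pair, 5.0, x2) == pytest.approx(0.1, abs=1e-12)
        # the mean keeps its unequal-asymptote closed form
        f1x1 = hill_response(max_effect_pair.curve1, 5.0)
        manual = 0.5 * (0.1 + hill_response(
            max_effect_pair.curve2,
            hill_inverse(max_effect_pair.curve2, f1x1) + x2))
        assert explicit_mean(max_effect_pair, 5.0, x2) == pytest.approx(manual, abs=1e-12)

    def test_mirror_symmetry(self, both_pair):
        for x1, x2 in [(0.3, 1.2), (2.0, 0.1), (0.0, 0.0), (4.0, 4.0)]:
            assert explicit_1to2(both_pair, x1, x2) == pytest.approx(
                explicit_2to1(both_pair.swapped(), x2, x1), abs=1e-14)

    def test_mean_swap_symmetric(self, both_pair):
        for x1, x2 in [(0.3, 1.2), (2.0, 0.1), (1.0, 1.0)]:
            assert explicit_mean(both_pair, x1, x2) == pytest.approx(
                explicit_mean(both_pair.swapped(), x2, x1), abs=1e-14)

    def test_mean_between_explicit_surfaces(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            pair = make_pair("both", rng)
            x1, x2 = rng.uniform(0, 4, 2)
            a = explicit_2to1(pair, x1, x2)
            b = explicit_1to2(pair, x1, x2)
            m = explicit_mean(pair, x1, x2)
            assert min(a, b) <= m <= max(a, b)

    def test_geometric_variant(self, both_pair):
        a = explicit_2to1(both_pair, 1.0, 1.0)
        b = explicit_1to2(both_pair, 1.0, 1.0)
        assert explicit_mean(both_pair, 1.0, 1.0, "geometric") == pytest.approx(
            np.sqrt(a * b))
        with pytest.raises(ValueError):
            explicit_mean(both_pair, 1.0, 1.0, "harmonic")


class TestSurfaceGrid:
    def test_origin_only_grid(self, both_pair):
        mat = surface(SurfaceModel("mean", both_pair), [0.0], [0.0])
        assert mat.shape == (1, 1)
        assert mat[0, 0] == both_pair.y0

    def test_marginals_reproduced_all_kinds(self, both_pair):
        d1 = np.array([0.0, 0.3, 1.0, 3.0])
        d2 = np.array([0.0, 0.5, 2.0, 4.0])
        for kind in MODEL_KINDS:
            mat = surface(SurfaceModel(kind, both_pair), d1, d2)
            np.testing.assert_allclose(mat[:, 0], hill_response(both_pair.curve1, d1),
                                       atol=Y_TOL)
            np.testing.assert_allclose(mat[0, :], hill_response(both_pair.curve2, d2),
                                       atol=Y_TOL)

    def test_monotone_in_each_dose(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            pair = make_pair("both", rng)
            d1, d2 = random_grid(rng, pair)
            for kind in MODEL_KINDS:
                mat = surface(SurfaceModel(kind, pair), d1, d2)
                assert np.all(np.diff(mat, axis=0) <= Y_TOL)
                assert np.all(np.diff(mat, axis=1) <= Y_TOL)

    def test_models_coincide_under_lacc(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            pair = make_pair("lacc", rng)
            d1, d2 = random_grid(rng, pair)
            mats = [surface(SurfaceModel(k, pair), d1, d2)
                    for k in ("gi", "2to1", "1to2", "mean")]
            for i in range(len(mats)):
                for j in range(i + 1, len(mats)):
                    assert np.max(np.abs(mats[i] - mats[j])) < 5 * Y_TOL

    def test_models_diverge_when_lacc_violated(self, both_pair):
        d = np.linspace(0, 4, 20)
        gi = surface(SurfaceModel("gi", both_pair), d, d)
        mean = surface(SurfaceModel("mean", both_pair), d, d)
        assert np.max(np.abs(gi - mean)) > 0.01

    def test_unsorted_grid_rejected(self, fig_pair):
        with pytest.raises(ValueError):
            surface(SurfaceModel("gi", fig_pair), [1.0, 0.0], [0.0, 1.0])

    def test_unknown_kind_rejected(self, fig_pair):
        with pytest.raises(ValueError):
            SurfaceModel("bliss", fig_pair)


class TestIsoboles:
    def test_straight_parallel_under_lacc(self, fig_pair):
        d1 = np.linspace(0, 2.5, 201)
        d2 = np.linspace(0, 5.0, 201)
        cont = isoboles(SurfaceModel("gi", fig_pair), [0.3], d1, d2)
        (seg,) = cont[0.3]
        # endpoints on the axes at the conditional EC-level doses
        x1_star = hill_inverse(fig_pair.curve1, 0.3)
        x2_star = hill_inverse(fig_pair.curve2, 0.3)
        ends = np.array(sorted([seg[0], seg[-1]], key=lambda p: p[0]))
        np.testing.assert_allclose(ends[0], [0.0, x2_star], atol=1e-3)
        np.testing.assert_allclose(ends[1], [x1_star, 0.0], atol=1e-3)
        assert max_chord_deviation(seg) < 1e-3

    def test_gi_straight_but_explicit_curved_when_slopes_differ(self, slopes_pair):
        d = np.linspace(0, 4, 201)
        for level in (0.3, 0.5, 0.7):
            (gi_seg,) = isoboles(SurfaceModel("gi", slopes_pair), [level], d, d)[level]
            assert max_chord_deviation(gi_seg) < 1e-3
            for kind in ("2to1", "1to2"):
                (seg,) = isoboles(SurfaceModel(kind, slopes_pair), [level], d, d)[level]
                assert max_chord_deviation(seg) > 1e-3

    def test_unreachable_level_is_empty(self, max_effect_pair):
        d = np.linspace(0, 4, 30)
        cont = isoboles(SurfaceModel("2to1", max_effect_pair), [0.05, 2.0], d, d)
        assert cont[2.0] == []  # above y0: unreachable
        # 0.05 sits below y_inf,1=0.3: only reachable where compound 2 acts
        for seg in cont[0.05]:
            assert np.all(seg[:, 1] > 0)
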