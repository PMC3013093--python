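"""Homogenized model, corrector cell, boundary layers, bulk resummation."""

import numpy as np
import pytest
from scipy.integrate import simpson

from vesselhomog import (
    DimensionlessParams,
    build_corrector,
    build_profile,
    bulk_periodic_solution,
    predict_oscillation,
    semianalytic_solution,
    solve_boundary_layer,
    solve_exact,
    solve_homogenized,
    volumetric_mean,
)


class TestVolumetricMean:
    @pytest.mark.parametrize("delta, kappa, expected",
                             [(0.1, 1000.0, 100.0), (1.0, 42.0, 42.0)])
    def test_closed_form(self, delta, kappa, expected):
        prof = build_profile(eps=0.25, delta=delta, kappa=kappa)
        assert volumetric_mean(prof) == pytest.approx(expected, rel=1e-14)

    def test_quadrature_oracle(self):
        prof = build_profile(eps=1 / 8, delta=0.3, kappa=17.0)
        # aligned grid: coefficient is constant on each subinterval
        xs = np.unique(np.concatenate(
            [np.linspace(a, b, 51) for a, b in
             zip(prof.breakpoints[:-1], prof.breakpoints[1:])]))
        mid = (xs[:-1] + xs[1:]) / 2
        quad = float(np.sum(prof.kappa_at(mid) * np.diff(xs)))
        assert volumetric_mean(prof) == pytest.approx(quad, abs=1e-12)


class TestSolveHomogenized:
    def test_constant_solution(self):
        u0 = solve_homogenized(40.0, 80.0, 2.0, 2.0)
        np.testing.assert_allclose(u0.evaluate(np.linspace(0, 1, 50)), 2.0, rtol=1e-14)

    def test_single_exponential_limit(self):
        u0 = solve_homogenized(400.0, 0.0, 1.0, 0.0)
        xs = np.linspace(0.0, 0.5, 20)
        np.testing.assert_allclose(u0.evaluate(xs), np.exp(-20.0 * xs), rtol=1e-8)

    def test_residual_vanishes(self):
        u0 = solve_homogenized(37.0, 11.0, 0.4, 0.9)
        xs = np.linspace(1e-3, 1 - 1e-3, 1000)
        h = 1e-5
        upp = (u0.evaluate(xs + h) - 2 * u0.evaluate(xs) + u0.evaluate(xs - h)) / h**2
        res = -upp + 37.0 * u0.evaluate(xs) - 11.0
        assert np.max(np.abs(res)) < 1e-4  # limited by the numerical u''

    def test_rejects_nonpositive_coefficient(self):
        with pytest.raises(ValueError):
            solve_homogenized(0.0, 1.0, 0.0, 0.0)


class TestCorrector:
    def test_constant_coefficient_gives_zero(self):
        prof = build_profile(eps=0.25, delta=1.0, kappa=9.0)
        P = build_corrector(prof)
        assert P.amplitude == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("delta, kappa", [(0.08, 3.0), (0.5, 8.0), (0.9, 1e4)])
    def test_zero_mean_and_periodicity(self, delta, kappa):
        prof = build_profile(eps=0.5, delta=delta, kappa=kappa)
        P = build_corrector(prof)
        assert abs(P.mean()) < 1e-12 * max(1.0, P.amplitude)
        assert P.evaluate([0.0])[0] == pytest.approx(P.evaluate([1.0])[0], abs=1e-12)

    def test_amplitude_closed_form(self):
        """Centered strip: max P - min P = kappa*delta*(1-delta)/8 exactly."""
        for delta, kappa in [(0.5, 8.0), (0.1, 100.0), (0.25, 1e3)]:
            prof = build_profile(eps=0.5, delta=delta, kappa=kappa)
            P = build_corrector(prof)
            assert P.amplitude == pytest.approx(
                kappa * delta * (1 - delta) / 8.0, rel=1e-12)

    def test_double_integration_oracle(self):
        """P from brute-force double integration of K - <K> on an aligned grid."""
        delta, kappa = 0.5, 8.0
        prof = build_profile(eps=0.5, delta=delta, kappa=kappa)
        P = build_corrector(prof)
        # aligned grid so every quadrature step sees a single polynomial piece
        cell_breaks = np.array([0.0, (1 - delta) / 2, (1 + delta) / 2, 1.0])
        ys = np.unique(np.concatenate(
            [np.linspace(a, b, 1601) for a, b in zip(cell_breaks[:-1], cell_breaks[1:])]))
        mids = (ys[:-1] + ys[1:]) / 2
        K = np.where((mids >= (1 - delta) / 2) & (mids < (1 + delta) / 2), kappa, 0.0)
        q = K - delta * kappa  # P'' per cell (piecewise constant, exact)
        from scipy.integrate import cumulative_trapezoid

        Q = np.concatenate([[0.0], np.cumsum(q * np.diff(ys))])  # exact at nodes
        Q -= np.trapezoid(Q, ys)  # periodic P' has zero mean (exact: Q pw linear)
        Pn = cumulative_trapezoid(Q, ys, initial=0.0)  # exact: integrand pw linear
        # zero-mean shift via Simpson per piece (exact on quadratics)
        mean = 0.0
        for a, b in zip(cell_breaks[:-1], cell_breaks[1:]):
            sel = (ys >= a - 1e-15) & (ys <= b + 1e-15)
            mean += simpson(Pn[sel], x=ys[sel])
        Pn -= mean
        assert np.max(np.abs(Pn - P.evaluate(ys))) < 1e-10 * P.amplitude


class TestPredictOscillation:
    def test_linear_in_kappa(self):
        preds = []
        for kappa in (100.0, 200.0):
            params = DimensionlessParams(eps=1 / 20, delta=0.1, kappa=kappa)
            prof = build_profile(params)
            preds.append(predict_oscillation(params, build_corrector(prof)))
        assert preds[1] == pytest.approx(2 * preds[0], rel=1e-12)

    def test_matches_measured_bulk_oscillation(self):
        """p = 0.01: prediction within 50% of the measured oscillation."""
        params = DimensionlessParams(eps=1 / 50, delta=0.1, kappa=250.0, f=1.0)
        prof = build_profile(params)
        u = solve_exact(prof, params.f, params.g0, params.g1)
        pred = predict_oscillation(params, build_corrector(prof))
        xs = np.linspace(25 * params.eps, 26 * params.eps, 2001)
        v = u.evaluate(xs)
        measured = (v.max() - v.min()) / v.mean()
        assert pred == pytest.approx(measured, rel=0.5)

    def test_warns_outside_regime(self):
        params = DimensionlessParams(eps=1 / 4, delta=0.5, kappa=1e3)
        prof = build_profile(params)
        with pytest.warns(UserWarning, match="outside"):
            predict_oscillation(params, build_corrector(prof))


class TestBoundaryLayer:
    def test_zero_mismatch(self, case_a_params):
        prof = build_profile(case_a_params)
        layer = solve_boundary_layer(prof, "left", 0.0, cut_length=0.5)
        assert np.max(np.abs(layer.values)) == 0.0

    def test_constant_coefficient_closed_form(self):
        """K = k_hat everywhere: z = mismatch * exp(-sqrt(k_hat) x)."""
        prof = build_profile(eps=0.25, delta=1.0, kappa=100.0)
        layer = solve_boundary_layer(prof, "left", 1.0, cut_length=1.0, N=40_000)
        xs = np.linspace(0.0, 0.3, 61)
        z = layer.evaluate(xs)
        np.testing.assert_allclose(z, np.exp(-10.0 * xs), rtol=1e-6)

    def test_decay_rate_fit_case_a(self):
        """Fitted rate within 20% of the homogenized rate sqrt(delta*kappa)."""
        params = DimensionlessParams(eps=1 / 40, delta=0.1, kappa=2000.0)
        prof = build_profile(params)
        layer = solve_boundary_layer(prof, "left", 0.01)
        assert layer.decay_rate_fit == pytest.approx(
            np.sqrt(params.k_hat), rel=0.2)

    def test_clip_warns(self, case_a_params):
        prof = build_profile(case_a_params)
        with pytest.warns(UserWarning, match="clipped"):
            solve_boundary_layer(prof, "right", 0.1, cut_length=5.0)


class TestBulkPeriodic:
    def test_constant_coefficient(self):
        prof = build_profile(eps=0.25, delta=1.0, kappa=50.0)
        w = bulk_periodic_solution(prof, 2.0)
        assert w.mean == pytest.approx(2.0 / 50.0, rel=1e-12)
        assert w.oscillation() < 1e-14

    def test_case_a_mean_is_homogenized_constant(self):
        """p = 1e-3: cell mean within 0.5% of f/(delta*kappa)."""
        params = DimensionlessParams(eps=1 / 100, delta=0.1, kappa=100.0, f=1.0)
        prof = build_profile(params)
        w = bulk_periodic_solution(prof, params.f)
        assert w.mean == pytest.approx(params.f / params.k_hat, rel=5e-3)

    def test_case_b_mean_is_arch_mean(self):
        """p = 1e4, opaque vessels: cell mean ~ f eps^2 (1-delta)^3 / 12."""
        params = DimensionlessParams(eps=1 / 20, delta=0.2, kappa=2e7, f=1.0)
        prof = build_profile(params)
        w = bulk_periodic_solution(prof, params.f)
        arch_mean = params.f * params.eps**2 * (1 - params.delta) ** 3 / 12.0
        assert w.mean == pytest.approx(arch_mean, rel=0.1)


class TestSemiAnalytic:
    def test_reconstructs_exact_solution_case_a(self):
        """Tiled cell + boundary layers vs exact solve: sup error <= 1e-3."""
        params = DimensionlessParams(eps=1 / 40, delta=0.1, kappa=2000.0, f=1.0)
        prof = build_profile(params)
        exact = solve_exact(prof, params.f, params.g0, params.g1)
        recon = semianalytic_solution(prof, params.f, params.g0, params.g1)
        xs = np.linspace(0.0, 1.0, 8001)
        sup_u = np.max(np.abs(exact.evaluate(xs)))
        assert np.max(np.abs(recon.evaluate(xs) - exact.evaluate(xs))) < 1e-3 * sup_u

    def test_corrector_shape_matches_bulk_oscillation(self):
        """Period profile of u_exact correlates with the corrector P."""
        params = DimensionlessParams(eps=1 / 20, delta=0.1, kappa=100.0, f=1.0)
        prof = build_profile(params)
        u = solve_exact(prof, params.f, params.g0, params.g1)
        P = build_corrector(prof)
        xs = np.linspace(10 * params.eps, 11 * params.eps, 501)
        uv = u.evaluate(xs) - np.mean(u.evaluate(xs))
        pv = P.evaluate(xs / params.eps) - np.mean(P.evaluate(xs / params.eps))
        corr = np.corrcoef(uv, pv)[0, 1]
        assert corr > 0.95
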