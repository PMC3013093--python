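"""Opaque-vessel arch approximation and its residual structure."""

import numpy as np
import pytest

from vesselhomog import (
    DimensionlessParams,
    build_caseb,
    build_profile,
    residual_caseb,
    solve_exact,
)


@pytest.fixture(scope="module")
def deep_b():
    params = DimensionlessParams(eps=1 / 20, delta=0.2, kappa=2e5, f=1.0)
    return params, build_caseb(params)


class TestConstruction:
    def test_arch_midpoint_closed_form(self, deep_b):
        params, approx = deep_b
        prof = approx.profile
        # midpoints of all interior gaps
        gaps = [i for i in range(1, prof.n_intervals - 1)
                if prof.interval_kappa[i] == 0]
        mids = (prof.breakpoints[gaps] + prof.breakpoints[np.array(gaps) + 1]) / 2
        expected = params.f * params.eps**2 * (1 - params.delta) ** 2 / 8.0
        np.testing.assert_allclose(approx.evaluate(mids), expected, rtol=1e-12)
        assert approx.arch_midpoint_value == pytest.approx(expected)

    def test_boundary_conditions_exact(self, deep_b):
        params, approx = deep_b
        assert approx.evaluate([0.0])[0] == pytest.approx(params.g0, abs=1e-18)
        assert approx.evaluate([1.0])[0] == pytest.approx(params.g1, abs=1e-18)

    def test_zero_source(self):
        params = DimensionlessParams(eps=1 / 10, delta=0.2, kappa=1e5,
                                     f=0.0, g0=0.0, g1=0.0)
        approx = build_caseb(params)
        xs = np.linspace(0, 1, 2001)
        assert np.max(np.abs(approx.evaluate(xs))) == 0.0

    def test_warns_below_regime(self):
        params = DimensionlessParams(eps=1 / 10, delta=0.1, kappa=10.0)
        with pytest.warns(UserWarning, match="outside"):
            build_caseb(params)

    def test_cutoff_range_and_plateaus(self, deep_b):
        _, approx = deep_b
        phi = approx.cutoff
        xs = np.linspace(0, 1, 20001)
        v = phi.evaluate(xs)
        assert np.all((v >= 0) & (v <= 1))
        prof = approx.profile
        # deep inside the first vessel / the middle of a gap
        ves_mid = (prof.breakpoints[1] + prof.breakpoints[2]) / 2
        gap_mid = (prof.breakpoints[2] + prof.breakpoints[3]) / 2
        assert phi.evaluate([ves_mid])[0] == 0.0
        assert phi.evaluate([gap_mid])[0] == 1.0

    def test_cutoff_is_smooth(self, deep_b):
        """phi' from the analytic formula matches central differences."""
        _, approx = deep_b
        phi = approx.cutoff
        wall = approx.profile.breakpoints[1]
        xs = wall + np.linspace(-1.5, 1.5, 41) * phi.half_width
        h = 1e-9
        fd = (phi.evaluate(xs + h) - phi.evaluate(xs - h)) / (2 * h)
        np.testing.assert_allclose(phi.derivative_at(xs), fd, rtol=1e-4, atol=1e-3)


class TestResidual:
    def test_gap_interior_residual_zero(self, deep_b):
        _, approx = deep_b
        rep = residual_caseb(approx)
        assert rep["zones"]["gap"]["sup"] == 0.0

    def test_vessel_interior_residual_is_source(self, deep_b):
        """Beyond the transition the cutoff is exactly 0, so the residual is f."""
        params, approx = deep_b
        rep = residual_caseb(approx)
        assert rep["zones"]["vessel"]["sup"] == pytest.approx(params.f, rel=1e-12)

    def test_leakage_shrinks_with_transition_width(self):
        """kappa * |u_B| integrated over vessels falls as the cutoff narrows."""
        params = DimensionlessParams(eps=1 / 20, delta=0.2, kappa=2e5, f=1.0)
        leak = {}
        for tw in (0.8, 0.2):
            approx = build_caseb(params, transition_width=tw)
            prof = approx.profile
            total = 0.0
            for i in range(prof.n_intervals):
                if prof.interval_kappa[i] == 0:
                    continue
                xs = np.linspace(prof.breakpoints[i], prof.breakpoints[i + 1], 801)
                total += np.trapezoid(
                    prof.kappa * np.abs(approx.evaluate(xs)), xs)
            leak[tw] = total
        assert leak[0.2] < 0.2 * leak[0.8]


class TestAgainstExactSolver:
    def test_error_bounded_by_wall_value(self, deep_b):
        """sup|u_exact - u_B| is the wall-leak scale f*l/(2 sqrt(kappa))."""
        params, approx = deep_b
        prof = approx.profile
        exact = solve_exact(prof, params.f, params.g0, params.g1)
        xs = np.union1d(np.linspace(0, 1, 40001), prof.breakpoints[1:-1])
        err = np.max(np.abs(exact.evaluate(xs) - approx.evaluate(xs)))
        wall = params.f * params.eps * (1 - params.delta) / (
            2 * np.sqrt(params.kappa))
        assert 0.5 * wall < err < 1.5 * wall

    def test_wall_offset_refinement_improves(self, deep_b):
        params, plain = deep_b
        refined = build_caseb(params, wall_offset=True)
        prof = plain.profile
        exact = solve_exact(prof, params.f, params.g0, params.g1)
        xs = np.union1d(np.linspace(0, 1, 40001), prof.breakpoints[1:-1])
        sup_u = np.max(np.abs(exact.evaluate(xs)))
        err_plain = np.max(np.abs(exact.evaluate(xs) - plain.evaluate(xs)))
        err_ref = np.max(np.abs(exact.evaluate(xs) - refined.evaluate(xs)))
        assert err_ref < 0.5 * err_plain
        assert err_ref < 0.1 * sup_u
        # refinement keeps the boundary conditions exact
        assert refined.evaluate([0.0])[0] == pytest.approx(params.g0, rel=1e-12)

    def test_opacity_limit_midpoint_convergence(self):
        """Gap midpoints of u_exact -> f eps^2 (1-delta)^2/8 as kappa grows."""
        eps, delta, f = 1 / 20, 0.2, 1.0
        target = f * eps**2 * (1 - delta) ** 2 / 8.0
        devs = []
        for kappa in (2e5, 2e6, 1e7):
            params = DimensionlessParams(eps=eps, delta=delta, kappa=kappa, f=f)
            prof = build_profile(params)
            u = solve_exact(prof, params.f, params.g0, params.g1)
            # centered strips: interior gaps are centered on period boundaries
            mid = 0.5
            devs.append(abs(u.evaluate([mid])[0] - target) / target)
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.05

    def test_vessel_centers_reach_source_scale(self):
        """Opaque vessels: u at vessel centers is at the f/kappa scale."""
        params = DimensionlessParams(eps=1 / 20, delta=0.2, kappa=2e6, f=1.0)
        prof = build_profile(params)
        u = solve_exact(prof, params.f, params.g0, params.g1)
        centers = [(prof.breakpoints[i] + prof.breakpoints[i + 1]) / 2
                   for i in range(prof.n_intervals) if prof.interval_kappa[i] > 0]
        vals = u.evaluate(centers)
        assert np.all(vals <= 2.0 * params.f / params.kappa)
        assert np.all(vals >= params.f / params.kappa * (1 - 1e-6))

    def test_scale_separation_from_homogenized_constant(self, deep_b):
        """p = 100: sup u_exact is far above the homogenized level f/(dk)."""
        params, _ = deep_b
        prof = build_profile(params)
        u = solve_exact(prof, params.f, params.g0, params.g1)
        sup_u = np.max(u.evaluate(np.linspace(0, 1, 20001)))
        assert sup_u >= 5.0 * params.f / params.k_hat
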