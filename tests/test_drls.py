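"""Level-set evolution: closed forms, oracles, stability and convergence."""

import math

import numpy as np
import pytest

from octlumen.drls import (DRLSParams, NumericalInstabilityError, dirac,
                           edge_indicator, evolve_rhs_numpy, evolve_step,
                           heaviside, init_levelset_line, mean_grad_near_zero,
                           regularizer_rate, run_drls)


def scalar_reference_rhs(phi, g, alpha, mu, lam, eps, floor=1e-10):
    """Independent scalar-loop reference for the evolution right-hand side.

    Implements the documented discretization directly: central differences
    with replicated borders, the Li-split regularizer div((d−1)∇ϕ) + ∇²ϕ,
    the edge-weighted curvature divergence and the cosine Dirac — all in
    plain Python loops.
    """
    nr, nc = phi.shape

    def cl(i, n):
        return min(max(i, 0), n - 1)

    def dy(f, i, j):
        return (f[cl(i + 1, nr)][j] - f[cl(i - 1, nr)][j]) / 2.0

    def dx(f, i, j):
        return (f[i][cl(j + 1, nc)] - f[i][cl(j - 1, nc)]) / 2.0

    def d_rate(s):
        if s < 1e-12:
            return 1.0
        if s <= 1.0:
            return math.sin(2 * math.pi * s) / (2 * math.pi * s)
        return (s - 1.0) / s

    P = phi.tolist()
    ay = [[0.0] * nc for _ in range(nr)]
    ax = [[0.0] * nc for _ in range(nr)]
    ny = [[0.0] * nc for _ in range(nr)]
    nx = [[0.0] * nc for _ in range(nr)]
    for i in range(nr):
        for j in range(nc):
            py, px = dy(P, i, j), dx(P, i, j)
            s = math.hypot(py, px)
            ay[i][j] = (d_rate(s) - 1.0) * py
            ax[i][j] = (d_rate(s) - 1.0) * px
            sf = max(s, floor)
            ny[i][j] = g[i][j] * py / sf
            nx[i][j] = g[i][j] * px / sf
    out = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            lap = (P[cl(i + 1, nr)][j] + P[cl(i - 1, nr)][j]
                   + P[i][cl(j + 1, nc)] + P[i][cl(j - 1, nc)] - 4 * P[i][j])
            reg = dy(ay, i, j) + dx(ax, i, j) + lap
            curv = dy(ny, i, j) + dx(nx, i, j)
            a = abs(P[i][j])
            delta = (1 + math.cos(math.pi * P[i][j] / eps)) / (2 * eps) \
                if a <= eps else 0.0
            out[i, j] = mu * reg + lam * delta * curv + alpha * g[i][j] * delta
    return out


class TestEdgeIndicator:
    def test_constant_image_gives_one(self):
        assert np.allclose(edge_indicator(np.full((12, 9), 3.0)), 1.0)

    def test_unit_ramp_gives_half_interior(self):
        img = np.tile(np.arange(20, dtype=float), (10, 1))
        g = edge_indicator(img)
        assert np.allclose(g[:, 1:-1], 0.5)

    def test_bounds_and_argmin_on_edge(self, rng):
        img = rng.uniform(size=(30, 30))
        img[15:, :] += 5.0
        g = edge_indicator(img)
        assert np.all(g > 0) and np.all(g <= 1)
        assert np.all(g.argmin(axis=0) >= 13) and np.all(g.argmin(axis=0) <= 16)


class TestInit:
    def test_step_values(self):
        phi = init_levelset_line((10, 4), 3)
        assert np.all(phi[:3] == 2.0) and np.all(phi[3:] == -2.0)
        # zero level set lies between rows 2 and 3
        sign_change = np.nonzero((phi[:-1, 0] > 0) & (phi[1:, 0] < 0))[0]
        assert sign_change.tolist() == [2]

    @pytest.mark.parametrize("row0", [0, 10, -1])
    def test_out_of_range_rejected(self, row0):
        with pytest.raises(ValueError):
            init_levelset_line((10, 4), row0)


class TestDiracHeaviside:
    def test_peak_and_support(self):
        eps = 1.5
        assert dirac(np.array(0.0), eps) == pytest.approx(1.0 / eps)
        assert dirac(np.array([1.6, -2.0, 100.0]), eps).tolist() == [0, 0, 0]

    def test_unit_mass_along_transversal(self):
        eps = 1.5
        s = np.linspace(-3, 3, 20001)
        mass = np.trapezoid(dirac(s, eps), s)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_sharp_heaviside(self):
        h = heaviside(np.array([-0.1, 0.0, 2.0]))
        assert h.tolist() == [0.0, 1.0, 1.0]

    def test_smoothed_heaviside_integrates_dirac(self):
        eps = 1.5
        s = np.linspace(-2, 2, 4001)
        h = heaviside(s, eps)
        dh = np.gradient(h, s)
        assert np.allclose(dh, dirac(s, eps), atol=1e-3)


class TestRegularizerRate:
    def test_against_symbolic_oracle(self):
        # d(s) = p'(s)/s for the double-well p; sympy provides the oracle
        import sympy as sp

        s = sp.symbols("s", positive=True)
        p_inner = (1 - sp.cos(2 * sp.pi * s)) / (2 * sp.pi) ** 2
        p_outer = (s - 1) ** 2 / 2
        d_inner = sp.diff(p_inner, s) / s
        d_outer = sp.diff(p_outer, s) / s
        assert regularizer_rate(np.array(1.0)) == pytest.approx(
            float(d_inner.subs(s, 1)), abs=1e-15)
        assert regularizer_rate(np.array(2.0)) == pytest.approx(
            float(d_outer.subs(s, 2)), abs=1e-15)
        assert float(d_outer.subs(s, 2)) == 0.5
        # removable singularity: series limit at 0+ is 1
        assert float(sp.limit(d_inner, s, 0, "+")) == 1.0
        assert regularizer_rate(np.array(1e-15)) == pytest.approx(1.0)
        assert regularizer_rate(np.array(1e-6)) == pytest.approx(1.0, abs=1e-6)

    def test_wells_are_zeros(self):
        assert regularizer_rate(np.array(1.0)) == pytest.approx(0.0, abs=1e-15)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            regularizer_rate(np.array([-0.1]))


class TestEvolveStep:
    def test_matches_scalar_reference(self, rng):
        phi = rng.normal(scale=2.0, size=(16, 16))
        g = rng.uniform(0.01, 1.0, size=(16, 16))
        params = DRLSParams(alpha_schedule=((2.0, 1),), max_iters=1)
        out = evolve_step(phi.copy(), g, 2.0, params)
        ref = phi + params.dt * scalar_reference_rhs(
            phi, g.tolist(), 2.0, params.mu, params.lam, params.eps)
        assert np.max(np.abs(out - ref)) < 1e-10

    def test_numba_and_numpy_paths_agree(self, rng):
        from octlumen import _kernels

        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba not available; single path only")
        phi = rng.normal(scale=2.0, size=(24, 17))
        g = rng.uniform(0.01, 1.0, size=(24, 17))
        params = DRLSParams(alpha_schedule=((9.0, 1),), max_iters=1)
        fast = evolve_step(phi.copy(), g, 9.0, params)
        slow = phi + params.dt * evolve_rhs_numpy(phi, g, 9.0, params)
        assert np.max(np.abs(fast - slow)) < 1e-12

    def test_signed_distance_fixed_point_in_flat_region(self):
        # g ≡ 1, alpha = 0: a slope-one field is at the regularizer's well
        # and a straight front has zero curvature, so nothing moves inside
        rows = np.arange(40, dtype=float)[:, None]
        phi = np.broadcast_to(20.0 - rows, (40, 12)).copy()
        g = np.ones((40, 12))
        out = evolve_step(phi.copy(), g, 0.0, DRLSParams(alpha_schedule=((0.0, 1),)))
        assert np.max(np.abs(out - phi)[2:-2, 2:-2]) < 1e-12

    def test_instability_reported_with_iteration(self):
        phi = init_levelset_line((30, 10), 10)
        g = np.ones((30, 10))
        params = DRLSParams(dt=1e4, alpha_schedule=((9.0, 50),), max_iters=50)
        with pytest.raises(NumericalInstabilityError, match="iteration"):
            for it in range(50):
                phi = evolve_step(phi, g, 9.0, params, iteration=it)

    def test_evolution_slows_at_edges(self):
        # two-region fixture: the front crosses a flat zone then meets a
        # high-gradient band, where per-iteration displacement must drop
        # below 20% of its flat-region value
        img = np.zeros((120, 24))
        img[80:, :] = 200.0  # strong edge at row 80 (8-bit-scale units)
        img_s = img.copy()
        from scipy.ndimage import gaussian_filter1d
        img_s = gaussian_filter1d(img, 2.0, axis=0)
        g = edge_indicator(img_s)
        params = DRLSParams(alpha_schedule=((5.0, 400),), max_iters=400,
                            conv_tol=0.0)
        phi = init_levelset_line(img.shape, 20)
        front = []
        for it in range(400):
            phi = evolve_step(phi, g, 5.0, params, it)
            c = phi[:, 12]
            k = np.nonzero((c[:-1] > 0) & (c[1:] <= 0))[0]
            front.append(k[0] if k.size else np.nan)
        front = np.array(front, dtype=float)
        speed = np.diff(front)
        flat = speed[(front[:-1] > 30) & (front[:-1] < 60)].mean()
        near_edge = speed[front[:-1] >= 76].mean()
        assert near_edge < 0.2 * flat


class TestRunDRLS:
    def test_recovers_band_edge_on_small_frame(self, small_frame):
        frame, truth = small_frame
        from octlumen.contour import extract_boundary
        from octlumen.smoothing import SmoothParams, smooth_narrow

        img = smooth_narrow(frame.pixels, SmoothParams())
        res = run_drls(img, DRLSParams(), init_row=35)
        b = extract_boundary(res.phi, start_row=30)
        err = np.abs(b - truth.radii[0])
        assert err.mean() <= 2.0
        assert 0.8 <= res.mean_grad_near_zero <= 1.2
        assert res.iterations <= 3000

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            DRLSParams(alpha_schedule=((9.0, 300), (2.0, 300)), max_iters=400)
        with pytest.raises(ValueError):
            DRLSParams(mu=-1.0)
        with pytest.raises(ValueError):
            DRLSParams(alpha_schedule=())


def test_mean_grad_near_zero_of_signed_distance():
    rows = np.arange(60, dtype=float)[:, None]
    phi = np.broadcast_to(30.0 - rows, (60, 8)).copy()
    assert mean_grad_near_zero(phi, 1.5) == pytest.approx(1.0, abs=1e-12)
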