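"""Linear stability analysis and the reaction-diffusion solver."""



import numpy as np
import pytest

import woundfield as wf
from woundfield.turing import (_jacobian, explicit_dt_bound, stability,
                               steady_E)


class TestSourceAndSteadyState:
    def test_gaussian_source_values(self):
        assert wf.gaussian_source(0.0, 0.0, 20.0) == pytest.approx(1.0)
        assert wf.gaussian_source(20.0, 0.0, 20.0) == pytest.approx(np.exp(-1))
        assert wf.gaussian_source(50.0, 50.0, 20.0) == \
            pytest.approx(np.exp(-12.5))
        with pytest.raises(ValueError, match="sigma"):
            wf.gaussian_source(0, 0, 0.0)

    @pytest.mark.parametrize("alpha,b,expect", [
        (1.0, 0.0, (1.0, 0.0)),
        (0.1, 0.9, (1.0, 0.9)),
    ])
    def test_homogeneous_steady_state_values(self, alpha, b, expect):
        assert wf.homogeneous_steady_state(alpha, b) == \
            pytest.approx(expect)

    def test_reaction_terms_vanish_at_steady_state(self):
        for alpha, b in [(0.05, 1.3), (0.2, 0.4), (1.0, 2.0)]:
            u, v = wf.homogeneous_steady_state(alpha, b)
            assert abs(alpha - u + u * u * v) < 1e-12
            assert abs(b - u * u * v) < 1e-12

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError, match="alpha"):
            wf.homogeneous_steady_state(0.0, 1.0)


class TestDispersion:
    def test_stable_at_k0_when_b_below_alpha(self):
        assert wf.dispersion(0.5, 0.3, 40.0, 0.0) < 0

    def test_equal_diffusion_never_turing(self):
        for b in np.linspace(0.05, 5, 30):
            res = stability(0.5, b, D_v=1.0)
            assert not res.turing_unstable

    def test_matches_brute_force_eigenvalues(self):
        """Closed-form growth equals numpy eigvals of the explicit matrix."""
        alpha, b, D_v = 0.05, 1.5, 40.0
        k2 = np.linspace(0, 3, 500)
        J = _jacobian(alpha, b)
        brute = np.array([
            np.linalg.eigvals(J - np.diag([k, D_v * k])).real.max()
            for k in k2])
        ours = wf.dispersion(alpha, b, D_v, k2)
        np.testing.assert_allclose(ours, brute, atol=1e-10)
        assert ours.max() > 0 and 0 < k2[np.argmax(ours)] < 3


class TestTuringWindow:
    def test_window_against_brute_force_scan(self):
        win = wf.turing_window(0.05, 40.0)
        assert win is not None
        b_min, b_max = win
        for b in np.linspace(0.1, 4.0, 60):
            res = stability(0.05, b, 40.0)
            inside = b_min < b < b_max
            near_edge = min(abs(b - b_min), abs(b - b_max)) < 1e-3
            if not near_edge:
                assert res.turing_unstable == inside

    def test_endpoints_are_marginal(self):
        """Each endpoint sits on the binding marginal condition.

        The upper edge is Turing-marginal (peak growth crosses zero); the
        lower edge for alpha=0.05 is bound by k=0 (Hopf) stability, so the
        trace of the Jacobian crosses zero there instead.
        """
        b_min, b_max = wf.turing_window(0.05, 40.0)
        res_hi = stability(0.05, b_max, 40.0)
        assert abs(res_hi.max_growth) < 5e-3
        J = _jacobian(0.05, b_min)
        assert abs(J[0, 0] + J[1, 1]) < 5e-3

    def test_no_window_for_equal_diffusion(self):
        assert wf.turing_window(0.5, 1.0) is None


class TestSteadyE:
    def test_zero_diffusion_equals_source(self):
        p = wf.TuringParams(D_E=0.0, s=3.0, n_grid=64)
        c = p.cell_centers()
        X, Y = np.meshgrid(c, c)
        expected = 3.0 * wf.gaussian_source(X, Y, p.sigma)
        np.testing.assert_allclose(steady_E(p), expected, rtol=1e-12)

    def test_zero_source_gives_zero_field(self):
        p = wf.TuringParams(s=0.0, n_grid=64)
        assert np.allclose(steady_E(p), 0.0)

    def test_source_sink_balance_and_center_max(self):
        p = wf.TuringParams(n_grid=64, s=2.0)
        c = p.cell_centers()
        X, Y = np.meshgrid(c, c)
        src = p.s * wf.gaussian_source(X, Y, p.sigma)
        E = steady_E(p)
        # zero-flux domain: integrated source balances integrated decay
        assert E.sum() == pytest.approx(src.sum(), rel=1e-10)
        i, j = np.unravel_index(np.argmax(E), E.shape)
        assert abs(c[i]) < 2 * p.dx and abs(c[j]) < 2 * p.dx


def small_params(**kw):
    base = dict(n_grid=64, t_end=30.0, dt=0.05, seed=1)
    base.update(kw)
    return wf.TuringParams(**base)


class TestEvolve:
    def test_seeded_determinism(self):
        p = small_params(t_end=5.0)
        a = wf.evolve(p)
        b = wf.evolve(p)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.E, b.E)

    def test_positivity(self):
        p = small_params(t_end=60.0, s=6.0)
        st = wf.evolve(p)
        for f in (st.u, st.v, st.E):
            assert f.min() >= -1e-9

    def test_E_preserves_square_symmetry(self):
        """E decouples from (u, v); its radially symmetric source keeps it
        invariant under the square's reflections."""
        p = small_params(t_end=20.0, s=4.0)
        st = wf.evolve(p)
        np.testing.assert_allclose(st.E, st.E[::-1, :], atol=1e-12)
        np.testing.assert_allclose(st.E, st.E[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(st.E, st.E.T, atol=1e-12)

    def test_zero_source_attracts_homogeneous_state(self):
        p = small_params(s=0.0, t_end=400.0, steady_tol=0.0)
        st = wf.evolve(p)
        assert abs(st.u - p.alpha).max() < 0.02
        assert st.v.max() < 0.5  # slow alpha^2 tail; full decay tested e2e

    def test_uniform_clamped_E_matches_linear_theory(self):
        # spike cores span only ~2 length units, so this runs at the
        # production resolution rather than the cheap 64-cell grid
        b_in, b_out = 1.5, 3.5
        p = small_params(t_end=200.0, n_grid=128)
        patterned = wf.evolve(p, E_fixed=b_in)
        assert wf.pattern_present(patterned)
        assert patterned.u.max() > 3.8  # placode threshold exceeded in-window
        homogeneous = wf.evolve(p, E_fixed=b_out)
        assert not wf.pattern_present(homogeneous)
        u_star, v_star = wf.homogeneous_steady_state(p.alpha, b_out)
        assert abs(homogeneous.u - u_star).max() < 1e-3
        assert abs(homogeneous.v - v_star).max() < 1e-3

    def test_explicit_scheme_agrees_with_imex_short_horizon(self):
        """Both integrators approximate the same flow: their difference is
        O(dt) and halves with the step."""
        bound = explicit_dt_bound(wf.TuringParams(n_grid=64))
        diffs = []
        for dt in (0.8 * bound, 0.4 * bound):
            pa = small_params(t_end=1.0, dt=dt, scheme="explicit")
            pb = small_params(t_end=1.0, dt=dt, scheme="imex")
            a = wf.evolve(pa, E_fixed=1.5)
            b = wf.evolve(pb, E_fixed=1.5)
            diffs.append(np.abs(a.u - b.u).max())
        assert diffs[0] < 0.1
        assert diffs[1] < 0.65 * diffs[0]

    def test_explicit_dt_preflight(self):
        with pytest.raises(ValueError, match="dt"):
            wf.TuringParams(n_grid=64, dt=1.0, scheme="explicit")

    def test_source_shape_mismatch_rejected(self):
        p = small_params()
        with pytest.raises(ValueError, match="shape"):
            wf.evolve(p, source=np.zeros((4, 4)))


class TestSweepAndMapping:
    def test_sweep_returns_ordered_states_with_growing_E(self):
        p = small_params(t_end=30.0)
        out = wf.sweep_s(p, s_list=[1.0, 3.0, 6.0])
        assert [s for s, _ in out] == [1.0, 3.0, 6.0]
        maxima = [st.E.max() for _, st in out]
        assert maxima[0] < maxima[1] < maxima[2]

    def test_default_mapping_monotone_and_capped(self):
        from woundfield.turing import default_stiffness_to_source
        k = np.linspace(0, 40, 200)
        src = default_stiffness_to_source(k)
        assert np.all(np.diff(src) <= 0)
        assert src.min() == 0.0 and src.max() == pytest.approx(3.5)

    def test_uniform_stiffness_reduces_to_uniform_source(self):
        """A flat wound drives a spatially constant E source."""
        cfg = wf.LandscapeConfig.preset("uniform")
        _, samples = wf.gen_stiffness_landscape(cfg)
        grid = wf.interpolate_grid(samples, pixel_size=0.2)
        p = small_params(t_end=10.0)
        st = wf.simulate_from_measured_stiffness(grid, p)
        assert np.ptp(st.E) < 1e-6 * max(st.E.max(), 1e-12) + 1e-9
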