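"""D2Q9 core: moment identities, conservation, and analytic flow oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinchflow import lattice_core as lc
from pinchflow._kernels import FLUID, SOLID


SPEC = lc.LatticeSpec(tau=0.8)


class TestLatticeSpec:
    def test_weights_and_directions(self):
        w = SPEC.weights
        assert w[0] == pytest.approx(4 / 9)
        assert np.all(w[1:5] == pytest.approx(1 / 9))
        assert np.all(w[5:] == pytest.approx(1 / 36))
        assert w.sum() == pytest.approx(1.0)
        e = SPEC.directions
        speeds = np.linalg.norm(e, axis=1)
        assert speeds[0] == 0
        assert np.allclose(speeds[1:5], SPEC.c)
        assert np.allclose(speeds[5:], np.sqrt(2) * SPEC.c)

    def test_sound_speed(self):
        assert SPEC.c_s == pytest.approx(SPEC.h / (np.sqrt(3) * SPEC.dt))

    def test_tau_must_exceed_half(self):
        with pytest.raises(lc.ConfigurationError):
            lc.LatticeSpec(tau=0.5)


class TestEquilibrium:
    def test_rest_state_equals_weights(self):
        g = lc.equilibrium_distribution(1.0, np.zeros(2), SPEC)
        assert np.allclose(g, SPEC.weights)

    def test_scalar_value_moving_state(self):
        # direct evaluation of the second-order Maxwellian at u = (0.1, 0):
        # g0 = (4/9)(1 - u^2/(2 c_s^2)) = (4/9)(1 - 0.015)
        g = lc.equilibrium_distribution(1.0, np.array([0.1, 0.0]),
                                        lc.LatticeSpec(tau=1.0))
        assert g[0] == pytest.approx((4 / 9) * (1 - 0.015), rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(rho=st.floats(0.5, 2.0),
           ux=st.floats(-0.1, 0.1), uy=st.floats(-0.1, 0.1))
    def test_moment_identities(self, rho, ux, uy):
        u = np.array([ux, uy])
        g = lc.equilibrium_distribution(rho, u, SPEC)
        assert np.sum(g) == pytest.approx(rho, rel=1e-12)
        mom = np.tensordot(g, SPEC.directions, axes=(0, 0))
        assert np.allclose(mom, rho * u, atol=1e-14)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(lc.InvalidStateError):
            lc.equilibrium_distribution(0.0, np.zeros(2), SPEC)


class TestForcing:
    def test_zero_force_gives_zero(self):
        G = lc.forcing_term(np.array([0.02, 0.0]), np.zeros(2), SPEC)
        assert np.allclose(G, 0.0)

    def test_tau_half_limit_vanishes(self):
        # at tau = 0.5 the (1 - 1/(2 tau)) prefactor is zero
        spec = lc.LatticeSpec.__new__(lc.LatticeSpec)
        object.__setattr__(spec, "h", 1.0)
        object.__setattr__(spec, "dt", 1.0)
        object.__setattr__(spec, "tau", 0.5)
        G = lc.forcing_term(np.array([0.01, 0.02]), np.array([1e-3, 0]),
                            spec)
        assert np.allclose(G, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(ux=st.floats(-0.1, 0.1), uy=st.floats(-0.1, 0.1),
           fx=st.floats(-1e-3, 1e-3), fy=st.floats(-1e-3, 1e-3))
    def test_force_moments(self, ux, uy, fx, fy):
        u = np.array([ux, uy])
        f = np.array([fx, fy])
        G = lc.forcing_term(u, f, SPEC)
        assert np.sum(G) == pytest.approx(0.0, abs=1e-16)
        mom = np.tensordot(G, SPEC.directions, axes=(0, 0))
        assert np.allclose(mom, (1 - 0.5 / SPEC.tau) * f, atol=1e-15)


class TestViscosity:
    def test_value(self):
        spec = lc.LatticeSpec(tau=1.0)
        assert lc.viscosity_from_tau(1.0, spec) == pytest.approx(1 / 6)

    def test_rejects_tau_at_half(self):
        with pytest.raises(lc.ConfigurationError):
            lc.viscosity_from_tau(0.5, SPEC)

    def test_monotone_in_tau(self):
        taus = np.linspace(0.51, 2.0, 10)
        nus = [lc.viscosity_from_tau(t, SPEC) for t in taus]
        assert np.all(np.diff(nus) > 0)


class TestCollideStream:
    def test_uniform_equilibrium_is_fixed_point(self):
        f = lc.make_periodic_field(12, 10, SPEC)
        g0 = f.g.copy()
        for _ in range(5):
            f.step()
        assert np.allclose(f.g, g0, atol=1e-14)

    def test_mass_conserved_on_periodic_domain(self):
        rng = np.random.default_rng(7)
        f = lc.make_periodic_field(16, 14, SPEC)
        f.g += 0.01 * rng.random(f.g.shape)
        m0 = f.total_mass()
        for _ in range(20):
            f.step()
        assert f.total_mass() == pytest.approx(m0, rel=1e-13)

    def test_tau_one_relaxes_to_equilibrium_plus_forcing(self):
        spec = lc.LatticeSpec(tau=1.0)
        rng = np.random.default_rng(3)
        f = lc.make_periodic_field(8, 8, spec)
        f.g += 0.01 * rng.random(f.g.shape)
        rho, u, _ = lc.macroscopics(f)
        geq = lc.equilibrium_distribution(rho, u, spec)
        f.step()
        # after streaming, pull back: post-collision at tau=1 is g_eq
        post = np.empty_like(f.g)
        for i in range(9):
            ex, ey = int(lc.K.EX[i]), int(lc.K.EY[i])
            post[i] = np.roll(np.roll(f.g[i], -ey, axis=0), -ex, axis=1)
        assert np.allclose(post, geq, atol=1e-13)

    def test_momentum_gain_equals_applied_force(self):
        f = lc.make_periodic_field(10, 10, SPEC)
        f.fx[:] = 1e-5
        mom0 = np.sum(f.g * lc.K.EX[:, None, None])
        f.step()
        mom1 = np.sum(f.g * lc.K.EX[:, None, None])
        assert mom1 - mom0 == pytest.approx(1e-5 * 100, rel=1e-12)


class TestMacroscopics:
    def test_rest_state(self):
        f = lc.make_periodic_field(6, 6, lc.LatticeSpec(tau=1.0))
        rho, u, p = lc.macroscopics(f)
        assert np.allclose(rho, 1.0)
        assert np.allclose(u, 0.0)
        assert np.allclose(p, 1 / 3)

    def test_consistency_with_equilibrium(self):
        spec = lc.LatticeSpec(tau=1.0)
        u0 = np.zeros((5, 5, 2))
        u0[..., 0] = 0.05
        f = lc.make_periodic_field(5, 5, spec, u=u0)
        _, u, _ = lc.macroscopics(f)
        assert np.allclose(u[..., 0], 0.05, atol=1e-14)

    def test_half_force_shift(self):
        spec = lc.LatticeSpec(tau=1.0)
        f = lc.make_periodic_field(5, 5, spec)
        f.fx[:] = 0.01
        _, u, _ = lc.macroscopics(f)
        assert np.allclose(u[..., 0], 0.005, atol=1e-15)


class TestFlowOracles:
    def test_poiseuille_profile(self):
        """Body-force-driven channel flow matches the analytic parabola
        with nu = (tau - 1/2) c_s^2 dt to < 1% L2 error."""
        spec = lc.LatticeSpec(tau=0.8)
        ny, nx = 34, 4       # 32 fluid rows across the gap
        mask = np.full((ny, nx), FLUID, np.uint8)
        mask[0, :] = SOLID
        mask[-1, :] = SOLID
        f = lc.LatticeField(spec=spec, mask=mask, periodic=True)
        gf = 1e-6
        for _ in range(20000):
            f.fx[:] = gf
            f.step()
        y = np.arange(1, ny - 1)
        ua = gf / (2 * spec.viscosity) * (y - 0.5) * (ny - 1.5 - y)
        ux = f.ux[1:-1, 0]
        err = np.linalg.norm(ux - ua) / np.linalg.norm(ua)
        assert err < 0.01

    def test_taylor_green_viscosity_recovery(self):
        """Decay rate of the Taylor-Green vortex recovers the nominal
        viscosity within 2%."""
        spec = lc.LatticeSpec(tau=0.7)
        N = 48
        k = 2 * np.pi / N
        xx, yy = np.meshgrid(np.arange(N), np.arange(N))
        U0 = 0.02
        u = np.zeros((N, N, 2))
        u[..., 0] = U0 * np.cos(k * xx) * np.sin(k * yy)
        u[..., 1] = -U0 * np.sin(k * xx) * np.cos(k * yy)
        rho = 1 - U0 ** 2 * 3 / 4 * (np.cos(2 * k * xx) + np.cos(2 * k * yy))
        f = lc.make_periodic_field(N, N, spec, rho=rho, u=u)
        E = []
        for t in range(2000):
            f.step()
            if t % 100 == 99:
                E.append((t + 1.0, float(np.sum(f.ux ** 2 + f.uy ** 2))))
        E = np.array(E)
        slope = np.polyfit(E[:, 0], np.log(E[:, 1]), 1)[0]
        nu = -slope / (4 * k ** 2)
        assert nu == pytest.approx(spec.viscosity, rel=0.02)

    def test_divergence_error_names_time_step(self):
        f = lc.make_periodic_field(6, 6, SPEC)
        f.g[0, 2, 2] = np.nan
        f.time_step = 41
        with pytest.raises(lc.InvalidStateError, match="41"):
            f.check_finite()
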