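"""Delta-kernel transfer operators and feedback forcing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinchflow import immersed_coupling as ib
from pinchflow import lattice_core as lc


SPEC = lc.LatticeSpec(tau=0.8)


def uniform_field(ny=20, nx=20, u=(0.0, 0.0)):
    u0 = np.zeros((ny, nx, 2))
    u0[..., 0] = u[0]
    u0[..., 1] = u[1]
    return lc.make_periodic_field(ny, nx, SPEC, u=u0)


class TestDeltaKernel:
    def test_center_value(self):
        assert ib.delta_kernel(0.0) == pytest.approx(0.5)

    def test_zero_outside_support(self):
        assert ib.delta_kernel(2.5) == 0.0
        assert ib.delta_kernel(-3.0) == 0.0

    def test_continuity_at_branch_points(self):
        # both branches give 1/4 at |r| = 1; zero at |r| = 2
        eps = 1e-9
        assert ib.delta_kernel(1 - eps) == pytest.approx(0.25, abs=1e-6)
        assert ib.delta_kernel(1 + eps) == pytest.approx(0.25, abs=1e-6)
        assert ib.delta_kernel(2 - eps) == pytest.approx(0.0, abs=1e-4)
        assert ib.delta_kernel(1.0) == pytest.approx(0.25)

    @settings(deadline=None, max_examples=100)
    @given(x=st.floats(-1.0, 1.0))
    def test_partition_of_unity_and_first_moment(self, x):
        j = np.arange(-4, 5)
        w = ib.delta_kernel(j - x)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        assert np.sum((j - x) * w) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self):
        r = np.linspace(-2.2, 2.2, 401)
        assert np.all(ib.delta_kernel(r) >= 0)


class TestInterpolation:
    def test_uniform_field_exact(self):
        f = uniform_field(u=(0.03, -0.01))
        pts = ib.LagrangianSet(X=[[5.3, 7.8], [10.0, 3.2]], ds=0.5)
        U = ib.interpolate_velocity(f, pts)
        assert np.allclose(U, [[0.03, -0.01]] * 2, atol=1e-14)

    def test_on_node_weight(self):
        # a point on a node draws weight 0.25 from that node in 2D
        f = uniform_field()
        f._ux[8, 9] = 1.0
        pts = ib.LagrangianSet(X=[[9.0, 8.0]], ds=0.5)
        U = ib.interpolate_velocity(f, pts)
        assert U[0, 0] == pytest.approx(0.25)

    def test_linear_field_second_order(self):
        errs = []
        for n in (10, 20):
            f = uniform_field(ny=4 * n, nx=4 * n)
            yy, xx = np.meshgrid(np.arange(4 * n), np.arange(4 * n),
                                 indexing="ij")
            f._ux[:] = 1e-3 * xx + 2e-3 * yy
            pts = ib.LagrangianSet(X=[[2 * n + 0.37, 2 * n + 0.61]], ds=0.5)
            U = ib.interpolate_velocity(f, pts)
            exact = 1e-3 * (2 * n + 0.37) + 2e-3 * (2 * n + 0.61)
            errs.append(abs(U[0, 0] - exact))
        # linear fields are reproduced to round-off (kernel has exact
        # zeroth and first moments)
        assert max(errs) < 1e-12

    def test_out_of_domain_raises(self):
        f = uniform_field()
        f.periodic = False
        pts = ib.LagrangianSet(X=[[0.5, 5.0]], ds=0.5)
        with pytest.raises(ib.OutOfDomainError, match="0"):
            ib.interpolate_velocity(f, pts)


class TestSpreading:
    def test_zero_forces_leave_field_clean(self):
        f = uniform_field()
        pts = ib.LagrangianSet(X=[[5.0, 5.0]], ds=0.5)
        ib.spread_force(pts, f)
        assert np.all(f.fx == 0) and np.all(f.fy == 0)

    def test_total_force_conserved(self):
        f = uniform_field()
        pts = ib.LagrangianSet(X=[[5.3, 6.7]], ds=0.8)
        pts.F = np.array([[1.0, -0.5]])
        ib.spread_force(pts, f)
        assert f.fx.sum() == pytest.approx(1.0 * 0.8, rel=1e-12)
        assert f.fy.sum() == pytest.approx(-0.5 * 0.8, rel=1e-12)

    def test_adjointness_with_interpolation(self):
        """<interp(u), F ds> = <u, spread(F)> for random u and F."""
        rng = np.random.default_rng(11)
        f = uniform_field(ny=16, nx=16)
        f._ux[:] = rng.standard_normal((16, 16))
        f._uy[:] = rng.standard_normal((16, 16))
        X = rng.uniform(4, 12, size=(7, 2))
        F = rng.standard_normal((7, 2))
        pts = ib.LagrangianSet(X=X, ds=0.6)
        U = ib.interpolate_velocity(f, pts)
        lhs = np.sum(U * F * pts.ds[:, None])
        f2 = uniform_field(ny=16, nx=16)
        pts2 = ib.LagrangianSet(X=X, ds=0.6, F=F)
        ib.spread_force(pts2, f2)
        rhs = np.sum(f2.fx * f._ux) + np.sum(f2.fy * f._uy)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestFeedback:
    def test_zero_error_zero_force(self):
        pts = ib.LagrangianSet(X=np.zeros((3, 2)) + 5, ds=0.5)
        st_ = ib.FeedbackState(alpha1=-1.0, alpha2=-0.5, n_points=3)
        for _ in range(5):
            F = ib.feedback_force(pts, np.zeros((3, 2)), st_, dt=1.0)
        assert np.allclose(F, 0.0)

    def test_proportional_term(self):
        pts = ib.LagrangianSet(X=np.zeros((1, 2)) + 5, ds=0.5)
        st_ = ib.FeedbackState(alpha1=-1e-300, alpha2=-0.5, n_points=1)
        e = np.array([[0.02, -0.01]])
        F = ib.feedback_force(pts, e, st_, dt=1.0)
        assert np.allclose(F, -0.5 * e, atol=1e-12)

    def test_integral_accumulation(self):
        pts = ib.LagrangianSet(X=np.zeros((1, 2)) + 5, ds=0.5)
        st_ = ib.FeedbackState(alpha1=-2.0, alpha2=-1e-300, n_points=1)
        e = np.array([[0.01, 0.0]])
        k, dt = 7, 0.5
        for _ in range(k):
            F = ib.feedback_force(pts, e, st_, dt=dt)
        assert F[0, 0] == pytest.approx(-2.0 * 0.01 * k * dt, rel=1e-12)

    def test_nonnegative_constants_rejected(self):
        with pytest.raises(lc.ConfigurationError):
            ib.FeedbackState(alpha1=0.0, alpha2=-1.0, n_points=1)


class TestAdvection:
    def test_zero_velocity_fixed(self):
        pts = ib.LagrangianSet(X=[[5.0, 5.0]], ds=0.5)
        ib.advect_points(pts, np.zeros((1, 2)), dt=1.0)
        assert np.allclose(pts.X, [[5.0, 5.0]])

    def test_rigid_translation(self):
        X0 = np.array([[5.0, 5.0], [6.0, 5.0]])
        pts = ib.LagrangianSet(X=X0.copy(), ds=0.5)
        U = np.tile([[0.1, -0.2]], (2, 1))
        ib.advect_points(pts, U, dt=0.5)
        assert np.allclose(pts.X, X0 + [0.05, -0.1])

    def test_overlarge_step_rejected(self):
        pts = ib.LagrangianSet(X=[[5.0, 5.0]], ds=0.5)
        with pytest.raises(ib.StabilityError):
            ib.advect_points(pts, np.array([[1.5, 0.0]]), dt=1.0)

    def test_spacing_contract_enforced(self):
        with pytest.raises(lc.ConfigurationError):
            ib.LagrangianSet(X=[[1.0, 1.0], [3.0, 1.0]], ds=1.5)


class TestRigidNoSlip:
    def test_cylinder_held_in_stream(self):
        """Feedback forcing drives the boundary slip velocity to under
        1% of the free-stream speed."""
        from pinchflow.simulation import Simulator
        from pinchflow._kernels import FLUID, PPORT, SLIP, VPORT

        U0 = 0.05
        ny, nx = 64, 96
        mask = np.full((ny, nx), FLUID, np.uint8)
        mask[0, :] = SLIP
        mask[-1, :] = SLIP
        spec = lc.LatticeSpec(tau=0.7)
        u0 = np.zeros((ny, nx, 2))
        u0[..., 0] = U0
        f = lc.LatticeField(spec=spec, mask=mask, u=u0)
        ys = np.arange(1, ny - 1)
        ut = np.zeros((len(ys), 2))
        ut[:, 0] = U0
        f.ports = [
            lc.PortGroup(name="in", y=ys, x=np.zeros(len(ys), int),
                         normal=(0, 1), kind="velocity", u_target=ut),
            lc.PortGroup(name="out", y=ys, x=np.full(len(ys), nx - 1),
                         normal=(0, -1), kind="pressure",
                         rho_target=np.ones(len(ys))),
        ]
        X, ds = ib.circle_points((32.0, 32.0), 6.0, 0.6)
        pts = ib.LagrangianSet(X=X, ds=ds, role="rigid")
        sim = Simulator(field=f)
        sim.add_rigid(pts, alpha1=-0.05, alpha2=-2.0)
        sim.run(4000)
        u_b = ib.interpolate_velocity(f, pts)
        assert np.sqrt(np.mean(u_b ** 2)) < 0.01 * U0
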