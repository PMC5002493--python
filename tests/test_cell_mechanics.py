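"""Membrane force model: analytic limits, force balance, relaxation."""

import numpy as np
import pytest

from pinchflow import cell_mechanics as cm
from pinchflow import lattice_core as lc


def circle_membrane(r=10.0, n=120, center=(0.0, 0.0), **kw):
    th = 2 * np.pi * np.arange(n) / n
    X = np.stack([center[0] + r * np.cos(th),
                  center[1] + r * np.sin(th)], axis=1)
    ds = 2 * np.pi * r / n
    return cm.Membrane(X=X, ds=ds, S0=np.pi * r * r, **kw)


class TestEnclosedArea:
    def test_circle(self):
        m = circle_membrane(r=10.0, n=120)
        assert cm.enclosed_area(m) == pytest.approx(np.pi * 100, rel=0.002)

    def test_unit_square(self):
        X = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        # need >= 5 points: refine edges
        Xf = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1],
                       [0.5, 1], [0, 1], [0, 0.5]], float)
        m = cm.Membrane(X=Xf, ds=0.5, S0=1.0)
        assert cm.enclosed_area(m) == pytest.approx(1.0)

    def test_translation_invariance(self):
        m1 = circle_membrane(center=(0, 0))
        m2 = circle_membrane(center=(137.2, -9.4))
        assert cm.enclosed_area(m1) == pytest.approx(cm.enclosed_area(m2))

    def test_ccw_enforced(self):
        th = 2 * np.pi * np.arange(20) / 20
        X = np.stack([np.cos(-th), np.sin(-th)], axis=1)  # clockwise
        m = cm.Membrane(X=X, ds=2 * np.pi / 20, S0=np.pi)
        assert cm._signed_area(m.X) > 0


class TestTensileForce:
    def test_unstretched_circle_force_free(self):
        m = circle_membrane(Kl=0.5)
        # reference spacing = chord length of the sampled circle
        m.ds = float(np.linalg.norm(m.X[1] - m.X[0]))
        F = cm.tensile_force(m)
        assert np.max(np.abs(F)) < 1e-10 * m.Kl

    def test_inflated_circle_pulls_inward_and_balances(self):
        m = circle_membrane(r=10.0, Kl=0.5)
        m.ds = float(np.linalg.norm(m.X[1] - m.X[0]))
        m.X = m.X * 1.1
        F = cm.tensile_force(m)
        radial = np.sum(F * (m.X / np.linalg.norm(m.X, axis=1)[:, None]),
                        axis=1)
        assert np.all(radial < 0)                      # restoring
        assert np.allclose(F.sum(axis=0), 0, atol=1e-12)

    def test_linear_in_stiffness(self):
        m1 = circle_membrane(Kl=0.2)
        m2 = circle_membrane(Kl=0.6)
        m1.X = m2.X = m1.X * 1.05
        assert np.allclose(3 * cm.tensile_force(m1), cm.tensile_force(m2))

    def test_degenerate_segment_rejected(self):
        m = circle_membrane(n=12)
        m.X[3] = m.X[4]
        with pytest.raises(cm.GeometryError):
            cm.tensile_force(m)


class TestBendingForce:
    def test_circle_matches_analytic_fourth_derivative(self):
        # for X(s) on a circle of radius R, d4X/ds4 = X / R^4
        R, n = 20.0, 400
        m = circle_membrane(r=R, n=n, Kb=1.0)
        F = cm.bending_force(m)
        expected = m.Kb * (m.X / R ** 4)
        assert np.allclose(F, expected, rtol=5e-3, atol=1e-8)

    def test_refinement_convergence(self):
        R = 15.0
        mags = []
        for n in (200, 400):
            m = circle_membrane(r=R, n=n, Kb=1.0)
            mags.append(np.linalg.norm(cm.bending_force(m)[0]))
        assert abs(mags[1] - mags[0]) / mags[1] < 0.02

    def test_closed_chain_balance(self):
        rng = np.random.default_rng(5)
        m = circle_membrane(n=64, Kb=0.3)
        m.X = m.X + 0.3 * rng.standard_normal(m.X.shape)
        assert np.allclose(cm.bending_force(m).sum(axis=0), 0, atol=1e-10)

    def test_too_few_points_rejected(self):
        X = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        with pytest.raises(cm.GeometryError):
            cm.Membrane(X=X, ds=1.0, S0=1.0)


class TestAreaForce:
    def test_zero_at_reference_area(self):
        m = circle_membrane()
        m.S0 = cm.enclosed_area(m)
        assert np.allclose(cm.area_force(m), 0.0, atol=1e-14)

    def test_magnitude_at_ten_percent_inflation(self):
        m = circle_membrane(Ks=2.0)
        m.S0 = cm.enclosed_area(m) / 1.1
        F = cm.area_force(m)
        mags = np.linalg.norm(F, axis=1)
        assert np.allclose(mags, 0.1 * m.Ks, rtol=1e-9)

    def test_restoring_direction(self):
        m = circle_membrane(Ks=1.0)
        m.S0 = cm.enclosed_area(m) / 1.1          # inflated -> inward
        F = cm.area_force(m)
        nrm = cm.outward_normals(m)
        assert np.all(np.sum(F * nrm, axis=1) < 0)
        m.S0 = cm.enclosed_area(m) * 1.1          # deflated -> outward
        F = cm.area_force(m)
        assert np.all(np.sum(F * nrm, axis=1) > 0)


class TestWallRepulsion:
    def walls(self):
        return cm.WallSet([[[-50.0, -15.0], [50.0, -15.0]]])

    def test_zero_beyond_cutoff(self):
        m = circle_membrane(r=10.0, Ke=1.0, rc=2.0)
        # closest approach to the wall y=-15 is 5 > rc
        F = cm.wall_repulsion(m, self.walls())
        assert np.all(F == 0)

    def test_inverse_square_magnitude(self):
        m = circle_membrane(r=10.0, center=(0.0, -4.0), Ke=1.0, rc=2.0)
        # lowest point at y=-14, gap d=1
        F = cm.wall_repulsion(m, self.walls())
        k = np.argmin(m.X[:, 1])
        assert np.linalg.norm(F[k]) == pytest.approx(1.0, rel=1e-9)
        assert F[k, 1] > 0                        # points away from wall

    def test_singularity_clamped(self):
        # gap 0.05 below the clamp distance: magnitude capped at Ke/0.1^2
        m = circle_membrane(r=10.0, center=(0.0, -4.95), Ke=1.0, rc=2.0)
        F = cm.wall_repulsion(m, self.walls())
        assert np.all(np.isfinite(F))
        k = np.argmin(m.X[:, 1])
        assert np.linalg.norm(F[k]) == pytest.approx(1.0 / 0.1 ** 2,
                                                     rel=1e-6)


class TestTotalForce:
    def test_all_zero_stiffness(self):
        m = circle_membrane(Kl=0, Kb=0, Ks=0, Ke=0)
        assert np.allclose(cm.total_membrane_force(m, None), 0.0)

    def test_recomposition(self):
        rng = np.random.default_rng(2)
        m = circle_membrane(n=48, Kl=0.3, Kb=0.05, Ks=1.0, Ke=0.01)
        m.X = m.X + 0.2 * rng.standard_normal(m.X.shape)
        w = cm.WallSet([[[-50.0, -12.0], [50.0, -12.0]]])
        F = cm.total_membrane_force(m, w)
        ref = (cm.tensile_force(m) - cm.bending_force(m)
               + cm.area_force(m) + cm.wall_repulsion(m, w))
        assert np.allclose(F, ref)


class TestCircleFactory:
    def test_point_budget_and_spacing(self):
        m = cm.Membrane.circle((0, 0), diameter=12.0)
        assert m.n_points() >= 3 * 12
        assert m.ds <= 1.0

    def test_area_reference(self):
        m = cm.Membrane.circle((0, 0), diameter=16.0)
        assert m.S0 == pytest.approx(np.pi * 64)
        assert cm.enclosed_area(m) == pytest.approx(m.S0, rel=2e-3)


class TestFluidCoupledRelaxation:
    def test_inflated_cell_relaxes_to_reference_area(self):
        """A 10%-inflated cell in quiescent fluid returns to its
        reference area (within 2%) with monotonically decreasing |S-S0|."""
        from pinchflow.simulation import Simulator

        spec = lc.LatticeSpec(tau=0.8)
        f = lc.make_periodic_field(48, 48, spec)
        m = cm.Membrane.circle((24.0, 24.0), diameter=12.0,
                               Kl=0.05, Kb=0.002, Ks=2.0, Ke=0.0)
        m.X = (m.X - 24.0) * np.sqrt(1.1) + 24.0   # inflate area by 10%
        sim = Simulator(field=f)
        sim.add_membrane(m)
        errs = [abs(cm.enclosed_area(m) - m.S0)]
        for _ in range(4):
            sim.run(500, guard_every=0)
            errs.append(abs(cm.enclosed_area(m) - m.S0))
        assert errs[-1] / m.S0 < 0.02
        assert all(e1 <= e0 * 1.05 for e0, e1 in zip(errs, errs[1:]))
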