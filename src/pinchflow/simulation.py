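"""Coupled IB-LBM time stepper.

One update per lattice step: membrane elastic forces (from positions) and
rigid-body feedback forces (from the interpolated boundary velocity) are
spread to the lattice, the fluid is advanced by one collide-and-stream,
and the membranes are advected with the freshly computed macroscopic
velocity (forward Euler, one IB update per LBM step).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import cell_mechanics as cm
from . import immersed_coupling as ib
from .device_geometry import (DeviceGeometry, DeviceParams, FluxReport,
                              apply_port_conditions, build_device,
                              measure_fluxes)
from .lattice_core import InvalidStateError, LatticeField, LatticeSpec


@dataclass
class RigidBody:
    pts: ib.LagrangianSet
    state: ib.FeedbackState
    force_history: list = dc_field(default_factory=list)  # (sum Fx ds, sum Fy ds)


@dataclass
class Simulator:
    field: LatticeField
    walls: cm.WallSet | None = None
    membranes: list = dc_field(default_factory=list)
    rigid_bodies: list = dc_field(default_factory=list)
    ramp_steps: int = 0
    divergence_guard: float = 0.5     # abort when max|u| exceeds this * c_s
    body_force: tuple | None = None   # uniform (fx, fy) re-applied each step
    flux_beta: float | None = None    # outlet-split controller target
    flux_update_every: int = 200
    _base_u_targets: list = dc_field(default_factory=list)

    def __post_init__(self):
        self._base_u_targets = [
            (p, p.u_target.copy()) for p in self.field.ports
            if p.kind in ("velocity", "velocity_eq")
            and p.u_target is not None]

    def _update_flux_targets(self):
        """Rescale the outlet velocity targets so the *mass* outflow of
        outlets 1-3 is (1 - beta)/3 of the measured inlet mass flux each
        (the free pressure outlet 4 then takes the fraction beta).  Both
        sides are measured with the same link-plane operator the flux
        audit uses, so the closed loop converges to exact closure."""
        from .device_geometry import link_mass_flux

        qm_in = 0.0
        outlets = []
        for p, base in self._base_u_targets:
            if p.name.startswith("in"):
                qm_in += link_mass_flux(self.field, p.y, p.x, p.normal)
            else:
                outlets.append((p, base))
        if not outlets or qm_in <= 0:
            return
        target = (1.0 - self.flux_beta) / 3.0 * qm_in
        for p, base in outlets:
            cur = -link_mass_flux(self.field, p.y, p.x, p.normal)
            if cur > 0:
                base *= target / cur

    def add_membrane(self, m: cm.Membrane):
        self.membranes.append(m)

    def add_rigid(self, pts: ib.LagrangianSet, alpha1: float,
                  alpha2: float, U_target=None) -> RigidBody:
        st = ib.FeedbackState(alpha1=alpha1, alpha2=alpha2,
                              n_points=len(pts))
        if U_target is not None:
            st.U_target[:] = U_target
        body = RigidBody(pts=pts, state=st)
        self.rigid_bodies.append(body)
        return body

    def _ramp_factor(self):
        if self.ramp_steps <= 0:
            return 1.0
        t = self.field.time_step
        if t >= self.ramp_steps:
            return 1.0
        return 0.5 * (1.0 - np.cos(np.pi * t / self.ramp_steps))

    def step(self, record_forces: bool = False):
        fld = self.field
        dt = fld.spec.dt
        if (self.flux_beta is not None
                and fld.time_step % self.flux_update_every == 0):
            self._update_flux_targets()
        r = self._ramp_factor()
        for p, base in self._base_u_targets:
            p.u_target = base * r if r < 1.0 else base
        fld.clear_forces()
        if self.body_force is not None:
            fld.fx[:] += self.body_force[0]
            fld.fy[:] += self.body_force[1]
        for m in self.membranes:
            pts = getattr(m, "_pts", None)
            if pts is None or len(pts) != len(m.X):
                pts = ib.LagrangianSet(X=m.X, ds=m.ds, role="membrane")
                m._pts = pts
            pts.X = m.X
            pts.F = cm.total_membrane_force_fast(m, self.walls)
            ib.spread_force(pts, fld)
        for body in self.rigid_bodies:
            u_b = ib.interpolate_velocity(fld, body.pts)
            body.pts.F = ib.feedback_force(body.pts, u_b, body.state, dt)
            ib.spread_force(body.pts, fld)
            if record_forces:
                w = body.pts.ds
                body.force_history.append(
                    (float(np.sum(body.pts.F[:, 0] * w)),
                     float(np.sum(body.pts.F[:, 1] * w))))
        fld.step()
        for m in self.membranes:
            pts = m._pts
            U = ib.interpolate_velocity(fld, pts)
            m.X = pts.X = m.X + U * dt

    def run(self, n_steps: int, record_forces: bool = False,
            guard_every: int = 200):
        cs = self.field.spec.c_s
        for _ in range(n_steps):
            self.step(record_forces=record_forces)
            if guard_every and self.field.time_step % guard_every == 0:
                self.field.check_finite()
                umax = max(np.abs(self.field.ux).max(),
                           np.abs(self.field.uy).max())
                if umax > self.divergence_guard * cs:
                    raise InvalidStateError(
                        f"divergence guard: max|u|={umax:.3g} exceeds "
                        f"{self.divergence_guard:.2f} c_s at step "
                        f"{self.field.time_step}")

    def run_to_stationary(self, geometry: DeviceGeometry,
                          tol: float = 1e-5, window: int = 1000,
                          max_steps: int = 200_000,
                          min_steps: int = 0) -> FluxReport:
        """Advance until the port fluxes change by less than ``tol``
        (relative to the total inflow) over ``window`` steps."""
        prev = None
        n_done = 0
        min_steps = max(min_steps, self.ramp_steps + window)
        while n_done < max_steps:
            self.run(window)
            n_done += window
            rep = measure_fluxes(self.field, geometry)
            q = np.array([rep.Q_in1, rep.Q_in2, *rep.Q_out])
            if prev is not None and n_done >= min_steps:
                qtot = abs(rep.Q_in1 + rep.Q_in2)
                if np.max(np.abs(q - prev)) < tol * qtot:
                    return rep
            prev = q
        import warnings

        warnings.warn(f"flow not stationary after {max_steps} steps "
                      "(returning last flux report)", RuntimeWarning,
                      stacklevel=2)
        return measure_fluxes(self.field, geometry)


def device_simulator(params: DeviceParams = DeviceParams(),
                     resolution_scale: float = 1.0,
                     alpha: float = 1.0, beta: float = 0.25,
                     tau: float = 1.0, u_sum: float = 0.01,
                     mode: str = "flux", rho4_offset: float | None = None,
                     ramp_steps: int = 2000,
                     geometry: DeviceGeometry | None = None
                     ) -> tuple[Simulator, DeviceGeometry]:
    """Build a ready-to-run simulator for the sorting device."""
    geom = geometry or build_device(params, resolution_scale)
    spec = LatticeSpec(tau=tau)
    fld = LatticeField(spec=spec, mask=geom.mask)
    apply_port_conditions(fld, geom, alpha=alpha, beta=beta, u_sum=u_sum,
                          mode=mode, rho4_offset=rho4_offset)
    sim = Simulator(field=fld, walls=geom.walls, ramp_steps=ramp_steps)
    return sim, geom


def stationary_flux_report(params: DeviceParams, resolution_scale: float,
                           alpha: float = 1.0, beta: float = 0.25,
                           mode: str = "flux",
                           rho4_offset: float | None = None,
                           u_sum: float = 0.01, tau: float = 1.0,
                           tol: float = 1e-5,
                           max_steps: int = 120_000) -> FluxReport:
    """Pure-fluid stationary solve of the device; used for resistance
    calibration and flux audits."""
    sim, geom = device_simulator(params, resolution_scale, alpha=alpha,
                                 beta=beta, tau=tau, u_sum=u_sum, mode=mode,
                                 rho4_offset=rho4_offset)
    return sim.run_to_stationary(geom, tol=tol, max_steps=max_steps)
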