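"""Immersed-boundary transfer operators.

A Lagrangian point set (rigid boundary or cell membrane) exchanges
momentum with the Eulerian lattice through a smoothed delta kernel: fluid
velocity is interpolated to the points, point forces are spread back as a
body-force density.  Rigid boundaries are enforced by feedback (penalty)
forcing: a restoring force proportional to the velocity error at the
boundary and to its time integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .lattice_core import ConfigurationError, LatticeField


class OutOfDomainError(RuntimeError):
    pass


class StabilityError(RuntimeError):
    pass


def delta_kernel(r):
    """Peskin's four-point smoothed delta (1D factor), support |r| <= 2.

    Continuous at |r| = 1 and |r| = 2, nonnegative, and satisfies the
    partition of unity sum_j delta(j - x) = 1 on the integer grid.
    """
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    out[m1] = (3 - 2 * a[m1] + np.sqrt(1 + 4 * a[m1] - 4 * a[m1] ** 2)) / 8
    m2 = (a > 1.0) & (a <= 2.0)
    out[m2] = (5 - 2 * a[m2] - np.sqrt(-7 + 12 * a[m2] - 4 * a[m2] ** 2)) / 8
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(eq=False)
class LagrangianSet:
    """Ordered Lagrangian points with per-point force and arclength weight.

    Point spacing must not exceed one lattice unit (coupling-accuracy
    contract of the delta-kernel transfer).
    """

    X: np.ndarray                 # (n, 2) positions in lattice units
    ds: np.ndarray                # (n,) arclength weight per point
    role: str = "membrane"        # "membrane" | "rigid"
    F: np.ndarray = None          # (n, 2) force per unit arclength

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.ds = np.broadcast_to(
            np.asarray(self.ds, dtype=float), (len(self.X),)).copy()
        if self.F is None:
            self.F = np.zeros_like(self.X)
        if np.any(self.ds > 1.0 + 1e-12):
            raise ConfigurationError(
                "Lagrangian point spacing exceeds 1 lattice unit")

    def __len__(self):
        return len(self.X)


@dataclass
class FeedbackState:
    """State of the feedback (penalty) rigid-boundary forcing.

    alpha1 and alpha2 are large *negative* constants multiplying the time
    integral of the boundary velocity error and the instantaneous error.
    """

    alpha1: float
    alpha2: float
    n_points: int
    U_target: np.ndarray = None          # (n, 2) prescribed velocity
    integral_error: np.ndarray = None    # (n, 2)

    def __post_init__(self):
        if self.alpha1 >= 0 or self.alpha2 >= 0:
            raise ConfigurationError(
                "feedback constants alpha1, alpha2 must be negative")
        if self.U_target is None:
            self.U_target = np.zeros((self.n_points, 2))
        if self.integral_error is None:
            self.integral_error = np.zeros((self.n_points, 2))


def _check_in_domain(field: LatticeField, X):
    ny, nx = field.mask.shape
    bad = np.where((X[:, 0] < 2) | (X[:, 0] > nx - 3)
                   | (X[:, 1] < 2) | (X[:, 1] > ny - 3))[0]
    if len(bad):
        raise OutOfDomainError(
            f"Lagrangian point(s) {bad[:5].tolist()} outside the "
            "halo-shrunk domain")


def interpolate_velocity(field: LatticeField, pts: LagrangianSet,
                         u=None) -> np.ndarray:
    """Velocity at the Lagrangian points, U_k = sum_x u(x) D(x - X_k).

    By default interpolates the field's current macroscopic velocity
    arrays; pass ``u`` (ny, nx, 2) to interpolate another field.
    On periodic fields the stencil wraps around the domain.
    """
    if not field.periodic:
        _check_in_domain(field, pts.X)
    out = np.empty((len(pts), 2))
    if u is None:
        ux, uy = field.ux, field.uy
    else:
        ux = np.ascontiguousarray(u[..., 0])
        uy = np.ascontiguousarray(u[..., 1])
    K.interp_kernel(ux, uy, np.ascontiguousarray(pts.X[:, 0]),
                    np.ascontiguousarray(pts.X[:, 1]), out,
                    field.periodic)
    return out


def spread_force(pts: LagrangianSet, field: LatticeField,
                 accumulate: bool = True) -> None:
    """Spread point forces onto the field's body-force density,
    f(x) += sum_k F_k D(x - X_k) ds_k.  Conserves total force exactly."""
    if not field.periodic:
        _check_in_domain(field, pts.X)
    if not accumulate:
        field.clear_forces()
    K.spread_kernel(np.ascontiguousarray(pts.X[:, 0]),
                    np.ascontiguousarray(pts.X[:, 1]),
                    np.ascontiguousarray(pts.F[:, 0]),
                    np.ascontiguousarray(pts.F[:, 1]),
                    pts.ds, field.fx, field.fy, field.periodic)


def feedback_force(pts: LagrangianSet, u_interp: np.ndarray,
                   state: FeedbackState, dt: float) -> np.ndarray:
    """Penalty force F = alpha1 * int (u - U) dt + alpha2 * (u - U).

    Advances the accumulated velocity-error integral in ``state`` and
    returns the per-point force (per unit arclength).
    """
    err = u_interp - state.U_target
    state.integral_error += err * dt
    return state.alpha1 * state.integral_error + state.alpha2 * err


def advect_points(pts: LagrangianSet, U: np.ndarray, dt: float,
                  max_step: float = 1.0) -> LagrangianSet:
    """Forward-Euler update X <- X + U dt (one IB update per LBM step)."""
    step = np.asarray(U) * dt
    m = np.max(np.abs(step)) if len(step) else 0.0
    if m > max_step:
        raise StabilityError(
            f"Lagrangian step {m:.3g} exceeds one lattice unit")
    pts.X = pts.X + step
    return pts


def circle_points(center, radius, spacing) -> tuple[np.ndarray, float]:
    """Evenly spaced points on a circle with spacing <= the requested one.

    Returns (points (n,2), actual spacing)."""
    n = max(4, int(np.ceil(2 * np.pi * radius / spacing)))
    th = 2 * np.pi * np.arange(n) / n
    pts = np.stack([center[0] + radius * np.cos(th),
                    center[1] + radius * np.sin(th)], axis=1)
    return pts, 2 * np.pi * radius / n
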