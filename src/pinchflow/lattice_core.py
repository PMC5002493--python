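"""D2Q9 single-relaxation-time lattice Boltzmann core.

The solver evolves nine particle populations g_i per node under BGK
collision with Guo's forcing discretization, recovering the incompressible
Navier-Stokes equations at low Mach number with kinematic viscosity
nu = (tau - 0.5) c_s^2 dt.  Walls are halfway bounce-back; open ports use
non-equilibrium extrapolation of either a target velocity (inlets) or a
target density/pressure (outlets).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels as K
from ._kernels import FLUID, PPORT, SLIP, SOLID, VPORT


class InvalidStateError(RuntimeError):
    """Raised for nonphysical field states (rho <= 0, NaN populations)."""


class ConfigurationError(ValueError):
    """Raised for invalid solver parameters (e.g. tau <= 0.5)."""


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice constants of the D2Q9 model.

    h is the lattice spacing, dt the time step and tau the nondimensional
    BGK relaxation time (must exceed 0.5 for positive viscosity).
    """

    h: float = 1.0
    dt: float = 1.0
    tau: float = 1.0

    def __post_init__(self):
        if self.h <= 0 or self.dt <= 0:
            raise ConfigurationError("h and dt must be positive")
        if self.tau <= 0.5:
            raise ConfigurationError(
                f"tau={self.tau} gives nonpositive viscosity; need tau > 0.5")

    @property
    def c(self) -> float:
        return self.h / self.dt

    @property
    def c_s(self) -> float:
        return self.c / np.sqrt(3.0)

    @property
    def directions(self) -> np.ndarray:
        """The nine lattice velocity vectors, shape (9, 2)."""
        return np.stack([K.EX, K.EY], axis=1) * self.c

    @property
    def weights(self) -> np.ndarray:
        return K.W.copy()

    @property
    def viscosity(self) -> float:
        return viscosity_from_tau(self.tau, self)


def viscosity_from_tau(tau: float, spec: LatticeSpec) -> float:
    """Kinematic viscosity nu = (tau - 0.5) c_s^2 dt of the BGK model."""
    if tau <= 0.5:
        raise ConfigurationError(
            f"tau={tau} gives nonpositive viscosity; need tau > 0.5")
    return (tau - 0.5) * spec.c_s**2 * spec.dt


def equilibrium_distribution(rho, u, spec: LatticeSpec) -> np.ndarray:
    """Maxwellian truncated to second order in u.

    rho may be a scalar or (...,) array; u a (..., 2) array (or length-2
    vector).  Returns populations with a leading axis of length 9.
    Satisfies sum_i g_i = rho and sum_i e_i g_i = rho u exactly.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise InvalidStateError("equilibrium requires rho > 0")
    cs2 = spec.c_s**2
    umag = np.sqrt(np.sum(u**2, axis=-1))
    if np.any(umag > 0.3 * spec.c_s):
        import warnings

        warnings.warn("velocity above 0.3 c_s: low-Mach contract strained",
                      RuntimeWarning, stacklevel=2)
    e = self_directions = np.stack([K.EX, K.EY], axis=1) * spec.c  # (9, 2)
    eu = np.tensordot(e, np.moveaxis(u, -1, 0), axes=(1, 0)) / cs2  # (9, ...)
    usq = np.sum(u**2, axis=-1) / cs2
    w = K.W.reshape((9,) + (1,) * rho.ndim)
    return w * rho * (1.0 + eu + 0.5 * eu**2 - 0.5 * usq)


def forcing_term(u, f, spec: LatticeSpec) -> np.ndarray:
    """Guo forcing populations G_i; sum_i G_i = 0 and
    sum_i e_i G_i = (1 - 1/(2 tau)) f."""
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(f))):
        raise InvalidStateError("non-finite input to forcing_term")
    cs2 = spec.c_s**2
    e = np.stack([K.EX, K.EY], axis=1) * spec.c  # (9, 2)
    eu = np.tensordot(e, np.moveaxis(u, -1, 0), axes=(1, 0)) / cs2
    # ((e - u)/cs2 + (e.u) e /cs4) . f
    ef = np.tensordot(e, np.moveaxis(f, -1, 0), axes=(1, 0)) / cs2
    uf = np.sum(u * f, axis=-1) / cs2
    w = K.W.reshape((9,) + (1,) * np.asarray(uf).ndim)
    pref = 1.0 - 0.5 / spec.tau
    return pref * w * (ef - uf + eu * ef)


@dataclass
class PortGroup:
    """A contiguous set of boundary nodes acting as one flow port."""

    name: str
    y: np.ndarray           # node indices
    x: np.ndarray
    normal: tuple           # (dy, dx) unit step pointing into the fluid
    kind: str = "velocity"  # "velocity" | "pressure"
    u_target: np.ndarray | None = None   # (n, 2), velocity ports
    rho_target: np.ndarray | None = None  # (n,), pressure ports

    @property
    def nb(self):
        return self.y + self.normal[0], self.x + self.normal[1]


@dataclass
class LatticeField:
    """Eulerian state: populations, macroscopic fields, force and mask."""

    spec: LatticeSpec
    mask: np.ndarray
    g: np.ndarray = None
    rho: np.ndarray = None
    u: np.ndarray = None
    f: np.ndarray = None
    ports: list = dc_field(default_factory=list)
    periodic: bool = False
    time_step: int = 0

    def __post_init__(self):
        ny, nx = self.mask.shape
        if self.rho is None:
            self.rho = np.ones((ny, nx))
        if self.u is None:
            self.u = np.zeros((ny, nx, 2))
        if self.f is None:
            self.f = np.zeros((ny, nx, 2))
        if self.g is None:
            self.g = np.ascontiguousarray(
                equilibrium_distribution(self.rho, self.u, self.spec))
        self._gpost = np.empty_like(self.g)
        # fast-path nodes: interior fluid with all-streamable 3x3 sources
        streamable = (self.mask != SOLID) & (self.mask != SLIP)
        easy = (self.mask == FLUID).astype(np.uint8)
        ok = streamable.copy()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ok &= np.roll(np.roll(streamable, dy, axis=0), dx, axis=1)
        easy &= ok.astype(np.uint8)
        easy[0, :] = easy[-1, :] = 0
        easy[:, 0] = easy[:, -1] = 0
        self._easy = easy
        self._ux = np.ascontiguousarray(self.u[..., 0])
        self._uy = np.ascontiguousarray(self.u[..., 1])
        self._fx = np.ascontiguousarray(self.f[..., 0])
        self._fy = np.ascontiguousarray(self.f[..., 1])
        self.u = np.stack([self._ux, self._uy], axis=-1)

    # -- views kept in sync manually for kernel speed ------------------
    @property
    def ux(self):
        return self._ux

    @property
    def uy(self):
        return self._uy

    @property
    def fx(self):
        return self._fx

    @property
    def fy(self):
        return self._fy

    @property
    def p(self):
        return self.rho * self.spec.c_s**2

    def velocity(self) -> np.ndarray:
        """(ny, nx, 2) macroscopic velocity (copies from kernel arrays)."""
        return np.stack([self._ux, self._uy], axis=-1)

    def clear_forces(self):
        self._fx[:] = 0.0
        self._fy[:] = 0.0

    def refresh_moments(self):
        """Recompute rho and the *bare* momentum-based velocity from g
        (no half-force shift); used before assembling this step's forces."""
        mx = np.empty_like(self.rho)
        my = np.empty_like(self.rho)
        K.moments_kernel(self.g, self.mask, self.rho, mx, my)
        c = self.spec.c
        fluid = self.mask != SOLID
        if np.any(self.rho[fluid] <= 0):
            raise InvalidStateError("nonpositive density on a fluid node")
        np.divide(mx * c, self.rho, out=self._ux)
        np.divide(my * c, self.rho, out=self._uy)
        self._ux[~fluid & (self.mask == SOLID)] = 0.0
        self._uy[~fluid & (self.mask == SOLID)] = 0.0

    def step(self):
        """One collide-and-stream update (forces must already be set)."""
        spec = self.spec
        K.collide_kernel(self.g, self._gpost, self.rho, self._ux, self._uy,
                         self._fx, self._fy, self.mask, spec.tau, spec.c,
                         spec.dt)
        K.stream_interior_kernel(self._gpost, self.g, self._easy)
        K.stream_kernel(self._gpost, self.g, self.mask, self._easy,
                        self.periodic)
        for p in self.ports:
            nby, nbx = p.nb
            kind = {"velocity": 0, "pressure": 1, "velocity_eq": 2}[p.kind]
            ut = p.u_target if p.u_target is not None else np.zeros((len(p.y), 2))
            rt = p.rho_target if p.rho_target is not None else np.ones(len(p.y))
            K.port_kernel(self.g, self.mask, self._fx, self._fy,
                          p.y, p.x, nby, nbx, kind,
                          np.ascontiguousarray(ut[:, 0]),
                          np.ascontiguousarray(ut[:, 1]),
                          np.ascontiguousarray(rt), spec.c, spec.dt)
        self.time_step += 1
        if not np.isfinite(self.g[0, :: max(1, self.g.shape[1] // 8), 0]).all():
            self.check_finite()

    def check_finite(self):
        if not np.all(np.isfinite(self.g)):
            raise InvalidStateError(
                f"population divergence at time step {self.time_step}")

    def total_mass(self) -> float:
        fluid = self.mask != SOLID
        return float(self.g[:, fluid].sum())


def macroscopics(field: LatticeField, spec: LatticeSpec | None = None):
    """(rho, u, p) from the populations, with the half-force velocity
    correction of the Guo scheme."""
    spec = spec or field.spec
    mx = np.empty_like(field.rho)
    my = np.empty_like(field.rho)
    rho = np.empty_like(field.rho)
    K.moments_kernel(field.g, field.mask, rho, mx, my)
    fluid = field.mask != SOLID
    if np.any(rho[fluid] <= 0):
        raise InvalidStateError("nonpositive density on a fluid node")
    c = spec.c
    u = np.zeros(field.mask.shape + (2,))
    u[..., 0] = (mx * c + 0.5 * field.fx * spec.dt) / rho
    u[..., 1] = (my * c + 0.5 * field.fy * spec.dt) / rho
    u[~fluid] = 0.0
    p = rho * spec.c_s**2
    return rho, u, p


def collide_and_stream(field: LatticeField, spec: LatticeSpec | None = None):
    """Functional wrapper over LatticeField.step (in place, returns field)."""
    if spec is not None and spec is not field.spec:
        field.spec = spec
    field.step()
    return field


def make_periodic_field(ny, nx, spec: LatticeSpec, rho=None, u=None):
    mask = np.full((ny, nx), FLUID, dtype=np.uint8)
    f = LatticeField(spec=spec, mask=mask, periodic=True)
    if rho is not None or u is not None:
        rho_arr = np.ones((ny, nx)) if rho is None else np.asarray(rho, float)
        u_arr = np.zeros((ny, nx, 2)) if u is None else np.asarray(u, float)
        f.rho = rho_arr
        f.g = np.ascontiguousarray(
            equilibrium_distribution(rho_arr, u_arr, spec))
        f._ux[:] = u_arr[..., 0]
        f._uy[:] = u_arr[..., 1]
    return f
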