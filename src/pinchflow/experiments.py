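"""Scripted studies: cylinder validation, inlet-ratio (alpha) sweep, and
size-dependent sorting experiments.

The cylinder benchmark reproduces the classical flow past a stationary
circular cylinder at Re = 40 (steady twin-vortex wake) and Re = 100
(periodic vortex street), with the cylinder held by feedback forcing on
an immersed boundary; drag/lift coefficients, the wake recirculation
length and the Strouhal number are the validation metrics.  The device
studies release deformable cells in U-branch 2 and track which D-branch
each cell enters as a function of the inlet flow ratio alpha, the
outlet-4 flux fraction beta, and the cell diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import immersed_coupling as ib
from ._kernels import FLUID, SLIP
from .cell_mechanics import Membrane
from .device_geometry import DeviceGeometry, DeviceParams
from .lattice_core import (ConfigurationError, LatticeField, LatticeSpec,
                           PortGroup)
from .simulation import Simulator


# ---------------------------------------------------------------------
# cylinder benchmark

# effective no-slip offset of a feedback-held four-point-kernel boundary,
# in lattice units; measured by ib_wall_offset (flat-wall Poiseuille
# oracle) and confirmed by the cylinder's front-stagnation position
KERNEL_OFFSET = 0.79


@dataclass
class CylinderBenchmarkConfig:
    """Flow past a stationary cylinder in a free stream.

    Full-scale domain is 1000 x 800 with the cylinder (diameter 40) at
    (301, 401); resolution_scale shrinks the grid while preserving the
    Reynolds number U_inf * D / nu.
    """

    L: float = 1000.0
    H: float = 800.0
    center: tuple = (301.0, 401.0)
    D: float = 40.0
    spacing: float = 0.6          # Lagrangian spacing, full-scale units
    Re: float = 40.0
    U_inf: float = 0.08           # lattice units (scale-independent)
    resolution_scale: float = 0.5
    alpha1: float = -0.05         # feedback constants (integral, instant)
    alpha2: float = -2.0
    perturb_window: tuple = (1500, 4000)   # inflow tilt to trigger shedding
    perturb_eps: float = 0.08
    max_steps: int = 120_000
    seed: int = 0
    # lateral (top/bottom) boundary: "open" holds the reference pressure
    # and lets the wake displace fluid laterally (far-field behaviour;
    # confinement otherwise inflates Cl and St at this 5% blockage);
    # "freestream" imposes u = (U_inf, 0); "slip" is a specular wall
    lateral: str = "open"
    # inlet realization: "eq" imposes the equilibrium populations of the
    # free stream (soft far-field inlet); "nebb" adds the extrapolated
    # non-equilibrium part (stiffer, builds a larger stagnation pressure
    # at this short inlet-to-cylinder distance)
    inlet_scheme: str = "eq"
    # The smoothed-delta boundary places its effective no-slip surface
    # about 0.8 lattice units outside the Lagrangian points (measured
    # with the plane-channel oracle, see ib_wall_offset).  At full scale
    # the Lagrangian points sit on the nominal circle, so the full-scale
    # effective diameter is D + 2 * KERNEL_OFFSET; scaled runs retract
    # the circle by KERNEL_OFFSET * (1 - scale), which preserves the
    # full-scale effective-to-nominal diameter ratio and with it the
    # effective Reynolds number of the setup being emulated.  Pass a
    # number to override (e.g. KERNEL_OFFSET for an exactly nominal
    # hydrodynamic diameter).
    boundary_offset: float | None = None

    @property
    def tau(self):
        s = self.resolution_scale
        nu = self.U_inf * self.D * s / self.Re
        return 0.5 + 3.0 * nu

    @property
    def retraction(self) -> float:
        if self.boundary_offset is not None:
            return self.boundary_offset
        return KERNEL_OFFSET * (1.0 - self.resolution_scale)

    def __post_init__(self):
        if self.tau <= 0.5:
            raise ConfigurationError("benchmark parameters give tau <= 0.5")


@dataclass
class DiagnosticsSeries:
    """Per-step drag/lift coefficients of the cylinder plus derived
    quantities (computed over an analysis window)."""

    t: np.ndarray
    Cd: np.ndarray
    Cl: np.ndarray
    dt: float
    D: float
    U_inf: float
    Lw: float | None = None
    analysis_start: int = 0

    def mean_cd(self):
        return float(np.mean(self.Cd[self.analysis_start:]))

    def cl_amplitude(self):
        """Half the peak-to-peak lift-coefficient excursion."""
        cl = self.Cl[self.analysis_start:]
        return float(0.5 * (np.max(cl) - np.min(cl)))

    def strouhal(self):
        return strouhal_number(self.Cl[self.analysis_start:], self.dt,
                               self.D, self.U_inf)


def drag_lift_coefficients(force_series, rho, U_inf, D):
    """Cd = FD / (0.5 rho U_inf^2 D), Cl likewise with the transverse
    force.  ``force_series`` holds the per-step feedback force exerted on
    the fluid; the hydrodynamic reaction on the cylinder is its negative.
    """
    if U_inf <= 0 or D <= 0:
        raise ValueError("U_inf and D must be positive")
    fs = np.asarray(force_series, dtype=float).reshape(-1, 2)
    norm = 0.5 * rho * U_inf ** 2 * D
    return -fs[:, 0] / norm, -fs[:, 1] / norm


def strouhal_number(cl, sample_dt, D, U_inf):
    """St = f_peak D / U_inf with f_peak the dominant spectral frequency
    of the lift series (Hann window, parabolic peak interpolation)."""
    cl = np.asarray(cl, dtype=float)
    cl = cl - np.mean(cl)
    if len(cl) < 16 or np.max(np.abs(cl)) == 0:
        raise ValueError("no oscillatory lift signal")
    w = np.hanning(len(cl))
    spec = np.abs(np.fft.rfft(cl * w))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if spec[k] < 1e-12 or k == 0:
        raise ValueError("no significant spectral peak in lift series")
    # parabolic interpolation around the peak bin
    if 0 < k < len(spec) - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    else:
        shift = 0.0
    f = (k + shift) / (len(cl) * sample_dt)
    # refine with upward zero-crossing timing when enough periods are
    # present (sub-bin accuracy on short windows)
    sgn = cl > 0
    up = np.where(~sgn[:-1] & sgn[1:])[0]
    if len(up) >= 5:
        # sub-sample crossing positions by linear interpolation
        t_up = up + cl[up] / (cl[up] - cl[up + 1])
        span = t_up[-1] - t_up[0]
        f_zc = (len(up) - 1) / (span * sample_dt)
        if abs(f_zc - f) < 0.25 * f:
            f = f_zc
    return float(f * D / U_inf)


def recirculation_length(field_or_profile, center, D):
    """Wake-bubble length behind the cylinder over the diameter: distance
    from the rear stagnation point to the downstream centerline position
    where the streamwise velocity changes sign (sub-node linear
    interpolation); 0 if the wake has no reversed flow.

    Accepts either a LatticeField or a precomputed (possibly
    time-averaged) centerline profile of the streamwise velocity."""
    cx, cy = center
    if isinstance(field_or_profile, np.ndarray):
        u_line = field_or_profile
    else:
        field = field_or_profile
        y0 = int(np.floor(cy))
        frac = cy - y0
        u_line = (1 - frac) * field.ux[y0, :] + frac * field.ux[y0 + 1, :]
    start = int(np.ceil(cx + 0.5 * D))
    seg = u_line[start:]
    neg = np.where(seg < 0)[0]
    if len(neg) == 0:
        return 0.0
    j = neg[-1]
    if j + 1 >= len(seg):
        return float((len(seg) - 1 + start - (cx + 0.5 * D)) / D)
    # linear interpolation of the sign change
    x_cross = j + seg[j] / (seg[j] - seg[j + 1])
    return float((start + x_cross - (cx + 0.5 * D)) / D)


def _cylinder_domain(cfg: CylinderBenchmarkConfig):
    s = cfg.resolution_scale
    nx = int(round(cfg.L * s))
    ny = int(round(cfg.H * s))
    mask = np.full((ny, nx), FLUID, dtype=np.uint8)
    if cfg.lateral == "slip":
        mask[0, :] = SLIP
        mask[-1, :] = SLIP
    spec = LatticeSpec(tau=cfg.tau)
    # start in the uniform free stream: an impulsive equilibrium start
    # barely excites the slow acoustic modes of the open domain, unlike
    # ramping the whole column from rest
    u0 = np.zeros((ny, nx, 2))
    u0[..., 0] = cfg.U_inf
    fld = LatticeField(spec=spec, mask=mask, u=u0)
    ys = np.arange(1, ny - 1)
    u_in = np.zeros((len(ys), 2))
    u_in[:, 0] = cfg.U_inf
    vkind = "velocity_eq" if cfg.inlet_scheme == "eq" else "velocity"
    fld.ports = [
        PortGroup(name="inflow", y=ys, x=np.zeros(len(ys), int),
                  normal=(0, 1), kind=vkind, u_target=u_in),
        PortGroup(name="outflow", y=ys, x=np.full(len(ys), nx - 1),
                  normal=(0, -1), kind="pressure",
                  rho_target=np.ones(len(ys))),
    ]
    if cfg.lateral in ("freestream", "open"):
        xs = np.arange(1, nx - 1)
        for name, row, nrm in (("bottom", 0, (1, 0)),
                               ("top", ny - 1, (-1, 0))):
            if cfg.lateral == "freestream":
                u_lat = np.zeros((len(xs), 2))
                u_lat[:, 0] = cfg.U_inf
                grp = PortGroup(name=name, y=np.full(len(xs), row, int),
                                x=xs, normal=nrm, kind=vkind,
                                u_target=u_lat)
            else:
                grp = PortGroup(name=name, y=np.full(len(xs), row, int),
                                x=xs, normal=nrm, kind="pressure",
                                rho_target=np.ones(len(xs)))
            fld.ports.append(grp)
    elif cfg.lateral != "slip":
        raise ConfigurationError(f"unknown lateral boundary {cfg.lateral!r}")
    return fld


def run_cylinder_benchmark(cfg: CylinderBenchmarkConfig,
                           progress=None) -> DiagnosticsSeries:
    """Run the benchmark to a steady state (Re ~ 40) or through at least
    ten shedding periods after the periodic regime is established
    (Re ~ 100)."""
    s = cfg.resolution_scale
    fld = _cylinder_domain(cfg)
    center = (cfg.center[0] * s, cfg.center[1] * s)
    R = 0.5 * cfg.D * s - cfg.retraction
    X, ds = ib.circle_points(center, R, cfg.spacing * s)
    pts = ib.LagrangianSet(X=X, ds=ds, role="rigid")
    sim = Simulator(field=fld, ramp_steps=0)
    body = sim.add_rigid(pts, alpha1=cfg.alpha1, alpha2=cfg.alpha2)

    # temporary inflow tilt to break symmetry and trigger shedding
    base = next(b for p, b in sim._base_u_targets if p.name == "inflow")
    t0, t1 = cfg.perturb_window
    periodic_regime = cfg.Re >= 60
    period_est = int(round(cfg.D * s / (0.16 * cfg.U_inf)))
    chunk = max(500, period_est)
    amp_hist = []
    norm = 0.5 * cfg.U_inf ** 2 * cfg.D * s
    steady_at = None
    while fld.time_step < cfg.max_steps:
        lo = fld.time_step
        sim.run(chunk, record_forces=True)
        if periodic_regime:
            t = fld.time_step
            tilt = cfg.perturb_eps if t0 <= t < t1 else 0.0
            base[:, 1] = tilt * cfg.U_inf
        f = np.asarray(body.force_history[lo:], dtype=float)
        cl = -f[:, 1] / norm
        cd = -f[:, 0] / norm
        if progress:
            progress(fld.time_step, float(np.mean(cd)),
                     0.5 * (cl.max() - cl.min()))
        if periodic_regime:
            amp_hist.append(0.5 * (cl.max() - cl.min()))
            if steady_at is None and len(amp_hist) >= 5:
                last = amp_hist[-3:]
                spread = (max(last) - min(last)) / max(last)
                # trend-free: the onset overshoot decays monotonically
                # and must not leak into the measurement window
                if min(last) > 0.05 and spread < 0.02:
                    steady_at = fld.time_step
            if steady_at is not None and \
                    fld.time_step >= steady_at + 12 * period_est:
                break
        else:
            amp_hist.append(float(np.mean(cd)))
            if len(amp_hist) >= 6:
                # compare two-chunk means: single chunks still carry a
                # small acoustic ripple
                m_new = 0.5 * (amp_hist[-1] + amp_hist[-2])
                m_old = 0.5 * (amp_hist[-3] + amp_hist[-4])
                if abs(m_new - m_old) / abs(m_new) < 1.5e-3:
                    steady_at = fld.time_step
                    break
    # averaging window: smooths the residual acoustic ripple out of the
    # wake-length measurement (the centerline crossing sits where u ~ 0)
    avg_steps = 2 * chunk
    y0 = int(np.floor(center[1]))
    frac = center[1] - y0
    acc = np.zeros(fld.mask.shape[1])
    for _ in range(avg_steps):
        sim.step(record_forces=True)
        acc += (1 - frac) * fld.ux[y0, :] + frac * fld.ux[y0 + 1, :]
    acc /= avg_steps

    f = np.asarray(body.force_history, dtype=float)
    Cd, Cl = drag_lift_coefficients(f, 1.0, cfg.U_inf, cfg.D * s)
    if steady_at is None:
        import warnings

        warnings.warn("cylinder benchmark hit the step budget before "
                      "reaching its asymptotic regime", RuntimeWarning,
                      stacklevel=2)
        steady_at = max(0, fld.time_step - 10 * period_est)
    analysis_start = steady_at if periodic_regime else fld.time_step \
        - 2 * chunk - avg_steps
    series = DiagnosticsSeries(t=np.arange(len(Cd), dtype=float),
                               Cd=Cd, Cl=Cl, dt=1.0, D=cfg.D * s,
                               U_inf=cfg.U_inf,
                               analysis_start=int(analysis_start))
    series.Lw = recirculation_length(acc, center, cfg.D * s)
    series._field = fld
    series._body = body
    return series


def ib_wall_offset(tau: float = 0.62, spacing: float = 0.3,
                   alpha1: float = -0.05, alpha2: float = -2.0,
                   n_steps: int = 40000) -> float:
    """Effective no-slip offset of a feedback-held immersed boundary.

    Drives Poiseuille flow between two straight IB wall lines in a
    periodic box and locates the zeros of the fitted parabolic profile:
    the smoothed delta kernel shifts the effective wall a fraction of a
    lattice unit into the fluid.  The cylinder benchmark retracts its
    Lagrangian radius by this offset so its hydrodynamic diameter equals
    the nominal one.
    """
    from .lattice_core import LatticeSpec, make_periodic_field

    spec = LatticeSpec(tau=tau)
    ny, nx = 48, 12
    fld = make_periodic_field(ny, nx, spec)
    ya, yb = 9.5, ny - 9.5
    xs = np.arange(0, nx, spacing)

    def wall(y):
        X = np.stack([xs, np.full(len(xs), y)], axis=1)
        return ib.LagrangianSet(X=X, ds=spacing, role="rigid")

    sim = Simulator(field=fld, body_force=(1e-6, 0.0))
    sim.add_rigid(wall(ya), alpha1=alpha1, alpha2=alpha2)
    sim.add_rigid(wall(yb), alpha1=alpha1, alpha2=alpha2)
    sim.run(n_steps, guard_every=0)
    u = fld.ux[:, nx // 2]
    yy = np.arange(ny)
    sel = (yy > ya + 4) & (yy < yb - 4)
    c = np.polyfit(yy[sel], u[sel], 2)
    ylo, yhi = sorted(np.roots(c))
    return float(0.5 * ((ya - ylo) + (yhi - yb))) * -1.0


# ---------------------------------------------------------------------
# cell experiments on the sorting device

@dataclass
class CellParams:
    """Membrane stiffnesses in lattice units.

    Size-based pinched-flow sorting requires quasi-rigid cells: with a
    soft membrane every cell elongates in the pinch until its centre
    height no longer encodes its diameter.  The defaults are near the
    upper end of what the explicit coupling tolerates and keep a cell's
    aspect change small through the pinch (area drift < 0.5%)."""

    Kl: float = 5.0
    Kb: float = 0.1
    Ks: float = 2.0
    Ke: float = 0.003
    rc_um: float = 2.0
    spacing: float = 0.7


@dataclass
class BranchOutcome:
    diameter: float            # um
    beta: float
    alpha: float
    seed: int
    branch: int                # 1..4, or 0 = unresolved
    steps: int = 0
    exit_xy: tuple | None = None


def seed_cells(geometry: DeviceGeometry, n: int, diameter: float,
               rng, cell_params: CellParams = CellParams(),
               x_window=(8.0, 58.0), clearance: float = 2.0,
               max_attempts: int = 20000) -> list[Membrane]:
    """Place n non-overlapping circular cells of the given diameter (um)
    at random positions inside U-branch 2 (the lower inlet branch).

    Deterministic for a given rng state.  Raises if the region cannot
    accommodate the requested cells."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = geometry.params
    yc = p.y0 / 2.0
    hw0 = p.w0 / 2.0
    off = p.w_i / np.sqrt(2.0)
    # vertical margin: the strip walls run at 45 degrees, so a circle of
    # radius r needs sqrt(2) r of vertical clearance from each wall line
    m = (diameter / 2.0 + clearance) * np.sqrt(2.0)
    if 2 * off - 2 * m <= 0:
        raise ConfigurationError(
            f"cell diameter {diameter} does not fit U-branch 2")
    placed = []
    centers = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {n} cells of {diameter} um "
                f"without overlap (placed {len(placed)})")
        x = rng.uniform(max(x_window[0], m), x_window[1])
        ylo = x + (yc - hw0 - p.junction_x) + m       # lower wall + margin
        yhi = ylo + 2 * off - 2 * m
        y = rng.uniform(ylo, yhi)
        ok = all((x - cx) ** 2 + (y - cy) ** 2
                 >= (diameter / 2 + d0 / 2 + clearance) ** 2
                 for cx, cy, d0 in centers)
        if not ok:
            continue
        centers.append((x, y, diameter))
        c_lat = geometry.to_lattice([x, y])
        mem = Membrane.circle(c_lat, diameter * geometry.scale,
                              spacing=cell_params.spacing,
                              Kl=cell_params.Kl, Kb=cell_params.Kb,
                              Ks=cell_params.Ks, Ke=cell_params.Ke,
                              rc=cell_params.rc_um * geometry.scale,
                              cell_id=len(placed))
        mem.diameter = diameter
        placed.append(mem)
    return placed


def _device_with_flow(params, scale, alpha, beta, u_sum, tau, mode,
                      geometry=None, max_steps=60000, stat_tol=1e-5):
    from .simulation import device_simulator

    sim, geom = device_simulator(params, scale, alpha=alpha, beta=beta,
                                 tau=tau, u_sum=u_sum, mode=mode,
                                 geometry=geometry)
    if mode == "flux":
        sim.flux_beta = beta
    sim.run_to_stationary(geom, tol=stat_tol, max_steps=max_steps)
    return sim, geom


def classify_branch_outcome(trajectory, geometry: DeviceGeometry,
                            min_depth_um: float = 3.0) -> int:
    """D-branch whose entrance the centroid trajectory crosses (first
    point at depth >= min_depth_um inside a branch); 0 if it never
    does."""
    for p in np.atleast_2d(trajectory):
        b = geometry.which_branch(p, min_depth_um)
        if b:
            return b
    return 0


def run_sorting_experiment(diameters, beta, alpha=6.0,
                           params: DeviceParams = DeviceParams(),
                           resolution_scale: float = 1.0,
                           seed: int = 0,
                           cell_params: CellParams = CellParams(),
                           u_sum: float = 0.01, tau: float = 1.0,
                           mode: str = "flux",
                           max_steps: int = 250_000,
                           check_every: int = 200,
                           stat_tol: float = 1e-5,
                           snapshot_every: int | None = None,
                           prerun=None) -> list[BranchOutcome]:
    """Release one cell of each diameter (um) in U-branch 2 and record
    the D-branch through which each exits.

    The carrier flow is first converged without cells; cells are then
    inserted and advected until every cell has entered a branch (removed
    from the simulation at classification) or the step budget runs out
    (remaining cells reported as unresolved, branch 0)."""
    if prerun is not None:
        sim, geom = prerun
    else:
        sim, geom = _device_with_flow(params, resolution_scale, alpha, beta,
                                      u_sum, tau, mode, stat_tol=stat_tol)
    rng = np.random.default_rng(seed)
    cells = []
    for d in diameters:
        cells.extend(seed_cells(geom, 1, float(d), rng,
                                cell_params=cell_params))
    sim.membranes = list(cells)
    outcomes = {id(c): BranchOutcome(diameter=c.diameter, beta=beta,
                                     alpha=alpha, seed=seed, branch=0)
                for c in cells}
    trajectories = {id(c): [] for c in cells}
    start = sim.field.time_step
    while sim.membranes and sim.field.time_step - start < max_steps:
        sim.run(check_every)
        done = []
        for c in sim.membranes:
            cen = c.X.mean(axis=0)
            trajectories[id(c)].append(cen)
            b = geom.which_branch(cen)
            if b:
                o = outcomes[id(c)]
                o.branch = b
                o.steps = sim.field.time_step - start
                o.exit_xy = tuple(geom.from_lattice(cen))
                done.append(c)
        for c in done:
            sim.membranes.remove(c)
    for c in sim.membranes:   # unresolved
        outcomes[id(c)].steps = sim.field.time_step - start
        outcomes[id(c)].exit_xy = tuple(
            geom.from_lattice(c.X.mean(axis=0)))
    return [outcomes[id(c)] for c in cells]


def run_alpha_sweep(alphas, n_cells: int = 5, diameter: float = 8.0,
                    params: DeviceParams = DeviceParams(),
                    resolution_scale: float = 1.0, seed: int = 0,
                    cell_params: CellParams = CellParams(),
                    u_sum: float = 0.01, tau: float = 1.0,
                    beta: float = 0.25, mode: str = "flux",
                    x_window=(25.0, 55.0),
                    max_steps: int = 250_000,
                    check_every: int = 200,
                    stat_tol: float = 1e-5) -> dict:
    """For each inlet flow ratio alpha, release cells in U-branch 2 and
    record each cell centre's transverse position (um above the lower
    sidewall) as it leaves the pinched segment.

    Returns {alpha: list of exit heights}."""
    results = {}
    p = params
    # record just inside the pinched segment: at the buffer junction
    # itself the fan already deflects trajectories
    x_exit_um = p.junction_x + p.pinch_length - 2.0
    y_wall = p.y0 / 2.0 - p.w0 / 2.0
    for alpha in alphas:
        sim, geom = _device_with_flow(params, resolution_scale, alpha, beta,
                                      u_sum, tau, mode, stat_tol=stat_tol)
        rng = np.random.default_rng(seed)
        cells = seed_cells(geom, n_cells, diameter, rng,
                           cell_params=cell_params, x_window=x_window)
        sim.membranes = list(cells)
        heights = {}
        start = sim.field.time_step
        while sim.membranes and sim.field.time_step - start < max_steps:
            sim.run(check_every)
            done = []
            for c in sim.membranes:
                cen_um = geom.from_lattice(c.X.mean(axis=0))
                if cen_um[0] >= x_exit_um:
                    heights[c.cell_id] = float(cen_um[1] - y_wall)
                    done.append(c)
            for c in done:
                sim.membranes.remove(c)
        results[float(alpha)] = [heights[k] for k in sorted(heights)]
    return results
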