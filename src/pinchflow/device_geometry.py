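"""AsPFF sorting-device geometry.

The channel network consists of two upstream branches (U-branches) of
width 70.71 um meeting at 45 degrees, a pinched transitional segment of
width w0 = 30 um and length 2 w0, a circular buffer, and four downstream
branches (D-branches) of width 26 um whose entrances sit on the buffer
circle.  D-branches 1 and 4 (mirror pair about the centerline) run
straight to the bottom/top domain edges; D-branches 2 and 3 run to the
right edge and carry a narrowed 23 um "folded" segment whose length is
the free parameter used to equalize the four branch resistances (equal
outlet pressures then split the flow evenly, beta = 1/4).

All published device dimensions are in micrometres; the lattice maps
1 node to 1/scale um with node centres at (i + 0.5)/scale um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _kernels as K
from .cell_mechanics import WallSet
from .lattice_core import ConfigurationError, LatticeField, LatticeSpec, PortGroup


@dataclass(frozen=True)
class DeviceParams:
    """Channel dimensions in micrometres (defaults are the published
    device) plus layout angles of the D-branch fan, which the published
    schematic leaves undimensioned."""

    x0: float = 458.0            # overall device length
    y0: float = 400.0            # overall device width
    w_i: float = 70.71           # U-branch (inlet) width, 50 * sqrt(2)
    w0: float = 30.0             # pinched-segment width
    pinch_length: float = 60.0   # transitional channel length, 2 * w0
    w_b: float = 26.0            # D-branch width (straight/unfolded)
    w_e: float = 23.0            # folded-part width of D-branches 2, 3
    # the published schematic does not dimension the buffer: a compact
    # buffer keeps the outlet fan short, so cells commit to a branch
    # before drifting across the dividing streamlines
    buffer_radius: float = 50.0
    junction_x: float = 147.0    # x where the U-branches meet the pinch
    branch_angle_outer: float = 60.0  # D-branches 1/4, degrees off axis
    branch_angle_inner: float = 20.0  # D-branches 2/3
    folded_offset: float = 8.0   # axial start of the narrowed segment
    folded_length: float | None = None  # None -> calibration cache

    def __post_init__(self):
        for name in ("x0", "y0", "w_i", "w0", "pinch_length", "w_b", "w_e",
                     "buffer_radius"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class FluxReport:
    """Stationary port fluxes (lattice units, per step).

    Q_* are mass fluxes (the exactly conserved bookkeeping unit of the
    solver); Qv_in* are the volumetric inlet fluxes used for the alpha
    audit, since alpha = Q_in1 : Q_in2 is a volumetric flow-rate ratio
    and the weak compressibility makes the two inlets run at slightly
    different densities."""

    Q_in1: float
    Q_in2: float
    Q_out: tuple            # (Q_out1..Q_out4), positive out of the device
    Qv_in1: float | None = None
    Qv_in2: float | None = None

    @property
    def alpha(self):
        if self.Qv_in1 is not None:
            return self.Qv_in1 / self.Qv_in2
        return self.Q_in1 / self.Q_in2

    @property
    def beta(self):
        return self.Q_out[3] / sum(self.Q_out)

    @property
    def imbalance(self):
        """Relative mass defect |sum in - sum out| / sum in."""
        qin = self.Q_in1 + self.Q_in2
        return abs(qin - sum(self.Q_out)) / qin


@dataclass
class DeviceGeometry:
    params: DeviceParams
    scale: float
    mask: np.ndarray                      # (ny, nx) mask codes
    walls: WallSet                        # lattice coordinates
    port_nodes: dict                      # name -> (y_idx, x_idx, normal)
    buffer_center: np.ndarray             # um
    branch_axes: dict                     # branch -> (origin um, unit dir)
    folded_length: float

    @property
    def shape(self):
        return self.mask.shape

    # -- coordinate maps ------------------------------------------------
    def to_lattice(self, p_um):
        return np.asarray(p_um, float) * self.scale - 0.5

    def from_lattice(self, p_lat):
        return (np.asarray(p_lat, float) + 0.5) / self.scale

    def which_branch(self, p_lat, min_depth_um: float = 3.0) -> int:
        """D-branch index (1..4) whose channel contains the lattice-frame
        point at axial depth >= min_depth_um past the buffer circle, else
        0."""
        p = self.from_lattice(p_lat)
        for k, (origin, d, halfw) in self.branch_axes.items():
            rel = p - origin
            s = rel @ d
            t = abs(rel @ np.array([-d[1], d[0]]))
            if s >= min_depth_um and t <= halfw:
                return k
        return 0


# ---------------------------------------------------------------------
# construction

def _region_test(params: DeviceParams, X, Y, folded_length):
    """Vectorized fluid-region membership test in um coordinates."""
    p = params
    yc = p.y0 / 2.0
    hw0 = p.w0 / 2.0
    # vertical offset between the two wall lines of a 45-degree branch
    off = p.w_i / np.sqrt(2.0)
    xj = p.junction_x
    # outer walls run at slopes +-1 through the pinch corners
    low_outer = X + (yc - hw0 - xj)
    up_outer = -X + (yc + hw0 + xj)
    # wedge tip: intersection of the two inner U-branch walls
    x_wedge = xj + hw0 - 2.0 * off
    fluid = np.zeros(X.shape, dtype=bool)
    # U-branch strips for x <= x_wedge
    lower_strip = (Y >= low_outer) & (Y <= low_outer + 2 * off)
    upper_strip = (Y <= up_outer) & (Y >= up_outer - 2 * off)
    fluid |= (X <= x_wedge) & (X >= 0) & (lower_strip | upper_strip)
    # converging section
    fluid |= (X > x_wedge) & (X <= xj) & (Y >= low_outer) & (Y <= up_outer)
    # pinched segment up to the buffer centre
    cx = buffer_center_x(params)
    fluid |= (X > xj) & (X <= cx) & (np.abs(Y - yc) <= hw0)
    # buffer
    fluid |= (X - cx) ** 2 + (Y - yc) ** 2 <= p.buffer_radius ** 2
    # D-branches
    for k, (origin, d, hw) in branch_axes(params).items():
        rel_x = X - origin[0]
        rel_y = Y - origin[1]
        s = rel_x * d[0] + rel_y * d[1]
        t = np.abs(-rel_x * d[1] + rel_y * d[0])
        hw_arr = np.full(X.shape, hw)
        if k in (2, 3):
            narrow = (s >= p.folded_offset) & (s <= p.folded_offset
                                               + folded_length)
            hw_arr[narrow] = p.w_e / 2.0
        fluid |= (s >= 0) & (t <= hw_arr)
    # clip to the bounding box
    fluid &= (X >= 0) & (X <= p.x0) & (Y >= 0) & (Y <= p.y0)
    return fluid


def buffer_center_x(p: DeviceParams) -> float:
    return (p.junction_x + p.pinch_length
            + np.sqrt(p.buffer_radius ** 2 - (p.w0 / 2.0) ** 2))


def branch_axes(p: DeviceParams) -> dict:
    """Branch index -> (origin on the buffer circle (um), unit direction,
    nominal halfwidth).  Branch 1 is adjacent to the lower pinch sidewall
    (smallest cells), branch 4 is the regulatable one at the top."""
    yc = p.y0 / 2.0
    cx = buffer_center_x(p)
    C = np.array([cx, yc])
    out = {}
    for k, ang in ((1, -p.branch_angle_outer), (2, -p.branch_angle_inner),
                   (3, p.branch_angle_inner), (4, p.branch_angle_outer)):
        th = np.deg2rad(ang)
        d = np.array([np.cos(th), np.sin(th)])
        out[k] = (C + p.buffer_radius * d, d, p.w_b / 2.0)
    return out


def _wall_segments(params: DeviceParams, folded_length: float) -> np.ndarray:
    """Explicit wall polyline segments (um) for the membrane-wall
    repulsion query."""
    p = params
    yc = p.y0 / 2.0
    hw0 = p.w0 / 2.0
    off = p.w_i / np.sqrt(2.0)
    xj = p.junction_x
    x_wedge = xj + hw0 - 2.0 * off
    cx = buffer_center_x(p)
    x_pb = cx - np.sqrt(p.buffer_radius ** 2 - hw0 ** 2)
    segs = []
    # outer converging walls (full straight runs, inlet to pinch corner)
    segs.append(((0.0, yc - hw0 - xj), (xj, yc - hw0)))
    segs.append(((0.0, yc + hw0 + xj), (xj, yc + hw0)))
    # wedge walls (inner U-branch walls meeting at the tip)
    segs.append(((0.0, yc - hw0 - xj + 2 * off), (x_wedge, yc)))
    segs.append(((0.0, yc + hw0 + xj - 2 * off), (x_wedge, yc)))
    # pinch walls
    segs.append(((xj, yc - hw0), (x_pb, yc - hw0)))
    segs.append(((xj, yc + hw0), (x_pb, yc + hw0)))
    # buffer arcs between channel mouths (angles in [0, 360))
    half_p = np.rad2deg(np.arcsin(hw0 / p.buffer_radius))
    half_b = np.rad2deg(np.arcsin((p.w_b / 2.0) / p.buffer_radius))
    mouths = [(180.0 - half_p, 180.0 + half_p)]
    for ang in (-p.branch_angle_outer, -p.branch_angle_inner,
                p.branch_angle_inner, p.branch_angle_outer):
        mouths.append(((ang - half_b) % 360.0, (ang - half_b) % 360.0
                       + 2 * half_b))
    mouths.sort()
    C = np.array([cx, yc])

    def arc(a0, a1):
        n = max(2, int(np.ceil((a1 - a0) / 2.0)))
        th = np.deg2rad(np.linspace(a0, a1, n + 1))
        pts = C + p.buffer_radius * np.stack(
            [np.cos(th), np.sin(th)], axis=1)
        for i in range(n):
            segs.append((tuple(pts[i]), tuple(pts[i + 1])))

    for i, (a0, a1) in enumerate(mouths):
        b0 = mouths[(i + 1) % len(mouths)][0]
        if i == len(mouths) - 1:
            b0 += 360.0
        if b0 > a1:
            arc(a1, b0)
    # branch walls
    axes = branch_axes(p)
    for k, (origin, d, hw) in axes.items():
        # clip the walls where the branch axis leaves the device box
        ts = [((p.x0 - origin[0]) / d[0]) if d[0] > 0 else np.inf,
              ((p.y0 - origin[1]) / d[1]) if d[1] > 0 else np.inf,
              ((0.0 - origin[1]) / d[1]) if d[1] < 0 else np.inf]
        L_max = min(t for t in ts if t > 0) + 2.0 * hw
        n = np.array([-d[1], d[0]])
        if k in (2, 3):
            s_pts = [0.0, p.folded_offset, p.folded_offset + folded_length,
                     L_max]
            h_pts = [hw, p.w_e / 2.0, hw]
        else:
            s_pts = [0.0, L_max]
            h_pts = [hw]
        for sgn in (1.0, -1.0):
            prev = origin + sgn * hw * n
            for j in range(len(h_pts)):
                a = origin + s_pts[j] * d + sgn * h_pts[j] * n
                b = origin + s_pts[j + 1] * d + sgn * h_pts[j] * n
                if j > 0:
                    segs.append((tuple(prev), tuple(a)))  # step wall
                segs.append((tuple(a), tuple(b)))
                prev = b
    segs = np.array(segs)
    # orient every segment with the fluid on its left (the membrane-wall
    # repulsion pushes along the left normal); probe a point offset from
    # the midpoint and flip segments whose probe lands in solid
    mids = 0.5 * (segs[:, 0] + segs[:, 1])
    d = segs[:, 1] - segs[:, 0]
    n = np.stack([-d[:, 1], d[:, 0]], axis=1)
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    probe = mids + 0.5 * n
    ok = _region_test(params, probe[:, 0], probe[:, 1], folded_length)
    segs[~ok] = segs[~ok][:, ::-1]
    return segs


DEFAULT_FOLDED_LENGTH = 15.0
_CAL_FILE = "device_calibration.json"


def _calibration_key(p: DeviceParams) -> str:
    core = (p.x0, p.y0, p.w_i, p.w0, p.pinch_length, p.w_b, p.w_e,
            p.buffer_radius, p.junction_x, p.branch_angle_outer,
            p.branch_angle_inner, p.folded_offset)
    return ",".join(f"{v:g}" for v in core)


def load_calibration() -> dict:
    try:
        text = (resources.files("pinchflow") / "data" / _CAL_FILE).read_text()
        return json.loads(text)
    except (FileNotFoundError, ModuleNotFoundError):
        return {}


def calibrated_folded_length(p: DeviceParams) -> float:
    cal = load_calibration().get(_calibration_key(p))
    if cal:
        return float(cal["folded_length"])
    return DEFAULT_FOLDED_LENGTH


def calibrated_beta_slope(p: DeviceParams) -> float | None:
    """d(beta)/d(rho4 offset) from the calibration cache, if present."""
    cal = load_calibration().get(_calibration_key(p))
    if cal and "beta_slope" in cal:
        return float(cal["beta_slope"])
    return None


def build_device(params: DeviceParams = DeviceParams(),
                 resolution_scale: float = 1.0) -> DeviceGeometry:
    """Rasterize the device at 1/resolution_scale um per node and label
    the six ports.  Raises if the rasterized fluid region is not simply
    connected between all ports."""
    if resolution_scale < 0.5:
        raise ConfigurationError("resolution_scale must be >= 0.5")
    p = params
    folded = (p.folded_length if p.folded_length is not None
              else calibrated_folded_length(p))
    s = resolution_scale
    nx = int(round(p.x0 * s))
    ny = int(round(p.y0 * s))
    ix = (np.arange(nx) + 0.5) / s
    iy = (np.arange(ny) + 0.5) / s
    X, Y = np.meshgrid(ix, iy)
    fluid = _region_test(p, X, Y, folded)
    # connectivity check
    lab, nlab = ndimage.label(fluid)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, nlab + 1))
        keep = 1 + int(np.argmax(sizes))
        if np.any((lab > 0) & (lab != keep) & fluid):
            # small spurious islands are dropped; a split main region is
            # a construction error
            if sorted(sizes)[-2] > 0.01 * sizes.max():
                raise ConfigurationError(
                    "device fluid region is disconnected")
            fluid &= lab == keep
    mask = np.where(fluid, K.FLUID, K.SOLID).astype(np.uint8)

    # port labelling on the domain border
    yc_l = p.y0 / 2.0 * s
    port_nodes = {}

    def register(name, ys, xs, normal):
        if len(ys) == 0:
            raise ConfigurationError(f"port {name} has no fluid nodes")
        order = np.argsort(ys if normal[1] != 0 else xs)
        port_nodes[name] = (ys[order].astype(np.int64),
                            xs[order].astype(np.int64), normal)

    ys = np.where(fluid[:, 0])[0]
    register("in1", ys[ys >= yc_l], np.zeros(np.sum(ys >= yc_l), int),
             (0, 1))
    register("in2", ys[ys < yc_l], np.zeros(np.sum(ys < yc_l), int),
             (0, 1))
    xs = np.where(fluid[0, :])[0]
    register("out1", np.zeros(len(xs), int), xs, (1, 0))
    xs = np.where(fluid[-1, :])[0]
    register("out4", np.full(len(xs), ny - 1, int), xs, (-1, 0))
    ys = np.where(fluid[:, -1])[0]
    register("out2", ys[ys < yc_l], np.full(np.sum(ys < yc_l), nx - 1, int),
             (0, -1))
    register("out3", ys[ys >= yc_l], np.full(np.sum(ys >= yc_l), nx - 1, int),
             (0, -1))

    segs_um = _wall_segments(p, folded)
    segs_lat = segs_um * s - 0.5
    axes = {k: (o, d, hw) for k, (o, d, hw) in branch_axes(p).items()}
    return DeviceGeometry(params=p, scale=s, mask=mask,
                          walls=WallSet(segs_lat),
                          port_nodes=port_nodes,
                          buffer_center=np.array(
                              [buffer_center_x(p), p.y0 / 2.0]),
                          branch_axes=axes, folded_length=folded)


# ---------------------------------------------------------------------
# flow control and measurement

# populations with a positive component along (dy, dx)
_INTO = {(0, 1): (1, 5, 8), (0, -1): (3, 6, 7),
         (1, 0): (2, 5, 6), (-1, 0): (4, 7, 8)}


def _post_collision(field, yy, xx, i):
    """Post-collision population i at the given nodes, rebuilt from the
    current (post-stream) state: what actually streams next step."""
    g = field.g
    spec = field.spec
    rho = np.zeros(len(yy))
    mx = np.zeros(len(yy))
    my = np.zeros(len(yy))
    for j in range(9):
        gj = g[j][yy, xx]
        rho += gj
        mx += K.EX[j] * gj
        my += K.EY[j] * gj
    c = spec.c
    dt = spec.dt
    fx = field.fx[yy, xx]
    fy = field.fy[yy, xx]
    u = (mx * c + 0.5 * fx * dt) / rho
    v = (my * c + 0.5 * fy * dt) / rho
    cs2 = spec.c_s ** 2
    ex = K.EX[i] * c
    ey = K.EY[i] * c
    eu = (ex * u + ey * v) / cs2
    usq = (u * u + v * v) / cs2
    feq = K.W[i] * rho * (1.0 + eu + 0.5 * eu ** 2 - 0.5 * usq)
    G = K.W[i] * (((ex - u) / cs2 + eu * ex / cs2) * fx
                  + ((ey - v) / cs2 + eu * ey / cs2) * fy)
    om = 1.0 / spec.tau
    return (1 - om) * g[i][yy, xx] + om * feq \
        + (1.0 - 0.5 / spec.tau) * dt * G


def link_mass_flux(field, ys, xs, nrm) -> float:
    """Exact mass flux (along +nrm, per step) through the link plane
    between the given boundary nodes and their interior neighbours.

    Each streaming link (a -> b = a + e_i) crossing the plane is
    counted once as the difference of the *post-collision* populations
    that will stream across it, g*_i(a) - g*_opp(i)(b); links whose far
    endpoint is a solid node bounce back at the halfway plane and
    transfer no mass, so they are skipped.  At stationarity this closes
    over the whole boundary to round-off."""
    mask = field.mask
    ny, nx = mask.shape
    net = 0.0
    for i in _INTO[nrm]:
        ty = np.clip(ys + K.EY[i], 0, ny - 1)
        tx = np.clip(xs + K.EX[i], 0, nx - 1)
        open_link = (mask[ty, tx] != K.SOLID) & \
            (ys + K.EY[i] >= 0) & (ys + K.EY[i] < ny) & \
            (xs + K.EX[i] >= 0) & (xs + K.EX[i] < nx)
        fwd = _post_collision(field, ys, xs, i)
        rev = _post_collision(field, ty, tx, K.OPP[i])
        net += float(np.sum((fwd - rev)[open_link]))
    return net


def _parabola(n):
    """Unit-mean parabolic profile over n nodes, zero at the walls half a
    node beyond the first/last node."""
    xi = (np.arange(n) + 0.5) / n
    prof = 6.0 * xi * (1.0 - xi)
    return prof / prof.mean()


def apply_port_conditions(field: LatticeField, geometry: DeviceGeometry,
                          alpha: float, beta: float,
                          u_sum: float = 0.01, mode: str = "pressure",
                          rho4_offset: float | None = None) -> LatticeField:
    """Configure the six ports for inlet flow ratio alpha = Q_in1:Q_in2
    and outlet-4 flux fraction beta.

    mode "pressure": outlets 1-3 held at reference density, outlet 4 at a
    density offset realizing beta (taken from the calibration cache's
    linear response unless rho4_offset is given).  mode "flux": outlets
    1-3 are velocity ports imposing the (1-beta)/3 split directly and
    outlet 4 a pressure port absorbing the remainder.

    u_sum is the sum of the two inlet mean speeds (lattice units); it
    sets the overall flow rate and is chosen to keep the peak pinch
    velocity well below the speed of sound.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    if not 0 < beta < 1:
        raise ConfigurationError("beta must lie in (0, 1)")
    for name in ("in1", "in2", "out1", "out2", "out3", "out4"):
        if name not in geometry.port_nodes:
            raise ConfigurationError(f"unlabeled port {name}")
    ports = []
    U1 = u_sum * alpha / (1.0 + alpha)
    U2 = u_sum / (1.0 + alpha)
    n1 = len(geometry.port_nodes["in1"][0])
    n2 = len(geometry.port_nodes["in2"][0])
    qtot = U1 * n1 + U2 * n2
    for name, U in (("in1", U1), ("in2", U2)):
        ys, xs, nrm = geometry.port_nodes[name]
        prof = _parabola(len(ys))
        ut = np.zeros((len(ys), 2))
        ut[:, 0] = U * prof * nrm[1]
        ut[:, 1] = U * prof * nrm[0]
        ports.append(PortGroup(name=name, y=ys, x=xs, normal=nrm,
                               kind="velocity", u_target=ut))
    if mode == "flux":
        for name in ("out1", "out2", "out3"):
            ys, xs, nrm = geometry.port_nodes[name]
            n = len(ys)
            U = (1.0 - beta) / 3.0 * qtot / n
            prof = _parabola(n)
            ut = np.zeros((n, 2))
            ut[:, 0] = -U * prof * nrm[1]   # outflow: against inward normal
            ut[:, 1] = -U * prof * nrm[0]
            ports.append(PortGroup(name=name, y=ys, x=xs, normal=nrm,
                                   kind="velocity", u_target=ut))
        ys, xs, nrm = geometry.port_nodes["out4"]
        ports.append(PortGroup(name="out4", y=ys, x=xs, normal=nrm,
                               kind="pressure",
                               rho_target=np.ones(len(ys))))
    elif mode == "pressure":
        if rho4_offset is None:
            slope = calibrated_beta_slope(geometry.params)
            if slope is None:
                raise ConfigurationError(
                    "pressure mode needs a calibrated beta slope or an "
                    "explicit rho4_offset")
            rho4_offset = (beta - 0.25) / slope
        for name in ("out1", "out2", "out3", "out4"):
            ys, xs, nrm = geometry.port_nodes[name]
            rt = np.ones(len(ys))
            if name == "out4":
                rt += rho4_offset
            ports.append(PortGroup(name=name, y=ys, x=xs, normal=nrm,
                                   kind="pressure", rho_target=rt))
    else:
        raise ConfigurationError(f"unknown port mode {mode!r}")
    field.ports = ports
    return field


def measure_fluxes(field: LatticeField, geometry: DeviceGeometry,
                   warn_residual: float | None = None) -> FluxReport:
    """Exact mass flux through each port, from the populations crossing
    the link plane between the port nodes and the first interior nodes
    (the quantity the solver conserves; volumetric flux differs between
    ports by the O(Ma^2) density variation driving the flow).  Inflows
    and outflows are reported positive, in units of reference density x
    node area per step."""
    q = {}
    for name, (ys, xs, nrm) in geometry.port_nodes.items():
        net = link_mass_flux(field, ys, xs, nrm)
        sign = 1.0 if name.startswith("in") else -1.0
        q[name] = sign * net
    qv = {}
    for name in ("in1", "in2"):
        ys, xs, nrm = geometry.port_nodes[name]
        qv[name] = float(np.sum(field.ux[ys, xs] * nrm[1]
                                + field.uy[ys, xs] * nrm[0]))
    return FluxReport(Q_in1=q["in1"], Q_in2=q["in2"],
                      Q_out=(q["out1"], q["out2"], q["out3"], q["out4"]),
                      Qv_in1=qv["in1"], Qv_in2=qv["in2"])


def equalize_resistance(params: DeviceParams = DeviceParams(),
                        resolution_scale: float = 0.5,
                        solver=None, tol: float = 0.02,
                        max_iter: int = 8) -> float:
    """Calibrate the folded-part length of D-branches 2 and 3 so that
    with all outlets at equal pressure the four outlet fluxes agree
    within ``tol`` (relative).  Returns the folded length in um.

    ``solver`` maps (DeviceParams, resolution_scale) to a FluxReport at
    stationarity; the default runs the lattice solver in pressure mode
    with equal outlet densities.
    """
    if solver is None:
        from .simulation import stationary_flux_report

        def solver(pp, sc):
            return stationary_flux_report(pp, sc, alpha=1.0,
                                          mode="pressure", rho4_offset=0.0)

    def imbalance(Lf):
        rep = solver(replace(params, folded_length=Lf), resolution_scale)
        q14 = 0.5 * (rep.Q_out[0] + rep.Q_out[3])
        q23 = 0.5 * (rep.Q_out[1] + rep.Q_out[2])
        spread = (max(rep.Q_out) - min(rep.Q_out)) / np.mean(rep.Q_out)
        return q23 / q14 - 1.0, spread

    # secant iteration on the pair imbalance, monotone in Lf
    L0 = params.folded_length or DEFAULT_FOLDED_LENGTH
    f0, spread0 = imbalance(L0)
    if spread0 < tol:
        return L0
    L1 = L0 * (1.3 if f0 > 0 else 0.7)   # longer fold -> more resistance
    f1, spread1 = imbalance(L1)
    best = (spread1, L1) if spread1 < spread0 else (spread0, L0)
    for _ in range(max_iter):
        if best[0] < tol:
            break
        if f1 == f0:
            raise ConfigurationError("resistance calibration stalled")
        L2 = L1 - f1 * (L1 - L0) / (f1 - f0)
        L2 = float(np.clip(L2, 0.0, 0.9 * params.x0))
        f2, spread2 = imbalance(L2)
        if spread2 < best[0]:
            best = (spread2, L2)
        L0, f0, L1, f1 = L1, f1, L2, f2
    if best[0] >= tol:
        raise ConfigurationError(
            f"resistance calibration did not converge (spread {best[0]:.3f})")
    return best[1]
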