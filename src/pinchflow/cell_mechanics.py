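"""Deformable-cell membrane mechanics.

A cell is a closed chain of Lagrangian points carrying four force
densities: a tensile force restoring local stretch to one, a bending
force (fourth arclength derivative), a penalty force restoring the
enclosed area to its reference value (soft incompressibility of the
cytoplasm), and a short-range membrane-wall repulsion that prevents wall
penetration.  The total force density handed to the fluid is
F = F_l - F_b + F_s + F_e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


class GeometryError(ValueError):
    pass


@dataclass
class WallSet:
    """Oriented wall polylines as an array of line segments, shape
    (m, 2, 2) ((start, end) x (x, y)), with the fluid on the *left* of
    each start->end direction, plus a vectorized nearest-point query."""

    segments: np.ndarray

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=float)
        self._a = self.segments[:, 0]              # (m, 2)
        d = self.segments[:, 1] - self.segments[:, 0]
        self._d = d
        self._len2 = np.maximum(np.sum(d * d, axis=1), 1e-300)
        # into-fluid unit normal of each segment (left of start->end)
        n = np.stack([-d[:, 1], d[:, 0]], axis=1)
        self._n = n / np.maximum(np.linalg.norm(n, axis=1,
                                                keepdims=True), 1e-300)

    def nearest(self, P):
        """For points P (n, 2) return (closest wall points (n, 2),
        unsigned distances (n,))."""
        proj, _, d = self.nearest_signed(P)
        return proj, np.abs(d)

    def nearest_signed(self, P):
        """(closest wall points, into-fluid normals, signed distances);
        the distance is negative for points on the solid side of their
        nearest segment."""
        P = np.atleast_2d(P)
        ap = P[:, None, :] - self._a[None, :, :]
        t = np.clip(np.sum(ap * self._d[None], axis=2) / self._len2,
                    0.0, 1.0)
        proj = self._a[None] + t[..., None] * self._d[None]
        d2 = np.sum((P[:, None, :] - proj) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        idx = np.arange(len(P))
        prj = proj[idx, j]
        nrm = self._n[j]
        sgn = np.sign(np.sum((P - prj) * nrm, axis=1))
        sgn[sgn == 0] = 1.0
        return prj, nrm, sgn * np.sqrt(d2[idx, j])


@dataclass(eq=False)
class Membrane:
    """Closed cell membrane: ordered counterclockwise point chain with
    reference arclength and area, plus the four stiffness coefficients.

    Stiffnesses (lattice force units): Kl tension, Kb bending, Ks area
    penalty, Ke wall repulsion with cutoff rc.
    """

    X: np.ndarray
    ds: float
    S0: float
    Kl: float = 0.1
    Kb: float = 0.01
    Ks: float = 1.0
    Ke: float = 0.01
    rc: float = 2.0
    diameter: float = 0.0       # nominal diameter, lattice units
    cell_id: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if len(self.X) < 5:
            raise GeometryError("membrane needs at least 5 points")
        if self.S0 <= 0 or self.ds <= 0:
            raise GeometryError("S0 and ds must be positive")
        if min(self.Kl, self.Kb, self.Ks, self.Ke) < 0 or self.rc <= 0:
            raise GeometryError("stiffnesses must be >= 0 and rc > 0")
        if _signed_area(self.X) < 0:     # enforce CCW orientation
            self.X = self.X[::-1].copy()

    @classmethod
    def circle(cls, center, diameter, spacing=0.7, n_min=16, **kw):
        """A circular cell of the given diameter (lattice units),
        discretized so the point spacing does not exceed one lattice
        unit (>= ~pi * diameter points)."""
        r = diameter / 2.0
        n = max(n_min, int(np.ceil(np.pi * diameter / spacing)))
        th = 2 * np.pi * np.arange(n) / n
        X = np.stack([center[0] + r * np.cos(th),
                      center[1] + r * np.sin(th)], axis=1)
        ds = 2 * np.pi * r / n
        return cls(X=X, ds=ds, S0=np.pi * r * r, diameter=diameter, **kw)

    def n_points(self):
        return len(self.X)


def _signed_area(X):
    x, y = X[:, 0], X[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def enclosed_area(m: Membrane) -> float:
    """Shoelace area of the closed chain (positive, CCW enforced)."""
    return abs(_signed_area(m.X))


def outward_normals(m: Membrane) -> np.ndarray:
    """Unit outward normals of the CCW chain (central-difference tangent
    rotated by -90 degrees)."""
    t = np.roll(m.X, -1, axis=0) - np.roll(m.X, 1, axis=0)
    n = np.stack([t[:, 1], -t[:, 0]], axis=1)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def tensile_force(m: Membrane) -> np.ndarray:
    """Per-point tension force density, the arclength derivative of
    T t with T = Kl (|dX/ds| - 1): evaluated as a difference of segment
    tensions so the closed-chain sum vanishes identically."""
    seg = np.roll(m.X, -1, axis=0) - m.X          # segment j: j -> j+1
    L = np.linalg.norm(seg, axis=1)
    if np.any(L < 1e-12):
        raise GeometryError("degenerate (zero-length) membrane segment")
    T = m.Kl * (L / m.ds - 1.0)                   # segment tensions
    tvec = seg / L[:, None]
    TT = T[:, None] * tvec
    return (TT - np.roll(TT, 1, axis=0)) / m.ds


def bending_force(m: Membrane) -> np.ndarray:
    """Kb d^4 X / ds^4 by the periodic central fourth difference.  Note
    the total-force recipe subtracts this term (F = Fl - Fb + Fs + Fe)."""
    if len(m.X) < 5:
        raise GeometryError("bending needs at least 5 points")
    X = m.X
    d4 = (np.roll(X, 2, axis=0) - 4 * np.roll(X, 1, axis=0) + 6 * X
          - 4 * np.roll(X, -1, axis=0) + np.roll(X, -2, axis=0))
    return m.Kb * d4 / m.ds**4


def area_force(m: Membrane) -> np.ndarray:
    """Area-restoring normal force density of magnitude Ks |S - S0|/S0,
    with the sign arranged to push the membrane back toward S0 (inward
    when inflated, outward when deflated)."""
    S = enclosed_area(m)
    mag = m.Ks * (m.S0 - S) / m.S0
    return mag * outward_normals(m)


def wall_repulsion(m: Membrane, walls: WallSet) -> np.ndarray:
    """Short-range wall force Ke (X - Xw)/|X - Xw|^3, cut off beyond rc.

    The force acts along the into-fluid normal of the nearest wall
    segment and the gap is clamped below at 0.1 lattice units, so a
    point that touches (or is pushed through) a wall receives a strong
    restoring push back into the fluid instead of a diverging or
    wrongly-directed one."""
    if walls is None or len(walls.segments) == 0 or m.Ke == 0.0:
        return np.zeros_like(m.X)
    _, nrm, d = walls.nearest_signed(m.X)
    F = np.zeros_like(m.X)
    act = d <= m.rc
    if np.any(act):
        dc = np.maximum(d[act], 0.1)
        F[act] = m.Ke / dc[:, None] ** 2 * nrm[act]
    return F


def total_membrane_force(m: Membrane, walls: WallSet | None = None
                         ) -> np.ndarray:
    """F = Fl - Fb + Fs + Fe per point (force per unit arclength)."""
    return (tensile_force(m) - bending_force(m) + area_force(m)
            + wall_repulsion(m, walls))


# ---------------------------------------------------------------------
# fused fast path (numba): identical math to the functions above, one
# pass per membrane; used by the coupled time stepper where the numpy
# call overhead on ~100-point chains would dominate

@njit(cache=True, fastmath=True)
def _membrane_force_kernel(X, ds, Kl, Kb, Ks, S0, F):
    n = X.shape[0]
    # shoelace area (chain is CCW by construction)
    S = 0.0
    for j in range(n):
        k = j + 1 if j + 1 < n else 0
        S += X[j, 0] * X[k, 1] - X[k, 0] * X[j, 1]
    S = abs(0.5 * S)
    amag = Ks * (S0 - S) / S0
    ids = 1.0 / ds
    ids4 = ids ** 4
    for j in range(n):
        jm2 = j - 2 if j >= 2 else j - 2 + n
        jm1 = j - 1 if j >= 1 else n - 1
        jp1 = j + 1 if j + 1 < n else 0
        jp2 = j + 2 if j + 2 < n else j + 2 - n
        # tension: difference of segment tensions
        sx = X[jp1, 0] - X[j, 0]
        sy = X[jp1, 1] - X[j, 1]
        L = np.sqrt(sx * sx + sy * sy)
        T = Kl * (L * ids - 1.0)
        fx = T * sx / L
        fy = T * sy / L
        px = X[j, 0] - X[jm1, 0]
        py = X[j, 1] - X[jm1, 1]
        Lp = np.sqrt(px * px + py * py)
        Tp = Kl * (Lp * ids - 1.0)
        fx = (fx - Tp * px / Lp) * ids
        fy = (fy - Tp * py / Lp) * ids
        # bending: periodic fourth difference (subtracted in the total)
        bx = (X[jm2, 0] - 4 * X[jm1, 0] + 6 * X[j, 0]
              - 4 * X[jp1, 0] + X[jp2, 0]) * Kb * ids4
        by = (X[jm2, 1] - 4 * X[jm1, 1] + 6 * X[j, 1]
              - 4 * X[jp1, 1] + X[jp2, 1]) * Kb * ids4
        # area restoration along the outward normal
        tx = X[jp1, 0] - X[jm1, 0]
        ty = X[jp1, 1] - X[jm1, 1]
        tn = np.sqrt(tx * tx + ty * ty)
        if tn == 0.0:
            tn = 1.0
        F[j, 0] = fx - bx + amag * ty / tn
        F[j, 1] = fy - by + amag * (-tx) / tn


@njit(cache=True, fastmath=True)
def _wall_force_kernel(X, seg_a, seg_d, seg_len2, seg_n, Ke, rc, F):
    npts = X.shape[0]
    nseg = seg_a.shape[0]
    for j in range(npts):
        best = 1e300
        bn_x = 0.0
        bn_y = 0.0
        bs = 1.0
        for s in range(nseg):
            apx = X[j, 0] - seg_a[s, 0]
            apy = X[j, 1] - seg_a[s, 1]
            t = (apx * seg_d[s, 0] + apy * seg_d[s, 1]) / seg_len2[s]
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            qx = apx - t * seg_d[s, 0]
            qy = apy - t * seg_d[s, 1]
            d2 = qx * qx + qy * qy
            if d2 < best:
                best = d2
                bn_x = seg_n[s, 0]
                bn_y = seg_n[s, 1]
                side = qx * bn_x + qy * bn_y
                bs = 1.0 if side >= 0 else -1.0
        d = bs * np.sqrt(best)
        if d <= rc:
            dc = d if d > 0.1 else 0.1
            mag = Ke / (dc * dc)
            F[j, 0] += mag * bn_x
            F[j, 1] += mag * bn_y


def total_membrane_force_fast(m: Membrane, walls: WallSet | None = None
                              ) -> np.ndarray:
    """Numba fast path of total_membrane_force (identical results)."""
    F = np.empty_like(m.X)
    _membrane_force_kernel(m.X, m.ds, m.Kl, m.Kb, m.Ks, m.S0, F)
    if walls is not None and len(walls.segments) and m.Ke > 0:
        _wall_force_kernel(m.X, walls._a, walls._d, walls._len2,
                           walls._n, m.Ke, m.rc, F)
    return F
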