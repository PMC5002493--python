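"""Numba kernels for the D2Q9 solver and the immersed-boundary transfer ops.

Layout conventions: population array ``g`` has shape (9, ny, nx), scalar
fields (ny, nx).  Direction ordering follows the usual D2Q9 convention:
rest, +x, +y, -x, -y, then the four diagonals (+x+y, -x+y, -x-y, +x-y).
All kernels are single-threaded so that runs are bit-reproducible.
"""

import numpy as np
from numba import njit

# mask codes
SOLID = 0       # halfway bounce-back wall
FLUID = 1
VPORT = 2       # velocity port (inlet): non-equilibrium extrapolation
PPORT = 3       # pressure port (outlet)
SLIP = 4        # free-slip (specular) wall row

EX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
EY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
W = np.array([4.0 / 9] + [1.0 / 9] * 4 + [1.0 / 36] * 4)
OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)
# direction with the y-component mirrored (specular reflection at a y-wall)
SPEC_Y = np.array([0, 1, 4, 3, 2, 8, 7, 6, 5], dtype=np.int64)


@njit(cache=True, fastmath=True)
def moments_kernel(g, mask, rho, mx, my):
    """First two bare moments of g on non-solid nodes (no force shift)."""
    ny, nx = mask.shape
    for y in range(ny):
        for x in range(nx):
            if mask[y, x] == SOLID:
                rho[y, x] = 1.0
                mx[y, x] = 0.0
                my[y, x] = 0.0
                continue
            r = 0.0
            px = 0.0
            py = 0.0
            for i in range(9):
                gi = g[i, y, x]
                r += gi
                px += EX[i] * gi
                py += EY[i] * gi
            rho[y, x] = r
            mx[y, x] = px
            my[y, x] = py


@njit(cache=True, fastmath=True)
def collide_kernel(g, gpost, rho, ux, uy, fx, fy, mask, tau, c, dt):
    """BGK collision with Guo forcing; also refreshes rho/ux/uy in place.

    ux/uy come out with the half-force correction (the macroscopic
    velocity), which is also the velocity used in f_eq and the forcing
    term.  ``c`` is the lattice speed h/dt.
    """
    ny, nx = mask.shape
    cs2 = c * c / 3.0
    ics2 = 1.0 / cs2
    omega = 1.0 / tau
    om1 = 1.0 - omega
    gpref = (1.0 - 0.5 / tau) * dt
    w0 = 4.0 / 9.0
    w1 = 1.0 / 9.0
    w2 = 1.0 / 36.0
    for y in range(ny):
        for x in range(nx):
            if mask[y, x] == SOLID:
                continue
            g0 = g[0, y, x]
            g1 = g[1, y, x]
            g2 = g[2, y, x]
            g3 = g[3, y, x]
            g4 = g[4, y, x]
            g5 = g[5, y, x]
            g6 = g[6, y, x]
            g7 = g[7, y, x]
            g8 = g[8, y, x]
            r = g0 + g1 + g2 + g3 + g4 + g5 + g6 + g7 + g8
            px = (g1 - g3 + g5 - g6 - g7 + g8) * c
            py = (g2 - g4 + g5 + g6 - g7 - g8) * c
            fxl = fx[y, x]
            fyl = fy[y, x]
            u = (px + 0.5 * fxl * dt) / r
            v = (py + 0.5 * fyl * dt) / r
            rho[y, x] = r
            ux[y, x] = u
            uy[y, x] = v
            usq = (u * u + v * v) * ics2
            # i = 0 (rest)
            feq = w0 * r * (1.0 - 0.5 * usq)
            G = w0 * ((-u * ics2) * fxl + (-v * ics2) * fyl)
            gpost[0, y, x] = om1 * g0 + omega * feq + gpref * G
            for (i, gi, ex, ey, wi) in ((1, g1, 1.0, 0.0, w1),
                                        (2, g2, 0.0, 1.0, w1),
                                        (3, g3, -1.0, 0.0, w1),
                                        (4, g4, 0.0, -1.0, w1),
                                        (5, g5, 1.0, 1.0, w2),
                                        (6, g6, -1.0, 1.0, w2),
                                        (7, g7, -1.0, -1.0, w2),
                                        (8, g8, 1.0, -1.0, w2)):
                exc = ex * c
                eyc = ey * c
                eu = (exc * u + eyc * v) * ics2
                feq = wi * r * (1.0 + eu + 0.5 * eu * eu - 0.5 * usq)
                G = wi * (((exc - u) * ics2 + eu * exc * ics2) * fxl +
                          ((eyc - v) * ics2 + eu * eyc * ics2) * fyl)
                gpost[i, y, x] = om1 * gi + omega * feq + gpref * G


@njit(cache=True, fastmath=True)
def stream_kernel(gpost, g, mask, easy, periodic):
    """Pull streaming with halfway bounce-back (SOLID) and specular free
    slip (SLIP).  Port nodes are streamed like fluid and later overwritten
    by the port update.  Nodes flagged in ``easy`` are handled by the
    fast-path kernel and skipped here."""
    ny, nx = mask.shape
    for y in range(ny):
        for x in range(nx):
            m = mask[y, x]
            if m == SOLID or m == SLIP or easy[y, x] == 1:
                continue
            for i in range(9):
                sy = y - EY[i]
                sx = x - EX[i]
                if periodic:
                    if sy < 0:
                        sy += ny
                    elif sy >= ny:
                        sy -= ny
                    if sx < 0:
                        sx += nx
                    elif sx >= nx:
                        sx -= nx
                    sm = mask[sy, sx]
                else:
                    if sy < 0 or sy >= ny or sx < 0 or sx >= nx:
                        sm = SOLID  # closed box fallback
                    else:
                        sm = mask[sy, sx]
                if sm == SOLID:
                    g[i, y, x] = gpost[OPP[i], y, x]
                elif sm == SLIP:
                    # specular: mirrored population from the same row,
                    # shifted only along the wall tangent
                    tx = x - EX[i]
                    if tx < 0:
                        tx = 0
                    elif tx >= nx:
                        tx = nx - 1
                    g[i, y, x] = gpost[SPEC_Y[i], y, tx]
                else:
                    g[i, y, x] = gpost[i, sy, sx]


@njit(cache=True, fastmath=True)
def stream_interior_kernel(gpost, g, easy):
    """Fast-path pull streaming for interior fluid nodes whose whole 3x3
    neighbourhood is streamable (no solid/slip source, no wrap-around)."""
    ny, nx = easy.shape
    for y in range(1, ny - 1):
        for x in range(1, nx - 1):
            if easy[y, x] != 1:
                continue
            g[0, y, x] = gpost[0, y, x]
            g[1, y, x] = gpost[1, y, x - 1]
            g[2, y, x] = gpost[2, y - 1, x]
            g[3, y, x] = gpost[3, y, x + 1]
            g[4, y, x] = gpost[4, y + 1, x]
            g[5, y, x] = gpost[5, y - 1, x - 1]
            g[6, y, x] = gpost[6, y - 1, x + 1]
            g[7, y, x] = gpost[7, y + 1, x + 1]
            g[8, y, x] = gpost[8, y + 1, x - 1]


@njit(cache=True, fastmath=True)
def port_kernel(g, mask, fx, fy, py_arr, px_arr, nby, nbx, kind,
                tux, tuy, trho, c, dt):
    """Boundary update on port nodes.

    kind 0: velocity port, non-equilibrium extrapolation (target u given,
    rho taken from the interior neighbour); kind 1: pressure port (target
    rho given, u extrapolated); kind 2: equilibrium velocity port (the
    non-equilibrium part is dropped -- a softer inlet).
    """
    cs2 = c * c / 3.0
    inv_cs2 = 1.0 / cs2
    n = py_arr.shape[0]
    for k in range(n):
        y = py_arr[k]
        x = px_arr[k]
        yn = nby[k]
        xn = nbx[k]
        # neighbour macroscopics
        r_n = 0.0
        px_n = 0.0
        py_n = 0.0
        for i in range(9):
            gi = g[i, yn, xn]
            r_n += gi
            px_n += EX[i] * gi
            py_n += EY[i] * gi
        px_n *= c
        py_n *= c
        u_n = (px_n + 0.5 * fx[yn, xn] * dt) / r_n
        v_n = (py_n + 0.5 * fy[yn, xn] * dt) / r_n
        if kind == 0 or kind == 2:
            rt = r_n
            ut = tux[k]
            vt = tuy[k]
        else:
            rt = trho[k]
            ut = u_n
            vt = v_n
        usq_t = (ut * ut + vt * vt) * inv_cs2
        usq_n = (u_n * u_n + v_n * v_n) * inv_cs2
        for i in range(9):
            ex = EX[i] * c
            ey = EY[i] * c
            eu_t = (ex * ut + ey * vt) * inv_cs2
            feq_t = W[i] * rt * (1.0 + eu_t + 0.5 * eu_t * eu_t - 0.5 * usq_t)
            if kind == 2:
                g[i, y, x] = feq_t
            else:
                eu_n = (ex * u_n + ey * v_n) * inv_cs2
                feq_n = W[i] * r_n * (1.0 + eu_n + 0.5 * eu_n * eu_n
                                      - 0.5 * usq_n)
                g[i, y, x] = feq_t + (g[i, yn, xn] - feq_n)


@njit(cache=True, fastmath=True)
def peskin_delta(r):
    """Four-point smoothed delta of Peskin (support |r| <= 2), 1D."""
    a = abs(r)
    if a <= 1.0:
        return (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a)) / 8.0
    if a <= 2.0:
        return (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a)) / 8.0
    return 0.0


@njit(cache=True, fastmath=True)
def interp_kernel(ux, uy, X, Y, out, periodic=False):
    """Interpolate a velocity field at Lagrangian points (4x4 stencil)."""
    n = X.shape[0]
    ny, nx = ux.shape
    for k in range(n):
        xp = X[k]
        yp = Y[k]
        ix0 = int(np.floor(xp)) - 1
        iy0 = int(np.floor(yp)) - 1
        su = 0.0
        sv = 0.0
        for jy in range(4):
            y = iy0 + jy
            wy = peskin_delta(y - yp)
            if wy == 0.0:
                continue
            if periodic:
                y = y % ny
            for jx in range(4):
                x = ix0 + jx
                w = wy * peskin_delta(x - xp)
                if periodic:
                    x = x % nx
                su += w * ux[y, x]
                sv += w * uy[y, x]
        out[k, 0] = su
        out[k, 1] = sv


@njit(cache=True, fastmath=True)
def spread_kernel(X, Y, FX, FY, ds, fx, fy, periodic=False):
    """Spread Lagrangian forces (per unit arclength, weight ds) onto the
    Eulerian force density arrays; accumulates in place."""
    n = X.shape[0]
    ny, nx = fx.shape
    for k in range(n):
        xp = X[k]
        yp = Y[k]
        fxk = FX[k] * ds[k]
        fyk = FY[k] * ds[k]
        ix0 = int(np.floor(xp)) - 1
        iy0 = int(np.floor(yp)) - 1
        for jy in range(4):
            y = iy0 + jy
            wy = peskin_delta(y - yp)
            if wy == 0.0:
                continue
            if periodic:
                y = y % ny
            for jx in range(4):
                x = ix0 + jx
                w = wy * peskin_delta(x - xp)
                if periodic:
                    x = x % nx
                fx[y, x] += w * fxk
                fy[y, x] += w * fyk
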