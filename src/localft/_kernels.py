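"""Numba-compiled force evaluation and trajectory integration kernels.

These kernels implement the same physics as the NumPy reference functions in
:mod:`localft.interactions` (cross-checked in the tests) but run the full
time-stepping loop in compiled code so that trajectory ensembles of order
10^3--10^4 are affordable on one CPU core.

Integration scheme (all three scenarios): velocity-Verlet splitting
kick(dt/2) - drift(dt) - kick(dt/2), where each kick applies the
non-thermostat force G_i and the Gaussian multiplier term -alpha p_i
together through a time-reversible implicit-midpoint update,

    p' = [ (1 - a) p + h G ] / (1 + a),      a = h * alpha / 2,

with the scalar multiplier chosen in closed form so the constrained quantity
(wall kinetic energy, fluid kinetic energy, or total energy H) is exact
after every kick.  Substituting s = 1/(1+a) makes sum p'^2 a quadratic in s,
so no iteration is needed.  For the active scenario the Ornstein--Uhlenbeck
propulsion variables are advanced by their exact half-step update on either
side of the mechanical step (Strang splitting).

Error codes returned by the kernels:
    0 ok, 1 particle overlap / obstacle penetration, 2 non-finite values,
    3 constraint unsolvable, 4 particle escaped the channel in y.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Thermostat codes used by the kernels.
THERMO_WALLS_ISO = 0   # channel: isokinetic on wall atoms only
THERMO_ERGOSTAT = 1    # obstacle: total energy H held constant
THERMO_FLUID_ISO = 2   # active: isokinetic on all (fluid) particles
THERMO_NONE = 3        # plain velocity Verlet (validation runs)

_RC = 2.0 ** (1.0 / 6.0)
_RC2 = _RC * _RC


@njit(cache=True)
def forces_energy(pos, charge, wall, anchors, lx, ly, periodic_y,
                  k_spring, has_obs, ocx, ocy, obs_r, out_f):
    """Pair + tether + obstacle forces into ``out_f``; returns (U, err)."""
    n = pos.shape[0]
    for i in range(n):
        out_f[i, 0] = 0.0
        out_f[i, 1] = 0.0
    u = 0.0

    # --- WCA pairs via linked cells (direct loop for small/thin boxes) ---
    ncx = int(lx / _RC)
    ncy = int(ly / _RC)
    use_cells = ncx >= 4 and ncy >= 4 and n > 32
    if use_cells:
        cwx = lx / ncx
        cwy = ly / ncy
        head = np.full(ncx * ncy, -1, dtype=np.int64)
        nxt = np.empty(n, dtype=np.int64)
        for i in range(n):
            cx = int(pos[i, 0] / cwx)
            if cx >= ncx:
                cx = ncx - 1
            elif cx < 0:
                cx = 0
            cy = int(pos[i, 1] / cwy)
            if cy >= ncy:
                cy = ncy - 1
            elif cy < 0:
                cy = 0
            c = cx + ncx * cy
            nxt[i] = head[c]
            head[c] = i
        for cy in range(ncy):
            for cx in range(ncx):
                i = head[cx + ncx * cy]
                while i >= 0:
                    for oy in range(-1, 2):
                        ncell_y = cy + oy
                        if periodic_y:
                            if ncell_y < 0:
                                ncell_y += ncy
                            elif ncell_y >= ncy:
                                ncell_y -= ncy
                        elif ncell_y < 0 or ncell_y >= ncy:
                            continue
                        for ox in range(-1, 2):
                            ncell_x = cx + ox
                            if ncell_x < 0:
                                ncell_x += ncx
                            elif ncell_x >= ncx:
                                ncell_x -= ncx
                            j = head[ncell_x + ncx * ncell_y]
                            while j >= 0:
                                if j > i:
                                    dx = pos[i, 0] - pos[j, 0]
                                    dx -= lx * math.floor(dx / lx + 0.5)
                                    dy = pos[i, 1] - pos[j, 1]
                                    if periodic_y:
                                        dy -= ly * math.floor(dy / ly + 0.5)
                                    r2 = dx * dx + dy * dy
                                    if r2 < _RC2:
                                        if r2 <= 0.0:
                                            return 0.0, 1
                                        inv2 = 1.0 / r2
                                        inv6 = inv2 * inv2 * inv2
                                        u += 4.0 * (inv6 * inv6 - inv6) + 1.0
                                        fr = 24.0 * (2.0 * inv6 * inv6
                                                     - inv6) * inv2
                                        out_f[i, 0] += fr * dx
                                        out_f[i, 1] += fr * dy
                                        out_f[j, 0] -= fr * dx
                                        out_f[j, 1] -= fr * dy
                                j = nxt[j]
                    i = nxt[i]
    else:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dx -= lx * math.floor(dx / lx + 0.5)
                dy = pos[i, 1] - pos[j, 1]
                if periodic_y:
                    dy -= ly * math.floor(dy / ly + 0.5)
                r2 = dx * dx + dy * dy
                if r2 < _RC2:
                    if r2 <= 0.0:
                        return 0.0, 1
                    inv2 = 1.0 / r2
                    inv6 = inv2 * inv2 * inv2
                    u += 4.0 * (inv6 * inv6 - inv6) + 1.0
                    fr = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
                    out_f[i, 0] += fr * dx
                    out_f[i, 1] += fr * dy
                    out_f[j, 0] -= fr * dx
                    out_f[j, 1] -= fr * dy

    # --- tethers (wall atoms only; minimum image along x) ---
    for i in range(n):
        if wall[i] == 1:
            ddx = pos[i, 0] - anchors[i, 0]
            ddx -= lx * math.floor(ddx / lx + 0.5)
            ddy = pos[i, 1] - anchors[i, 1]
            out_f[i, 0] -= k_spring * ddx
            out_f[i, 1] -= k_spring * ddy
            u += 0.5 * k_spring * (ddx * ddx + ddy * ddy)

    # --- static disk obstacle: WCA on the surface distance d = r - R ---
    if has_obs:
        for i in range(n):
            dx = pos[i, 0] - ocx
            dx -= lx * math.floor(dx / lx + 0.5)
            dy = pos[i, 1] - ocy
            if periodic_y:
                dy -= ly * math.floor(dy / ly + 0.5)
            r = math.sqrt(dx * dx + dy * dy)
            d = r - obs_r
            if d <= 0.0:
                return 0.0, 1
            if d < _RC:
                inv2 = 1.0 / (d * d)
                inv6 = inv2 * inv2 * inv2
                u += 4.0 * (inv6 * inv6 - inv6) + 1.0
                fmag = 24.0 * (2.0 * inv6 * inv6 - inv6) / d
                out_f[i, 0] += fmag * dx / r
                out_f[i, 1] += fmag * dy / r
    return u, 0


@njit(cache=True)
def _constrained_kick(mom, g, constrained, h, s_target):
    """Half-kick with the implicit-midpoint Gaussian multiplier.

    Unconstrained particles receive a plain kick p += h g.  Over the
    constrained subset the multiplier is solved in closed form so that
    sum p'^2 = s_target exactly.  Returns an error code.
    """
    n = mom.shape[0]
    p2 = 0.0
    pg = 0.0
    g2 = 0.0
    any_con = False
    for i in range(n):
        if constrained[i] == 1:
            any_con = True
            p2 += mom[i, 0] * mom[i, 0] + mom[i, 1] * mom[i, 1]
            pg += mom[i, 0] * g[i, 0] + mom[i, 1] * g[i, 1]
            g2 += g[i, 0] * g[i, 0] + g[i, 1] * g[i, 1]
        else:
            mom[i, 0] += h * g[i, 0]
            mom[i, 1] += h * g[i, 1]
    if not any_con:
        return 0
    if p2 <= 0.0 or s_target <= 0.0:
        return 3
    qa = 4.0 * p2 + 4.0 * h * pg + h * h * g2
    qb = -(4.0 * p2 + 2.0 * h * pg)
    qc = p2 - s_target
    disc = qb * qb - 4.0 * qa * qc
    if disc <= 0.0 or qa == 0.0:
        return 3
    s = (-qb + math.sqrt(disc)) / (2.0 * qa)
    uu = 2.0 * s - 1.0
    vv = h * s
    for i in range(n):
        if constrained[i] == 1:
            px = uu * mom[i, 0] + vv * g[i, 0]
            py = uu * mom[i, 1] + vv * g[i, 1]
            mom[i, 0] = px
            mom[i, 1] = py
    return 0


@njit(cache=True)
def _bin_index(x, y, part_mode, dx_cell, dy_cell, nx_cell, ny_cell, lx, ly):
    ix = int(x / dx_cell)
    if ix >= nx_cell:
        ix = nx_cell - 1
    elif ix < 0:
        ix = 0
    if part_mode == 0:
        return ix
    iy = int(y / dy_cell)
    if iy >= ny_cell:
        iy = ny_cell - 1
    elif iy < 0:
        iy = 0
    return ix + nx_cell * iy


@njit(cache=True)
def _accumulate_cells(pos, mom, charge, wall, xi, part_mode, dx_cell, dy_cell,
                      nx_cell, ny_cell, lx, ly, j_out, xip_out, cnt_out):
    ncells = j_out.shape[0]
    for c in range(ncells):
        j_out[c] = 0.0
        xip_out[c] = 0.0
        cnt_out[c] = 0.0
    n = pos.shape[0]
    for i in range(n):
        if wall[i] == 1:
            continue
        c = _bin_index(pos[i, 0], pos[i, 1], part_mode, dx_cell, dy_cell,
                       nx_cell, ny_cell, lx, ly)
        j_out[c] += charge[i] * mom[i, 0]
        xip_out[c] += xi[i] * mom[i, 0]
        cnt_out[c] += 1.0


@njit(cache=True)
def _gaussian_alpha(mom, forces, charge, wall, xi, f_e, thermo):
    """Diagnostic Gaussian multiplier from the analytic formulas."""
    n = mom.shape[0]
    num = 0.0
    den = 0.0
    for i in range(n):
        if thermo == THERMO_WALLS_ISO:
            if wall[i] == 1:
                num += mom[i, 0] * forces[i, 0] + mom[i, 1] * forces[i, 1]
                den += mom[i, 0] * mom[i, 0] + mom[i, 1] * mom[i, 1]
        elif thermo == THERMO_ERGOSTAT:
            num += charge[i] * f_e * mom[i, 0]
            den += mom[i, 0] * mom[i, 0] + mom[i, 1] * mom[i, 1]
        elif thermo == THERMO_FLUID_ISO:
            gx = forces[i, 0] + (charge[i] * f_e + xi[i])
            num += mom[i, 0] * gx + mom[i, 1] * forces[i, 1]
            den += mom[i, 0] * mom[i, 0] + mom[i, 1] * mom[i, 1]
    if den <= 0.0:
        return 0.0
    return num / den


@njit(cache=True)
def run_trajectory_kernel(pos, mom, charge, wall, anchors, xi,
                          lx, ly, periodic_y, thermo,
                          has_obs, ocx, ocy, obs_r,
                          f_e, k_spring, use_activity, tau, sig_noise,
                          dt, nsteps, noise,
                          part_mode, dx_cell, dy_cell, nx_cell, ny_cell,
                          sample_stride,
                          j_series, xip_series, cnt_series,
                          cons_series, alpha_series,
                          j_acc, xip_acc, cnt_acc):
    """Integrate one trajectory in place; fill series and trapezoid sums.

    ``j_series``/``xip_series``/``cnt_series`` have shape (n_rec, ncells)
    with n_rec = nsteps // sample_stride + 1; ``*_acc`` are full-resolution
    trapezoidal time integrals over [0, nsteps * dt] per cell.  ``noise`` has
    shape (nsteps, N, 2) (ignored unless ``use_activity``).
    """
    n = pos.shape[0]
    ncells = j_acc.shape[0]

    constrained = np.zeros(n, dtype=np.uint8)
    if thermo == THERMO_WALLS_ISO:
        for i in range(n):
            if wall[i] == 1:
                constrained[i] = 1
    elif thermo == THERMO_ERGOSTAT or thermo == THERMO_FLUID_ISO:
        for i in range(n):
            constrained[i] = 1

    forces = np.empty((n, 2))
    g = np.empty((n, 2))
    mom_trial = np.empty((n, 2))
    pos_trial = np.empty((n, 2))
    f_scratch = np.empty((n, 2))
    j_prev = np.empty(ncells)
    xip_prev = np.empty(ncells)
    cnt_prev = np.empty(ncells)
    j_now = np.empty(ncells)
    xip_now = np.empty(ncells)
    cnt_now = np.empty(ncells)

    u, err = forces_energy(pos, charge, wall, anchors, lx, ly, periodic_y,
                           k_spring, has_obs, ocx, ocy, obs_r, forces)
    if err != 0:
        return err

    # Constraint reference values at t = 0.
    p2_con = 0.0
    ke_tot = 0.0
    for i in range(n):
        p2 = mom[i, 0] * mom[i, 0] + mom[i, 1] * mom[i, 1]
        ke_tot += 0.5 * p2
        if constrained[i] == 1:
            p2_con += p2
    h_total0 = ke_tot + u

    e1h = math.exp(-0.5 * dt / tau)
    amp_h = sig_noise * math.sqrt(max(0.0, 1.0 - e1h * e1h))

    for c in range(ncells):
        j_acc[c] = 0.0
        xip_acc[c] = 0.0
        cnt_acc[c] = 0.0
    _accumulate_cells(pos, mom, charge, wall, xi, part_mode, dx_cell, dy_cell,
                      nx_cell, ny_cell, lx, ly, j_prev, xip_prev, cnt_prev)
    for c in range(ncells):
        j_series[0, c] = j_prev[c]
        xip_series[0, c] = xip_prev[c]
        cnt_series[0, c] = cnt_prev[c]
    if thermo == THERMO_WALLS_ISO:
        cons_series[0] = 0.5 * p2_con
    elif thermo == THERMO_FLUID_ISO:
        cons_series[0] = 0.5 * p2_con
    else:
        cons_series[0] = h_total0
    alpha_series[0] = _gaussian_alpha(mom, forces, charge, wall, xi, f_e,
                                      thermo)

    half = 0.5 * dt
    for step in range(nsteps):
        # OU half-step (exact) before the mechanical step
        if use_activity:
            for i in range(n):
                xi[i] = xi[i] * e1h + amp_h * noise[step, i, 0]

        # first half-kick
        for i in range(n):
            g[i, 0] = forces[i, 0] + charge[i] * f_e
            g[i, 1] = forces[i, 1]
            if use_activity:
                g[i, 0] += xi[i]
        if thermo == THERMO_ERGOSTAT:
            # The first half-kick targets the kinetic energy anchored at the
            # drift midpoint, K = H0 - [U(q_n) + U(q_{n+1})]/2, found by
            # fixed-point iteration; together with the second half-kick
            # targeting H0 - U(q_{n+1}) this makes the step exactly
            # time-reversible while keeping H exact at step boundaries.
            u_here = u
            s_target = 2.0 * (h_total0 - u_here)
            for _ in range(6):
                for i in range(n):
                    mom_trial[i, 0] = mom[i, 0]
                    mom_trial[i, 1] = mom[i, 1]
                err = _constrained_kick(mom_trial, g, constrained, half,
                                        s_target)
                if err != 0:
                    return err
                for i in range(n):
                    xt = pos[i, 0] + dt * mom_trial[i, 0]
                    yt = pos[i, 1] + dt * mom_trial[i, 1]
                    xt -= lx * math.floor(xt / lx)
                    if periodic_y:
                        yt -= ly * math.floor(yt / ly)
                    pos_trial[i, 0] = xt
                    pos_trial[i, 1] = yt
                u_next, err = forces_energy(pos_trial, charge, wall, anchors,
                                            lx, ly, periodic_y, k_spring,
                                            has_obs, ocx, ocy, obs_r,
                                            f_scratch)
                if err != 0:
                    return err
                t_new = 2.0 * (h_total0 - 0.5 * (u_here + u_next))
                if abs(t_new - s_target) < 1e-13 * (1.0 + abs(s_target)):
                    s_target = t_new
                    break
                s_target = t_new
        else:
            s_target = p2_con
        if thermo != THERMO_NONE:
            err = _constrained_kick(mom, g, constrained, half, s_target)
            if err != 0:
                return err
        else:
            for i in range(n):
                mom[i, 0] += half * g[i, 0]
                mom[i, 1] += half * g[i, 1]

        # drift + periodic wrap
        for i in range(n):
            x = pos[i, 0] + dt * mom[i, 0]
            y = pos[i, 1] + dt * mom[i, 1]
            x -= lx * math.floor(x / lx)
            if periodic_y:
                y -= ly * math.floor(y / ly)
            elif y < 0.0 or y >= ly:
                return 4
            if not (math.isfinite(x) and math.isfinite(y)):
                return 2
            pos[i, 0] = x
            pos[i, 1] = y

        u, err = forces_energy(pos, charge, wall, anchors, lx, ly, periodic_y,
                               k_spring, has_obs, ocx, ocy, obs_r, forces)
        if err != 0:
            return err

        # second half-kick
        for i in range(n):
            g[i, 0] = forces[i, 0] + charge[i] * f_e
            g[i, 1] = forces[i, 1]
            if use_activity:
                g[i, 0] += xi[i]
        if thermo == THERMO_ERGOSTAT:
            s_target = 2.0 * (h_total0 - u)
        else:
            s_target = p2_con
        if thermo != THERMO_NONE:
            err = _constrained_kick(mom, g, constrained, half, s_target)
            if err != 0:
                return err
        else:
            for i in range(n):
                mom[i, 0] += half * g[i, 0]
                mom[i, 1] += half * g[i, 1]

        # OU half-step after the mechanical step
        if use_activity:
            for i in range(n):
                xi[i] = xi[i] * e1h + amp_h * noise[step, i, 1]

        # trapezoidal accumulation of per-cell integrands
        _accumulate_cells(pos, mom, charge, wall, xi, part_mode, dx_cell,
                          dy_cell, nx_cell, ny_cell, lx, ly,
                          j_now, xip_now, cnt_now)
        for c in range(ncells):
            j_acc[c] += half * (j_prev[c] + j_now[c])
            xip_acc[c] += half * (xip_prev[c] + xip_now[c])
            cnt_acc[c] += half * (cnt_prev[c] + cnt_now[c])
            j_prev[c] = j_now[c]
            xip_prev[c] = xip_now[c]
            cnt_prev[c] = cnt_now[c]

        if (step + 1) % sample_stride == 0:
            rec = (step + 1) // sample_stride
            for c in range(ncells):
                j_series[rec, c] = j_now[c]
                xip_series[rec, c] = xip_now[c]
                cnt_series[rec, c] = cnt_now[c]
            if thermo == THERMO_WALLS_ISO or thermo == THERMO_FLUID_ISO:
                val = 0.0
                for i in range(n):
                    if constrained[i] == 1:
                        val += 0.5 * (mom[i, 0] * mom[i, 0]
                                      + mom[i, 1] * mom[i, 1])
                cons_series[rec] = val
            else:
                val = u
                for i in range(n):
                    val += 0.5 * (mom[i, 0] * mom[i, 0]
                                  + mom[i, 1] * mom[i, 1])
                cons_series[rec] = val
            alpha_series[rec] = _gaussian_alpha(mom, forces, charge, wall, xi,
                                                f_e, thermo)
    return 0
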