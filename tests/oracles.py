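"""Independent straightforward re-implementations used as test oracles.

Everything here is written as plain Python loops directly from the scheme
definition, deliberately ignoring the vectorized implementation, so that
agreement between the two is a meaningful check.
"""

import math

import numpy as np


def naive_step(h, u, t, dt, grid, fluid, shaker, settings):
    """One Heun step of the shallow-water update, cell-by-cell loops."""
    nr, nt = grid.n_r, grid.n_theta
    g = settings.gravity
    mu = fluid.dynamic_viscosity
    rho = fluid.density

    def lam(hval):
        if settings.closure == "lubrication":
            return 3 * mu / (rho * hval**2)
        return math.sqrt(rho * mu * shaker.omega / 2) / (rho * hval)

    def floor(hf, uf):
        hf = hf.copy()
        uf = uf.copy()
        for i in range(nr):
            for j in range(nt):
                if hf[i, j] <= settings.min_depth:
                    hf[i, j] = settings.min_depth
                    uf[i, j, :] = 0.0
        return hf, uf

    def dhdt(hc, uc):
        out = np.zeros((nr, nt))
        area = grid.cell_area
        for i in range(nr):
            for j in range(nt):
                net = 0.0
                th = grid.theta[j]
                # radial faces
                for face, sign in ((i + 1, +1), (i, -1)):
                    if face == 0 or face == nr:
                        continue
                    iL, iR = face - 1, face
                    unL = uc[iL, j, 0] * math.cos(th) + uc[iL, j, 1] * math.sin(th)
                    unR = uc[iR, j, 0] * math.cos(th) + uc[iR, j, 1] * math.sin(th)
                    hL, hR = hc[iL, j], hc[iR, j]
                    c = max(abs(unL) + math.sqrt(g * hL), abs(unR) + math.sqrt(g * hR))
                    flux = (0.5 * (hL * unL + hR * unR) - 0.5 * c * (hR - hL)) * (
                        grid.r_edges[face] * grid.dtheta
                    )
                    net += sign * flux
                # azimuthal faces: face j between j and j+1, face j-1 behind
                for face, sign in ((j, +1), ((j - 1) % nt, -1)):
                    jL, jR = face, (face + 1) % nt
                    thf = grid.theta[face] + grid.dtheta / 2
                    unL = -uc[i, jL, 0] * math.sin(thf) + uc[i, jL, 1] * math.cos(thf)
                    unR = -uc[i, jR, 0] * math.sin(thf) + uc[i, jR, 1] * math.cos(thf)
                    hL, hR = hc[i, jL], hc[i, jR]
                    c = max(abs(unL) + math.sqrt(g * hL), abs(unR) + math.sqrt(g * hR))
                    flux = (0.5 * (hL * unL + hR * unR) - 0.5 * c * (hR - hL)) * grid.dr
                    net += sign * flux
                out[i, j] = -net / area[i, j]
        return out

    def rhs(hc, uc, tc):
        out = np.zeros((nr, nt, 2))
        a = shaker.orbit_radius
        w = shaker.omega
        fx = a * w**2 * math.cos(w * tc)
        fy = a * w**2 * math.sin(w * tc)
        for i in range(nr):
            r = grid.r[i]
            for j in range(nt):
                th = grid.theta[j]
                ur = uc[i, j, 0] * math.cos(th) + uc[i, j, 1] * math.sin(th)
                ut = -uc[i, j, 0] * math.sin(th) + uc[i, j, 1] * math.cos(th)
                for comp in range(2):
                    f = uc[:, :, comp]
                    # upwind d/dr
                    if ur > 0:
                        dfr = (f[i, j] - f[i - 1, j]) / grid.dr if i > 0 else 0.0
                    else:
                        dfr = (f[i + 1, j] - f[i, j]) / grid.dr if i < nr - 1 else 0.0
                    # upwind d/dtheta (periodic)
                    if ut > 0:
                        dft = (f[i, j] - f[i, (j - 1) % nt]) / grid.dtheta
                    else:
                        dft = (f[i, (j + 1) % nt] - f[i, j]) / grid.dtheta
                    adv = ur * dfr + ut / r * dft
                    # Laplacian, Neumann walls
                    up = (f[i + 1, j] - f[i, j]) / grid.dr if i < nr - 1 else 0.0
                    dn = (f[i, j] - f[i - 1, j]) / grid.dr if i > 0 else 0.0
                    lap = (grid.r_edges[i + 1] * up - grid.r_edges[i] * dn) / (r * grid.dr)
                    lap += (
                        f[i, (j + 1) % nt] - 2 * f[i, j] + f[i, (j - 1) % nt]
                    ) / (r**2 * grid.dtheta**2)
                    out[i, j, comp] = -adv + settings.eddy_viscosity * lap
                # pressure gradient, central with one-sided walls
                if 0 < i < nr - 1:
                    hr = (hc[i + 1, j] - hc[i - 1, j]) / (2 * grid.dr)
                elif i == 0:
                    hr = (hc[1, j] - hc[0, j]) / grid.dr
                else:
                    hr = (hc[nr - 1, j] - hc[nr - 2, j]) / grid.dr
                ht = (hc[i, (j + 1) % nt] - hc[i, (j - 1) % nt]) / (2 * grid.dtheta) / r
                out[i, j, 0] += -g * (hr * math.cos(th) - ht * math.sin(th)) + fx
                out[i, j, 1] += -g * (hr * math.sin(th) + ht * math.cos(th)) + fy
        return out

    dh1 = dhdt(h, u)
    r1 = rhs(h, u, t)
    h_star = h + dt * dh1
    h_star, _ = floor(h_star, u)
    u_star = np.zeros_like(u)
    for i in range(nr):
        for j in range(nt):
            u_star[i, j] = (u[i, j] + dt * r1[i, j]) / (1 + dt * lam(h_star[i, j]))
    h_star, u_star = floor(h_star, u_star)
    dh2 = dhdt(h_star, u_star)
    r2 = rhs(h_star, u_star, t + dt)
    h_new = h + dt / 2 * (dh1 + dh2)
    h_new, _ = floor(h_new, u)
    u_new = np.zeros_like(u)
    for i in range(nr):
        for j in range(nt):
            u_new[i, j] = (u[i, j] + dt / 2 * (r1[i, j] + r2[i, j])) / (
                1 + dt * lam(h_new[i, j])
            )
    return floor(h_new, u_new)


def naive_tau_max(tau, bin_index, n_bins):
    """Flat max of |τ| over samples and member cells, plain loops."""
    nt_s, nr, ntheta, _ = tau.shape
    out = [0.0] * n_bins
    for k in range(nt_s):
        for i in range(nr):
            b = bin_index[i]
            for j in range(ntheta):
                m = math.hypot(tau[k, i, j, 0], tau[k, i, j, 1])
                if m > out[b]:
                    out[b] = m
    return np.array(out)


def naive_osi(tau_rot, bin_index, weights, dt, n_bins):
    """OSI per bin from the printed definition, plain loops.

    OSI = 1 − |Σ_cells Σ_t w τ Δt| / (Σ_cells Σ_t w |τ| Δt).
    """
    nt_s, nr, ntheta, _ = tau_rot.shape
    num = np.zeros((n_bins, 2))
    den = np.zeros(n_bins)
    for k in range(nt_s):
        for i in range(nr):
            b = bin_index[i]
            for j in range(ntheta):
                w = weights[i, j]
                num[b, 0] += w * tau_rot[k, i, j, 0] * dt
                num[b, 1] += w * tau_rot[k, i, j, 1] * dt
                den[b] += w * math.hypot(tau_rot[k, i, j, 0], tau_rot[k, i, j, 1]) * dt
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if den[b] > 0:
            out[b] = 1 - math.hypot(num[b, 0], num[b, 1]) / den[b]
    return out
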