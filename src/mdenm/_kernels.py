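"""Compiled inner loops: forces and Langevin / velocity-Verlet stepping.

All arrays are float64; units follow ``mdenm.constants``.  The pair
terms use a CHARMM-style switching taper S(r) between ``r_on`` and
``r_cut`` applied to both the 12-6 term and the Debye-screened
Coulomb term, so the potential and its gradient vanish continuously
at the cutoff.
"""

import numba as nb
import numpy as np

KE_CONV = 1.0e7 / 4184.0
COULOMB_K = 332.0637


@nb.njit(cache=True, fastmath=True)
def compute_forces(x, charges, excl,
                   b_i, b_j, b_k, b_r0,
                   a_i, a_j, a_k, a_kf, a_t0,
                   c_i, c_j, c_k, c_r0,
                   eps, rmin_half,
                   dielectric, lam_inv, r_on, r_cut, F):
    """Fill F with forces; return (bond, angle, contact, vdw, elec) energies."""
    n = x.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    e_bond = 0.0
    e_ang = 0.0
    e_con = 0.0
    e_vdw = 0.0
    e_el = 0.0

    for t in range(b_i.shape[0]):
        i = b_i[t]
        j = b_j[t]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b_r0[t]
        e_bond += 0.5 * b_k[t] * dr * dr
        fmag = -b_k[t] * dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    for t in range(c_i.shape[0]):
        i = c_i[t]
        j = c_j[t]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - c_r0[t]
        e_con += 0.5 * c_k[t] * dr * dr
        fmag = -c_k[t] * dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    for t in range(a_i.shape[0]):
        i = a_i[t]
        j = a_j[t]
        k = a_k[t]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dth = theta - a_t0[t]
        e_ang += 0.5 * a_kf[t] * dth * dth
        coef = -a_kf[t] * dth
        # dtheta/dri = (c*u/|u| - v/|v|) / (|u| s)
        gix = (c * ux / nu - vx / nv) / (nu * s)
        giy = (c * uy / nu - vy / nv) / (nu * s)
        giz = (c * uz / nu - vz / nv) / (nu * s)
        gkx = (c * vx / nv - ux / nu) / (nv * s)
        gky = (c * vy / nv - uy / nu) / (nv * s)
        gkz = (c * vz / nv - uz / nu) / (nv * s)
        F[i, 0] += coef * gix
        F[i, 1] += coef * giy
        F[i, 2] += coef * giz
        F[k, 0] += coef * gkx
        F[k, 1] += coef * gky
        F[k, 2] += coef * gkz
        F[j, 0] -= coef * (gix + gkx)
        F[j, 1] -= coef * (giy + gky)
        F[j, 2] -= coef * (giz + gkz)

    rc2 = r_cut * r_cut
    ron2 = r_on * r_on
    denom = (rc2 - ron2) ** 3
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            rm = rmin_half[i] + rmin_half[j]
            e_ij = np.sqrt(eps[i] * eps[j])
            sr6 = (rm * rm / r2) ** 3
            v_lj = e_ij * (sr6 * sr6 - 2.0 * sr6)
            dv_lj = -12.0 * e_ij * (sr6 * sr6 - sr6) / r
            qq = charges[i] * charges[j]
            if qq != 0.0:
                v_el = COULOMB_K * qq * np.exp(-r * lam_inv) / (dielectric * r)
                dv_el = -v_el * (lam_inv + 1.0 / r)
            else:
                v_el = 0.0
                dv_el = 0.0
            if r2 > ron2:
                sw = (rc2 - r2) ** 2 * (rc2 + 2.0 * r2 - 3.0 * ron2) / denom
                dsw = 12.0 * r * (rc2 - r2) * (ron2 - r2) / denom
            else:
                sw = 1.0
                dsw = 0.0
            e_vdw += sw * v_lj
            e_el += sw * v_el
            dvdr = sw * (dv_lj + dv_el) + dsw * (v_lj + v_el)
            fmag = -dvdr / r
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[i, 2] += fmag * dz
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
            F[j, 2] -= fmag * dz

    return e_bond, e_ang, e_con, e_vdw, e_el


@nb.njit(cache=True)
def run_segment(x, v, masses, charges, excl,
                b_i, b_j, b_k, b_r0,
                a_i, a_j, a_k, a_kf, a_t0,
                c_i, c_j, c_k, c_r0,
                eps, rmin_half,
                dielectric, lam_inv, r_on, r_cut,
                n_steps, dt, gamma_fs, kT, thermostat, seed,
                u_proj, record_proj, trace, temp_trace):
    """BAOAB Langevin (thermostat) or velocity-Verlet (NVE) propagation.

    Mutates ``x`` and ``v`` in place.  ``trace`` receives the kinetic
    energy projected on ``u_proj`` each step when ``record_proj``;
    ``temp_trace`` receives the instantaneous kinetic energy (kcal/mol).
    Returns -1 on success or the step index where coordinates blew up.
    """
    np.random.seed(seed)
    n = x.shape[0]
    F = np.zeros_like(x)
    compute_forces(x, charges, excl, b_i, b_j, b_k, b_r0,
                   a_i, a_j, a_k, a_kf, a_t0, c_i, c_j, c_k, c_r0,
                   eps, rmin_half, dielectric, lam_inv, r_on, r_cut, F)
    c1 = np.exp(-gamma_fs * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sig = np.empty(n)
    for i in range(n):
        sig[i] = np.sqrt(kT / (masses[i] * KE_CONV))
    winv = np.empty(n)
    for i in range(n):
        winv[i] = 0.5 * dt / (masses[i] * KE_CONV)
    mu = 0.0
    if record_proj:
        for i in range(n):
            mu += masses[i] * (u_proj[i, 0] ** 2 + u_proj[i, 1] ** 2 + u_proj[i, 2] ** 2)
    for step in range(n_steps):
        # B half kick
        for i in range(n):
            v[i, 0] += winv[i] * F[i, 0]
            v[i, 1] += winv[i] * F[i, 1]
            v[i, 2] += winv[i] * F[i, 2]
        # A half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        # O
        if thermostat:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * sig[i] * np.random.standard_normal()
                v[i, 1] = c1 * v[i, 1] + c2 * sig[i] * np.random.standard_normal()
                v[i, 2] = c1 * v[i, 2] + c2 * sig[i] * np.random.standard_normal()
        # A half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        compute_forces(x, charges, excl, b_i, b_j, b_k, b_r0,
                       a_i, a_j, a_k, a_kf, a_t0, c_i, c_j, c_k, c_r0,
                       eps, rmin_half, dielectric, lam_inv, r_on, r_cut, F)
        # B half kick
        for i in range(n):
            v[i, 0] += winv[i] * F[i, 0]
            v[i, 1] += winv[i] * F[i, 1]
            v[i, 2] += winv[i] * F[i, 2]
        ke = 0.0
        for i in range(n):
            ke += masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
        ke *= 0.5 * KE_CONV
        temp_trace[step] = ke
        if record_proj:
            p = 0.0
            for i in range(n):
                p += masses[i] * (v[i, 0] * u_proj[i, 0] + v[i, 1] * u_proj[i, 1]
                                  + v[i, 2] * u_proj[i, 2])
            coef = p / mu
            trace[step] = 0.5 * coef * coef * mu * KE_CONV
        if step % 100 == 0:
            bad = False
            for i in range(n):
                if (not np.isfinite(x[i, 0])) or abs(x[i, 0]) > 1e6 \
                        or abs(x[i, 1]) > 1e6 or abs(x[i, 2]) > 1e6:
                    bad = True
                    break
            if bad:
                return step
    return -1
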