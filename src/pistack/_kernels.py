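"""Numba-compiled inner loops: pair energetics and rigid-body updates.

These are the single implementation of the switched LJ + Coulomb pair sum
and of the velocity-Verlet rigid-body update; the Python-level
``forcefield`` and ``dynamics`` APIs delegate here, and the steered-pull
driver chains them in one compiled loop.  fastmath stays off so runs are
bitwise reproducible.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

KCAL = 418.4  # kcal/mol -> amu*A^2/ps^2


@njit(cache=True)
def pair_energy_forces(x, ii, jj, eps, rmin2, qq, ron2, roff2, inv_denom, forces):
    """Switched LJ + Coulomb sum over the pair list; fills ``forces`` in place.

    Returns the total energy (kcal/mol).  ``forces`` must cover every row of
    ``x`` and is zeroed here.
    """
    forces[:] = 0.0
    e_tot = 0.0
    for p in range(ii.shape[0]):
        i = ii[p]
        j = jj[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= roff2:
            continue
        r = math.sqrt(r2)
        s2 = rmin2[p] / r2
        s6 = s2 * s2 * s2
        e_lj = eps[p] * (s6 * s6 - 2.0 * s6)
        e_c = qq[p] / r
        dedr = -12.0 * eps[p] * (s6 * s6 - s6) / r - e_c / r
        e = e_lj + e_c
        if r2 > ron2:
            a = roff2 - r2
            sw = a * a * (roff2 + 2.0 * r2 - 3.0 * ron2) * inv_denom
            dsw = 12.0 * r * a * (ron2 - r2) * inv_denom
            dedr = dedr * sw + e * dsw
            e = e * sw
        e_tot += e
        c = -dedr / r
        fx = c * dx
        fy = c * dy
        fz = c * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e_tot


@njit(cache=True)
def kick(x, forces, coms, vels, ang_mom, mol_masses, offsets, fixed, half_dt):
    """Impulse update of COM velocities and angular momenta from atom forces."""
    for m in range(coms.shape[0]):
        if fixed[m]:
            continue
        fnx = 0.0
        fny = 0.0
        fnz = 0.0
        tx = 0.0
        ty = 0.0
        tz = 0.0
        for a in range(offsets[m], offsets[m + 1]):
            fx = forces[a, 0]
            fy = forces[a, 1]
            fz = forces[a, 2]
            rx = x[a, 0] - coms[m, 0]
            ry = x[a, 1] - coms[m, 1]
            rz = x[a, 2] - coms[m, 2]
            fnx += fx
            fny += fy
            fnz += fz
            tx += ry * fz - rz * fy
            ty += rz * fx - rx * fz
            tz += rx * fy - ry * fx
        s = half_dt * KCAL / mol_masses[m]
        vels[m, 0] += s * fnx
        vels[m, 1] += s * fny
        vels[m, 2] += s * fnz
        ang_mom[m, 0] += half_dt * KCAL * tx
        ang_mom[m, 1] += half_dt * KCAL * ty
        ang_mom[m, 2] += half_dt * KCAL * tz


@njit(cache=True)
def _axis_rotation(rots, lb, m, k, tau, inv_inertia):
    """Exact flow of the k-th principal-axis kinetic term for time tau.

    Rotates the body frame about its k-th principal axis by
    theta = (L_body_k / I_k) * tau (right-multiplication of R) and
    counter-rotates L_body, so R @ L_body — the lab angular momentum —
    is left exactly unchanged.
    """
    theta = lb[k] * inv_inertia[m, k] * tau
    if theta == 0.0:
        return
    c = math.cos(theta)
    s = math.sin(theta)
    i = (k + 1) % 3
    j = (k + 2) % 3
    for r in range(3):
        ri = rots[m, r, i]
        rj = rots[m, r, j]
        rots[m, r, i] = c * ri + s * rj
        rots[m, r, j] = -s * ri + c * rj
    li = lb[i]
    lj = lb[j]
    lb[i] = c * li + s * lj
    lb[j] = -s * li + c * lj


@njit(cache=True)
def drift_sync(x, coms, rots, vels, ang_mom, inv_inertia, body, offsets, fixed, dt):
    """Translate COMs, rotate body frames over dt, rebuild coordinates.

    Free rotation uses the symmetric principal-axis factorization
    exp(dt/2 T3) exp(dt/2 T2) exp(dt T1) exp(dt/2 T2) exp(dt/2 T3):
    time-reversible (second order) and exactly conserving the lab-frame
    angular momentum of each molecule.
    """
    lb = np.empty(3)
    for m in range(coms.shape[0]):
        if fixed[m]:
            continue
        coms[m, 0] += dt * vels[m, 0]
        coms[m, 1] += dt * vels[m, 1]
        coms[m, 2] += dt * vels[m, 2]
        l0 = ang_mom[m, 0]
        l1 = ang_mom[m, 1]
        l2 = ang_mom[m, 2]
        lb[0] = rots[m, 0, 0] * l0 + rots[m, 1, 0] * l1 + rots[m, 2, 0] * l2
        lb[1] = rots[m, 0, 1] * l0 + rots[m, 1, 1] * l1 + rots[m, 2, 1] * l2
        lb[2] = rots[m, 0, 2] * l0 + rots[m, 1, 2] * l1 + rots[m, 2, 2] * l2
        _axis_rotation(rots, lb, m, 2, 0.5 * dt, inv_inertia)
        _axis_rotation(rots, lb, m, 1, 0.5 * dt, inv_inertia)
        _axis_rotation(rots, lb, m, 0, dt, inv_inertia)
        _axis_rotation(rots, lb, m, 1, 0.5 * dt, inv_inertia)
        _axis_rotation(rots, lb, m, 2, 0.5 * dt, inv_inertia)
        for a in range(offsets[m], offsets[m + 1]):
            bx = body[a, 0]
            by = body[a, 1]
            bz = body[a, 2]
            x[a, 0] = coms[m, 0] + rots[m, 0, 0] * bx + rots[m, 0, 1] * by + rots[m, 0, 2] * bz
            x[a, 1] = coms[m, 1] + rots[m, 1, 0] * bx + rots[m, 1, 1] * by + rots[m, 1, 2] * bz
            x[a, 2] = coms[m, 2] + rots[m, 2, 0] * bx + rots[m, 2, 1] * by + rots[m, 2, 2] * bz


@njit(cache=True)
def pull_loop(
    n_steps,
    dt,
    stride,
    x,
    forces,
    ii,
    jj,
    eps,
    rmin2,
    qq,
    ron2,
    roff2,
    inv_denom,
    coms,
    rots,
    vels,
    ang_mom,
    inv_inertia,
    body,
    offsets,
    fixed,
    mol_masses,
    pulled,
    partner,
    weights,
    k_int,
    k_pn,
    velocity,
    nvec,
    origin,
    rec_t,
    rec_f,
    rec_d,
    rec_c,
):
    """Full constant-velocity pull: velocity-Verlet chain with spring force.

    Records every ``stride`` steps into the rec_* arrays (slot 0 is the
    initial state).  Returns (number of records, abort step); abort step is
    -1 on success, otherwise the step at which a non-finite energy appeared.
    """
    half = 0.5 * dt

    # initial force evaluation and record
    e = pair_energy_forces(x, ii, jj, eps, rmin2, qq, ron2, roff2, inv_denom, forces)
    t = 0.0
    ext = (
        (origin[0] + velocity * t * nvec[0] - coms[pulled, 0]) * nvec[0]
        + (origin[1] + velocity * t * nvec[1] - coms[pulled, 1]) * nvec[1]
        + (origin[2] + velocity * t * nvec[2] - coms[pulled, 2]) * nvec[2]
    )
    for a in range(offsets[pulled], offsets[pulled + 1]):
        w = weights[a - offsets[pulled]] * k_int * ext
        forces[a, 0] += w * nvec[0]
        forces[a, 1] += w * nvec[1]
        forces[a, 2] += w * nvec[2]
    rec_t[0] = 0.0
    rec_f[0] = k_pn * ext
    rec_d[0] = 0.0
    if partner >= 0:
        dx = coms[pulled, 0] - coms[partner, 0]
        dy = coms[pulled, 1] - coms[partner, 1]
        dz = coms[pulled, 2] - coms[partner, 2]
        rec_c[0] = math.sqrt(dx * dx + dy * dy + dz * dz)
    else:
        rec_c[0] = np.nan
    n_rec = 1

    for istep in range(n_steps):
        kick(x, forces, coms, vels, ang_mom, mol_masses, offsets, fixed, half)
        drift_sync(x, coms, rots, vels, ang_mom, inv_inertia, body, offsets, fixed, dt)
        t = (istep + 1) * dt
        e = pair_energy_forces(x, ii, jj, eps, rmin2, qq, ron2, roff2, inv_denom, forces)
        if not math.isfinite(e):
            return n_rec, istep
        ext = (
            (origin[0] + velocity * t * nvec[0] - coms[pulled, 0]) * nvec[0]
            + (origin[1] + velocity * t * nvec[1] - coms[pulled, 1]) * nvec[1]
            + (origin[2] + velocity * t * nvec[2] - coms[pulled, 2]) * nvec[2]
        )
        for a in range(offsets[pulled], offsets[pulled + 1]):
            w = weights[a - offsets[pulled]] * k_int * ext
            forces[a, 0] += w * nvec[0]
            forces[a, 1] += w * nvec[1]
            forces[a, 2] += w * nvec[2]
        kick(x, forces, coms, vels, ang_mom, mol_masses, offsets, fixed, half)
        if (istep + 1) % stride == 0:
            rec_t[n_rec] = t
            rec_f[n_rec] = k_pn * ext
            rec_d[n_rec] = (
                (coms[pulled, 0] - origin[0]) * nvec[0]
                + (coms[pulled, 1] - origin[1]) * nvec[1]
                + (coms[pulled, 2] - origin[2]) * nvec[2]
            )
            if partner >= 0:
                dx = coms[pulled, 0] - coms[partner, 0]
                dy = coms[pulled, 1] - coms[partner, 1]
                dz = coms[pulled, 2] - coms[partner, 2]
                rec_c[n_rec] = math.sqrt(dx * dx + dy * dy + dz * dz)
            else:
                rec_c[n_rec] = np.nan
            n_rec += 1
    return n_rec, -1
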