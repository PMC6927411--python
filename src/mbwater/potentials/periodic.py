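"""Periodic (liquid-box) evaluation: minimum-image real-space terms, Ewald
electrostatics, tapered induction, and the switched short-range terms.

Design notes
------------
* Permanent charge-charge electrostatics use a standard Ewald sum (erfc
  real space within the cutoff, reciprocal sum, self and intramolecular
  exclusion corrections).
* Induced dipoles interact through minimum-image Thole-damped tensors inside
  the real-space cutoff only; long-range induction is neglected.  A quintic
  taper over the last 1 A below the cutoff keeps the truncated terms smooth.
* Dispersion, Born-Mayer repulsion and the 3B term are minimum-image
  truncated at the cutoff with the same taper; no tail corrections.
* Fitted (swapped) short-range terms are evaluated outside the compiled
  kernel by enumerating molecule pairs/triples with minimum-image wrapping;
  adequate for short demonstration runs.

The hot loops are numba-compiled; the per-bead self-consistent dipole solve
is warm-started from the previous evaluation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..constants import COULOMB
from .cluster import PotentialError, molecule_atom_table
from .params import WaterParams

_SQRT_PI = math.sqrt(math.pi)

#: width (A) of the smooth taper applied below the real-space cutoff
TAPER_WIDTH = 1.0

#: Ewald accuracy parameters: kappa = EWALD_P / cutoff for the real-space
#: screening; the reciprocal sum is truncated at kmax ~ kappa*L*P_RECIP/pi
EWALD_P = 3.2
EWALD_P_RECIP = 2.8


# ---------------------------------------------------------------------------
# scalar helpers

@njit(cache=True, inline="always")
def _sw(r, r_in, r_out):
    if r <= r_in:
        return 1.0, 0.0
    if r >= r_out:
        return 0.0, 0.0
    x = (r - r_in) / (r_out - r_in)
    s = 1.0 - x * x * x * (10.0 - 15.0 * x + 6.0 * x * x)
    ds = -30.0 * x * x * (1.0 - x) * (1.0 - x) / (r_out - r_in)
    return s, ds


@njit(cache=True, inline="always")
def _tt6_s(x):
    if x > 60.0:
        return 1.0, 0.0
    term = 1.0
    s = 1.0
    for k in range(1, 7):
        term = term * x / k
        s += term
    ex = math.exp(-x)
    return 1.0 - ex * s, ex * term


@njit(cache=True, inline="always")
def _thole_s(r, a, alpha):
    s = a * r * r * r / alpha
    if s > 60.0:
        return 1.0, 1.0, 0.0, 0.0
    es = math.exp(-s)
    lam3 = 1.0 - es
    lam5 = 1.0 - (1.0 + s) * es
    dsdr = 3.0 * s / r
    return lam3, lam5, dsdr * es, dsdr * s * es


@njit(cache=True, inline="always")
def _mi(x, L):
    return x - L * round(x / L)


# ---------------------------------------------------------------------------
# the main periodic kernel

@njit(cache=True)
def _periodic_terms(coords, L, q, pp, kvecs, mu, want_forces):
    """Energies, forces, dipoles for one frame of a periodic water box.

    ``pp`` packs parameters:
    [0]=alpha, [1]=thole_a, [2]=c6, [3]=b_disp, [4]=bm_a, [5]=bm_b,
    [6]=sw2_in, [7]=sw2_out, [8]=c9, [9]=sw3_in, [10]=sw3_out, [11]=rc,
    [12]=kappa, [13]=hard_floor, [14]=k_r, [15]=r0, [16]=k_cub,
    [17]=k_theta, [18]=theta0, [19]=use_short2b, [20]=use_short3b,
    [21]=bm_a_oh, [22]=bm_a_hh.
    ``mu`` (n_mol, 3) is the dipole warm start, updated in place.
    Returns (eterms[6], F, ok) with eterms =
    [bonded, coulomb, induction, dispersion, short2b, short3b].
    """
    n = coords.shape[0]
    n_mol = n // 3
    alpha = pp[0]
    thole_a = pp[1]
    rc = pp[11]
    kappa = pp[12]
    rtap_in = rc - TAPER_WIDTH
    eterms = np.zeros(6)
    F = np.zeros((n, 3))
    ok = 1

    # ---- bonded (minimum-image intramolecular displacements) ----
    for m in range(n_mol):
        o = 3 * m
        for h in (o + 1, o + 2):
            dx = _mi(coords[h, 0] - coords[o, 0], L)
            dy = _mi(coords[h, 1] - coords[o, 1], L)
            dz = _mi(coords[h, 2] - coords[o, 2], L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - pp[15]
            eterms[0] += 0.5 * pp[14] * dr * dr + pp[16] * dr * dr * dr
            if want_forces:
                dEdr = (pp[14] * dr + 3.0 * pp[16] * dr * dr) / r
                F[h, 0] -= dEdr * dx
                F[h, 1] -= dEdr * dy
                F[h, 2] -= dEdr * dz
                F[o, 0] += dEdr * dx
                F[o, 1] += dEdr * dy
                F[o, 2] += dEdr * dz
        # bend
        d1x = _mi(coords[o + 1, 0] - coords[o, 0], L)
        d1y = _mi(coords[o + 1, 1] - coords[o, 1], L)
        d1z = _mi(coords[o + 1, 2] - coords[o, 2], L)
        d2x = _mi(coords[o + 2, 0] - coords[o, 0], L)
        d2y = _mi(coords[o + 2, 1] - coords[o, 1], L)
        d2z = _mi(coords[o + 2, 2] - coords[o, 2], L)
        r1 = math.sqrt(d1x * d1x + d1y * d1y + d1z * d1z)
        r2 = math.sqrt(d2x * d2x + d2y * d2y + d2z * d2z)
        ct = (d1x * d2x + d1y * d2y + d1z * d2z) / (r1 * r2)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        th = math.acos(ct)
        dth = th - pp[18]
        eterms[0] += 0.5 * pp[17] * dth * dth
        if want_forces:
            st = math.sqrt(max(1.0 - ct * ct, 1e-12))
            dEdth = pp[17] * dth
            u1x, u1y, u1z = d1x / r1, d1y / r1, d1z / r1
            u2x, u2y, u2z = d2x / r2, d2y / r2, d2z / r2
            g1x = (ct * u1x - u2x) / (st * r1)
            g1y = (ct * u1y - u2y) / (st * r1)
            g1z = (ct * u1z - u2z) / (st * r1)
            g2x = (ct * u2x - u1x) / (st * r2)
            g2y = (ct * u2y - u1y) / (st * r2)
            g2z = (ct * u2z - u1z) / (st * r2)
            F[o + 1, 0] -= dEdth * g1x
            F[o + 1, 1] -= dEdth * g1y
            F[o + 1, 2] -= dEdth * g1z
            F[o + 2, 0] -= dEdth * g2x
            F[o + 2, 1] -= dEdth * g2y
            F[o + 2, 2] -= dEdth * g2z
            F[o, 0] += dEdth * (g1x + g2x)
            F[o, 1] += dEdth * (g1y + g2y)
            F[o, 2] += dEdth * (g1z + g2z)

    # ---- real-space pair loop (Coulomb erfc; O-O dispersion/repulsion) ----
    q2sum = 0.0
    for i in range(n):
        q2sum += q[i] * q[i]
    have_pairs = (q2sum > 0.0 or pp[2] != 0.0 or pp[0] > 0.0
                  or pp[13] > 0.0)
    for i in range(n if have_pairs else 0):
        mi_ = i // 3
        for j in range(i + 1, n):
            if j // 3 == mi_:
                continue
            dx = _mi(coords[i, 0] - coords[j, 0], L)
            dy = _mi(coords[i, 1] - coords[j, 1], L)
            dz = _mi(coords[i, 2] - coords[j, 2], L)
            r2_ = dx * dx + dy * dy + dz * dz
            if r2_ > rc * rc:
                continue
            r = math.sqrt(r2_)
            if r < pp[13]:
                ok = 0
                return eterms, F, ok
            qq = COULOMB * q[i] * q[j]
            er = math.erfc(kappa * r)
            eterms[1] += qq * er / r
            if want_forces:
                dEdr = -qq * (er / r2_
                              + 2.0 * kappa / _SQRT_PI
                              * math.exp(-kappa * kappa * r2_) / r)
                fx = -dEdr * dx / r
                fy = -dEdr * dy / r
                fz = -dEdr * dz / r
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
            if i % 3 == 0 and j % 3 == 0:  # O-O pair: dispersion only
                t, dt = _sw(r, rtap_in, rc)  # taper: 1 below rtap_in
                f6, df6 = _tt6_s(pp[3] * r)
                r6 = r2_ * r2_ * r2_
                edisp = -pp[2] * f6 / r6
                eterms[3] += edisp * t
                if want_forces:
                    ddisp = -pp[2] * (df6 * pp[3] / r6 - 6.0 * f6 / (r6 * r))
                    dEdr = ddisp * t + edisp * dt
                    fx = -dEdr * dx / r
                    fy = -dEdr * dy / r
                    fz = -dEdr * dz / r
                    F[i, 0] += fx
                    F[i, 1] += fy
                    F[i, 2] += fz
                    F[j, 0] -= fx
                    F[j, 1] -= fy
                    F[j, 2] -= fz

    # ---- short-range 2B repulsion (molecule-pair loop, O-O switched) ----
    if pp[19] != 0.0 and (pp[4] != 0.0 or pp[21] != 0.0 or pp[22] != 0.0):
        for a in range(n_mol):
            for b in range(a + 1, n_mol):
                ox = _mi(coords[3 * a, 0] - coords[3 * b, 0], L)
                oy = _mi(coords[3 * a, 1] - coords[3 * b, 1], L)
                oz = _mi(coords[3 * a, 2] - coords[3 * b, 2], L)
                roo = math.sqrt(ox * ox + oy * oy + oz * oz)
                if roo >= rc or roo >= pp[7]:
                    continue
                s2, ds2 = _sw(roo, pp[6], pp[7])
                t, dt = _sw(roo, rtap_in, rc)
                pref = s2 * t
                dpref = ds2 * t + s2 * dt
                esum = 0.0
                for ai in range(3):
                    for bj in range(3):
                        if ai == 0 and bj == 0:
                            w = pp[4]
                        elif ai == 0 or bj == 0:
                            w = pp[21]
                        else:
                            w = pp[22]
                        if w == 0.0:
                            continue
                        i = 3 * a + ai
                        j = 3 * b + bj
                        dx = _mi(coords[i, 0] - coords[j, 0], L)
                        dy = _mi(coords[i, 1] - coords[j, 1], L)
                        dz = _mi(coords[i, 2] - coords[j, 2], L)
                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                        e = w * math.exp(-pp[5] * r)
                        esum += e
                        if want_forces:
                            dEdr = -pp[5] * e * pref
                            fx = -dEdr * dx / r
                            fy = -dEdr * dy / r
                            fz = -dEdr * dz / r
                            F[i, 0] += fx
                            F[i, 1] += fy
                            F[i, 2] += fz
                            F[j, 0] -= fx
                            F[j, 1] -= fy
                            F[j, 2] -= fz
                eterms[4] += esum * pref
                if want_forces:
                    dEdr = dpref * esum
                    fx = -dEdr * ox / roo
                    fy = -dEdr * oy / roo
                    fz = -dEdr * oz / roo
                    F[3 * a, 0] += fx
                    F[3 * a, 1] += fy
                    F[3 * a, 2] += fz
                    F[3 * b, 0] -= fx
                    F[3 * b, 1] -= fy
                    F[3 * b, 2] -= fz

    # ---- Ewald reciprocal + self + intramolecular exclusions ----
    # phase tables e^{i 2 pi n x / L} built by recursion; per k-vector each
    # atom needs two complex multiplies instead of trig calls
    nk = kvecs.shape[0] if q2sum > 0.0 else 0
    twopi = 2.0 * math.pi
    V = L * L * L
    pref = COULOMB * twopi / V
    kmax = 0
    for kk in range(nk):
        for d in range(3):
            a = abs(kvecs[kk, d])
            if a > kmax:
                kmax = a
    tab = np.empty((3, n, kmax + 1), dtype=np.complex128)
    for d in range(3):
        for i in range(n):
            u = complex(math.cos(twopi * coords[i, d] / L),
                        math.sin(twopi * coords[i, d] / L))
            tab[d, i, 0] = 1.0 + 0.0j
            for m in range(1, kmax + 1):
                tab[d, i, m] = tab[d, i, m - 1] * u
    ex = np.empty(n, dtype=np.complex128)
    for kk in range(nk):
        nx = kvecs[kk, 0]
        ny = kvecs[kk, 1]
        nz = kvecs[kk, 2]
        kx = twopi * nx / L
        ky = twopi * ny / L
        kz = twopi * nz / L
        k2 = kx * kx + ky * ky + kz * kz
        ck = math.exp(-k2 / (4.0 * kappa * kappa)) / k2
        sre = 0.0
        sim = 0.0
        for i in range(n):
            px = tab[0, i, nx] if nx >= 0 else tab[0, i, -nx].conjugate()
            py = tab[1, i, ny] if ny >= 0 else tab[1, i, -ny].conjugate()
            pz = tab[2, i, nz] if nz >= 0 else tab[2, i, -nz].conjugate()
            e = px * py * pz
            ex[i] = e
            sre += q[i] * e.real
            sim += q[i] * e.imag
        eterms[1] += 2.0 * pref * ck * (sre * sre + sim * sim)
        if want_forces:
            for i in range(n):
                # Im(conj(S) e^{ik r_i}) = sre*Im(e) - sim*Re(e)
                im = sre * ex[i].imag - sim * ex[i].real
                fac = 4.0 * pref * ck * q[i] * im
                F[i, 0] += fac * kx
                F[i, 1] += fac * ky
                F[i, 2] += fac * kz
    # self energy
    q2sum = 0.0
    for i in range(n):
        q2sum += q[i] * q[i]
    eterms[1] -= COULOMB * kappa / _SQRT_PI * q2sum
    # intramolecular exclusion: remove erf-screened part added by k-space
    for m in range(n_mol):
        base = 3 * m
        for a in range(3):
            for b in range(a + 1, 3):
                i = base + a
                j = base + b
                dx = _mi(coords[i, 0] - coords[j, 0], L)
                dy = _mi(coords[i, 1] - coords[j, 1], L)
                dz = _mi(coords[i, 2] - coords[j, 2], L)
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                qq = COULOMB * q[i] * q[j]
                erf = 1.0 - math.erfc(kappa * r)
                eterms[1] -= qq * erf / r
                if want_forces:
                    dEdr = qq * (erf / (r * r)
                                 - 2.0 * kappa / _SQRT_PI
                                 * math.exp(-kappa * kappa * r * r) / r)
                    fx = -dEdr * dx / r
                    fy = -dEdr * dy / r
                    fz = -dEdr * dz / r
                    F[i, 0] += fx
                    F[i, 1] += fy
                    F[i, 2] += fz
                    F[j, 0] -= fx
                    F[j, 1] -= fy
                    F[j, 2] -= fz

    # ---- induction ----
    if alpha > 0.0:
        e_ind, ok_scf = _induction(coords, L, q, alpha, thole_a, rc,
                                   rtap_in, mu, F, want_forces)
        eterms[2] = e_ind
        if ok_scf == 0:
            ok = 0
            return eterms, F, ok

    # ---- 3B ATM ----
    if pp[8] != 0.0 and pp[20] != 0.0 and n_mol >= 3:
        eterms[5] = _atm_periodic(coords, L, pp[8], pp[9], pp[10], F,
                                  want_forces)

    return eterms, F, ok


@njit(cache=True)
def _induction(coords, L, q, alpha, thole_a, rc, rtap_in, mu, F,
               want_forces):
    """Self-consistent tapered Thole dipoles on the oxygens; returns the
    induction energy and a success flag.  ``mu`` is warm start and output."""
    n = coords.shape[0]
    n_mol = n // 3
    # permanent field at each O site
    E0 = np.zeros((n_mol, 3))
    for s in range(n_mol):
        i = 3 * s
        for j in range(n):
            if j // 3 == s:
                continue
            dx = _mi(coords[i, 0] - coords[j, 0], L)
            dy = _mi(coords[i, 1] - coords[j, 1], L)
            dz = _mi(coords[i, 2] - coords[j, 2], L)
            r2_ = dx * dx + dy * dy + dz * dz
            if r2_ > rc * rc:
                continue
            r = math.sqrt(r2_)
            lam3, lam5, dlam3, dlam5 = _thole_s(r, thole_a, alpha)
            t, dt = _sw(r, rtap_in, rc)
            g1 = lam3 * t / (r2_ * r)
            c = COULOMB * q[j] * g1
            E0[s, 0] += c * dx
            E0[s, 1] += c * dy
            E0[s, 2] += c * dz
    # O-O dipole pair tables within cutoff
    max_pairs = n_mol * (n_mol - 1) // 2
    pi_ = np.empty(max_pairs, dtype=np.int64)
    pj_ = np.empty(max_pairs, dtype=np.int64)
    pd = np.empty((max_pairs, 3))
    pr = np.empty(max_pairs)
    npair = 0
    for a in range(n_mol):
        for b in range(a + 1, n_mol):
            dx = _mi(coords[3 * a, 0] - coords[3 * b, 0], L)
            dy = _mi(coords[3 * a, 1] - coords[3 * b, 1], L)
            dz = _mi(coords[3 * a, 2] - coords[3 * b, 2], L)
            r2_ = dx * dx + dy * dy + dz * dz
            if r2_ > rc * rc:
                continue
            pi_[npair] = a
            pj_[npair] = b
            pd[npair, 0] = dx
            pd[npair, 1] = dy
            pd[npair, 2] = dz
            pr[npair] = math.sqrt(r2_)
            npair += 1
    # SCF iteration: mu = (alpha/ke) (E0 + T mu), damped fixed point
    inv_hard = alpha / COULOMB
    mix = 0.65
    ok = 0
    for _ in range(500):
        field = E0.copy()
        for p in range(npair):
            a = pi_[p]
            b = pj_[p]
            r = pr[p]
            lam3, lam5, _, _ = _thole_s(r, thole_a, alpha)
            t, _ = _sw(r, rtap_in, rc)
            r2_ = r * r
            g3 = COULOMB * lam3 * t / (r2_ * r)
            g5 = COULOMB * 3.0 * lam5 * t / (r2_ * r2_ * r)
            dx, dy, dz = pd[p, 0], pd[p, 1], pd[p, 2]
            mbr = mu[b, 0] * dx + mu[b, 1] * dy + mu[b, 2] * dz
            mar = mu[a, 0] * dx + mu[a, 1] * dy + mu[a, 2] * dz
            field[a, 0] += g5 * mbr * dx - g3 * mu[b, 0]
            field[a, 1] += g5 * mbr * dy - g3 * mu[b, 1]
            field[a, 2] += g5 * mbr * dz - g3 * mu[b, 2]
            field[b, 0] += g5 * mar * dx - g3 * mu[a, 0]
            field[b, 1] += g5 * mar * dy - g3 * mu[a, 1]
            field[b, 2] += g5 * mar * dz - g3 * mu[a, 2]
        dmax = 0.0
        for s in range(n_mol):
            for d in range(3):
                new = inv_hard * field[s, d]
                upd = (1.0 - mix) * mu[s, d] + mix * new
                diff = abs(upd - mu[s, d])
                if diff > dmax:
                    dmax = diff
                mu[s, d] = upd
        if dmax < 1e-9:
            ok = 1
            break
    e_ind = 0.0
    for s in range(n_mol):
        e_ind -= 0.5 * (mu[s, 0] * E0[s, 0] + mu[s, 1] * E0[s, 1]
                        + mu[s, 2] * E0[s, 2])
    if not want_forces or ok == 0:
        return e_ind, ok
    # forces: charge-field gradients
    for s in range(n_mol):
        i = 3 * s
        for j in range(coords.shape[0]):
            if j // 3 == s:
                continue
            dx = _mi(coords[i, 0] - coords[j, 0], L)
            dy = _mi(coords[i, 1] - coords[j, 1], L)
            dz = _mi(coords[i, 2] - coords[j, 2], L)
            r2_ = dx * dx + dy * dy + dz * dz
            if r2_ > rc * rc:
                continue
            r = math.sqrt(r2_)
            lam3, lam5, dlam3, dlam5 = _thole_s(r, thole_a, alpha)
            t, dt = _sw(r, rtap_in, rc)
            g1 = lam3 * t / (r2_ * r)
            dg1 = (dlam3 * t + lam3 * dt) / (r2_ * r) - 3.0 * lam3 * t / (r2_ * r2_)
            mr = mu[s, 0] * dx + mu[s, 1] * dy + mu[s, 2] * dz
            c = COULOMB * q[j]
            fx = c * (g1 * mu[s, 0] + dg1 / r * mr * dx)
            fy = c * (g1 * mu[s, 1] + dg1 / r * mr * dy)
            fz = c * (g1 * mu[s, 2] + dg1 / r * mr * dz)
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
    # dipole-dipole gradients
    for p in range(npair):
        a = pi_[p]
        b = pj_[p]
        r = pr[p]
        dx, dy, dz = pd[p, 0], pd[p, 1], pd[p, 2]
        lam3, lam5, dlam3, dlam5 = _thole_s(r, thole_a, alpha)
        t, dt = _sw(r, rtap_in, rc)
        l3 = lam3 * t
        l5 = lam5 * t
        dl3 = dlam3 * t + lam3 * dt
        dl5 = dlam5 * t + lam5 * dt
        r2_ = r * r
        r5 = r2_ * r2_ * r
        Ci = mu[a, 0] * dx + mu[a, 1] * dy + mu[a, 2] * dz
        Cj = mu[b, 0] * dx + mu[b, 1] * dy + mu[b, 2] * dz
        B = (mu[a, 0] * mu[b, 0] + mu[a, 1] * mu[b, 1]
             + mu[a, 2] * mu[b, 2])
        c1 = COULOMB * 3.0 * l5 / r5
        c2 = COULOMB * (3.0 * dl5 * Ci * Cj / (r5 * r)
                        - 15.0 * l5 * Ci * Cj / (r5 * r2_)
                        - dl3 * B / (r2_ * r2_)
                        + 3.0 * l3 * B / r5)
        gx = c1 * (Cj * mu[a, 0] + Ci * mu[b, 0]) + c2 * dx
        gy = c1 * (Cj * mu[a, 1] + Ci * mu[b, 1]) + c2 * dy
        gz = c1 * (Cj * mu[a, 2] + Ci * mu[b, 2]) + c2 * dz
        F[3 * a, 0] += gx
        F[3 * a, 1] += gy
        F[3 * a, 2] += gz
        F[3 * b, 0] -= gx
        F[3 * b, 1] -= gy
        F[3 * b, 2] -= gz
    return e_ind, ok


@njit(cache=True)
def _atm_periodic(coords, L, c9, r_in, r_out, F, want_forces):
    """Minimum-image switched Axilrod-Teller-Muto sum over O triples."""
    n_mol = coords.shape[0] // 3
    E = 0.0
    for a in range(n_mol):
        for b in range(a + 1, n_mol):
            d12x = _mi(coords[3 * a, 0] - coords[3 * b, 0], L)
            d12y = _mi(coords[3 * a, 1] - coords[3 * b, 1], L)
            d12z = _mi(coords[3 * a, 2] - coords[3 * b, 2], L)
            s12 = math.sqrt(d12x * d12x + d12y * d12y + d12z * d12z)
            if s12 >= r_out:
                continue
            for c in range(b + 1, n_mol):
                d13x = _mi(coords[3 * a, 0] - coords[3 * c, 0], L)
                d13y = _mi(coords[3 * a, 1] - coords[3 * c, 1], L)
                d13z = _mi(coords[3 * a, 2] - coords[3 * c, 2], L)
                s13 = math.sqrt(d13x * d13x + d13y * d13y + d13z * d13z)
                if s13 >= r_out:
                    continue
                d23x = _mi(coords[3 * b, 0] - coords[3 * c, 0], L)
                d23y = _mi(coords[3 * b, 1] - coords[3 * c, 1], L)
                d23z = _mi(coords[3 * b, 2] - coords[3 * c, 2], L)
                s23 = math.sqrt(d23x * d23x + d23y * d23y + d23z * d23z)
                if s23 >= r_out:
                    continue
                aa = s12 * s12
                bb = s13 * s13
                cc = s23 * s23
                u = aa + bb - cc
                v = aa + cc - bb
                w = bb + cc - aa
                P = u * v * w
                abc = aa * bb * cc
                g1 = abc**-1.5
                g2 = abc**-2.5
                E0 = c9 * (g1 + 0.375 * P * g2)
                sw12, dsw12 = _sw(s12, r_in, r_out)
                sw13, dsw13 = _sw(s13, r_in, r_out)
                sw23, dsw23 = _sw(s23, r_in, r_out)
                S = sw12 * sw13 * sw23
                E += E0 * S
                if want_forces:
                    g3 = abc**-3.5
                    Pa = v * w + u * w - u * v
                    Pb = v * w - u * w + u * v
                    Pc = -v * w + u * w + u * v
                    dE0da = c9 * (-1.5 * g2 * bb * cc
                                  + 0.375 * (Pa * g2 - 2.5 * P * g3 * bb * cc))
                    dE0db = c9 * (-1.5 * g2 * aa * cc
                                  + 0.375 * (Pb * g2 - 2.5 * P * g3 * aa * cc))
                    dE0dc = c9 * (-1.5 * g2 * aa * bb
                                  + 0.375 * (Pc * g2 - 2.5 * P * g3 * aa * bb))
                    dEdr12 = dE0da * 2.0 * s12 * S + E0 * dsw12 * sw13 * sw23
                    dEdr13 = dE0db * 2.0 * s13 * S + E0 * sw12 * dsw13 * sw23
                    dEdr23 = dE0dc * 2.0 * s23 * S + E0 * sw12 * sw13 * dsw23
                    fx = -dEdr12 * d12x / s12
                    fy = -dEdr12 * d12y / s12
                    fz = -dEdr12 * d12z / s12
                    F[3 * a, 0] += fx
                    F[3 * a, 1] += fy
                    F[3 * a, 2] += fz
                    F[3 * b, 0] -= fx
                    F[3 * b, 1] -= fy
                    F[3 * b, 2] -= fz
                    fx = -dEdr13 * d13x / s13
                    fy = -dEdr13 * d13y / s13
                    fz = -dEdr13 * d13z / s13
                    F[3 * a, 0] += fx
                    F[3 * a, 1] += fy
                    F[3 * a, 2] += fz
                    F[3 * c, 0] -= fx
                    F[3 * c, 1] -= fy
                    F[3 * c, 2] -= fz
                    fx = -dEdr23 * d23x / s23
                    fy = -dEdr23 * d23y / s23
                    fz = -dEdr23 * d23z / s23
                    F[3 * b, 0] += fx
                    F[3 * b, 1] += fy
                    F[3 * b, 2] += fz
                    F[3 * c, 0] -= fx
                    F[3 * c, 1] -= fy
                    F[3 * c, 2] -= fz
    return E


# ---------------------------------------------------------------------------
# standalone Ewald sum for arbitrary point charges (oracle-facing op)

@njit(cache=True)
def _ewald_point(coords, q, L, kappa, kvecs, rc, want_forces):
    n = coords.shape[0]
    E = 0.0
    F = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(coords[i, 0] - coords[j, 0], L)
            dy = _mi(coords[i, 1] - coords[j, 1], L)
            dz = _mi(coords[i, 2] - coords[j, 2], L)
            r2_ = dx * dx + dy * dy + dz * dz
            if r2_ > rc * rc:
                continue
            r = math.sqrt(r2_)
            qq = COULOMB * q[i] * q[j]
            er = math.erfc(kappa * r)
            E += qq * er / r
            if want_forces:
                dEdr = -qq * (er / r2_ + 2.0 * kappa / _SQRT_PI
                              * math.exp(-kappa * kappa * r2_) / r)
                fx = -dEdr * dx / r
                fy = -dEdr * dy / r
                fz = -dEdr * dz / r
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
    twopi = 2.0 * math.pi
    V = L * L * L
    pref = COULOMB * twopi / V
    for kk in range(kvecs.shape[0]):
        kx = twopi * kvecs[kk, 0] / L
        ky = twopi * kvecs[kk, 1] / L
        kz = twopi * kvecs[kk, 2] / L
        k2 = kx * kx + ky * ky + kz * kz
        ck = math.exp(-k2 / (4.0 * kappa * kappa)) / k2
        sre = 0.0
        sim = 0.0
        for i in range(n):
            ph = kx * coords[i, 0] + ky * coords[i, 1] + kz * coords[i, 2]
            sre += q[i] * math.cos(ph)
            sim += q[i] * math.sin(ph)
        E += 2.0 * pref * ck * (sre * sre + sim * sim)
        if want_forces:
            for i in range(n):
                ph = (kx * coords[i, 0] + ky * coords[i, 1]
                      + kz * coords[i, 2])
                im = sre * math.sin(ph) - sim * math.cos(ph)
                fac = 4.0 * pref * ck * q[i] * im
                F[i, 0] += fac * kx
                F[i, 1] += fac * ky
                F[i, 2] += fac * kz
    q2sum = 0.0
    for i in range(n):
        q2sum += q[i] * q[i]
    E -= COULOMB * kappa / _SQRT_PI * q2sum
    return E, F


def half_space_kvectors(kmax: int) -> np.ndarray:
    """Integer reciprocal vectors of one half-space within |n| <= kmax."""
    out = []
    for nx in range(-kmax, kmax + 1):
        for ny in range(-kmax, kmax + 1):
            for nz in range(0, kmax + 1):
                if nz == 0 and (ny < 0 or (ny == 0 and nx <= 0)):
                    continue
                if nx * nx + ny * ny + nz * nz <= kmax * kmax:
                    out.append((nx, ny, nz))
    return np.array(out, dtype=np.int64)


def ewald_energy(coords, charges, box_edge, cutoff=None, accuracy_p=EWALD_P,
                 want_forces=True):
    """Ewald energy (kcal/mol) and forces of point charges in a cubic box.

    Parameters are auto-chosen from the cutoff: kappa = p/cutoff and the
    reciprocal sum truncated near kappa*L*p/pi.  The system must be neutral.
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    if abs(q.sum()) > 1e-10:
        raise ValueError("Ewald sum requires a neutral system")
    L = float(box_edge)
    rc = min(cutoff if cutoff is not None else L / 2.0, L / 2.0)
    kappa = accuracy_p / rc
    kmax = int(np.ceil(kappa * L * accuracy_p / np.pi))
    kvecs = half_space_kvectors(kmax)
    E, F = _ewald_point(coords, q, L, kappa, kvecs, rc, want_forces)
    return (E, F) if want_forces else (E, None)


# ---------------------------------------------------------------------------
# python-facing context

class PeriodicContext:
    """Precomputed topology + Ewald tables for one periodic system."""

    def __init__(self, elements, mol_index, params: WaterParams,
                 fitted2b=None, fitted3b=None):
        self.params = params
        self.fitted2b = fitted2b
        self.fitted3b = fitted3b
        mol_index = np.asarray(mol_index)
        n = len(elements)
        expect = np.repeat(np.arange(n // 3), 3)
        if not np.array_equal(mol_index, expect):
            raise ValueError(
                "periodic evaluation requires contiguous O,H,H molecules"
            )
        self.mol_table = molecule_atom_table(mol_index)
        self.q = np.array([params.q_o if e == "O" else params.q_h
                           for e in elements])
        self.n_mol = n // 3
        self._kcache: dict = {}
        self._mu = np.zeros((self.n_mol, 3))

    def _pack(self, box_edge):
        p = self.params
        rc = min(p.cutoff, box_edge / 2.0)
        if p.cutoff > box_edge / 2.0 + 1e-9:
            raise PotentialError(
                f"cutoff {p.cutoff} A exceeds half the box edge "
                f"{box_edge / 2.0:.3f} A"
            )
        kappa = EWALD_P / rc
        kmax = int(np.ceil(kappa * box_edge * EWALD_P_RECIP / np.pi))
        if kmax not in self._kcache:
            self._kcache[kmax] = half_space_kvectors(kmax)
        interacting = (p.q_h != 0.0 or p.alpha_o > 0.0 or p.c6_oo != 0.0
                       or p.bm_a != 0.0 or p.bm_a_oh != 0.0
                       or p.bm_a_hh != 0.0 or p.c9 != 0.0)
        pp = np.array([
            p.alpha_o, p.thole_a, p.c6_oo, p.b_disp, p.bm_a, p.bm_b,
            p.sw2_rin, p.sw2_rout, p.c9, p.sw3_rin, p.sw3_rout, rc, kappa,
            p.hard_floor if interacting else 0.0, p.k_r, p.r0, p.k_cub,
            p.k_theta, p.theta0,
            0.0 if self.fitted2b is not None else 1.0,
            0.0 if self.fitted3b is not None else 1.0,
            p.bm_a_oh, p.bm_a_hh,
        ])
        return pp, self._kcache[kmax]

    def terms(self, coords, box_edge, want_forces=True, mu0=None):
        """Term energies, forces and converged dipoles for one frame."""
        coords = np.asarray(coords, dtype=float)
        mu = (mu0.copy() if mu0 is not None
              else np.zeros((self.n_mol, 3)))
        pp, kvecs = self._pack(box_edge)
        et, F, ok = _periodic_terms(coords, float(box_edge), self.q, pp,
                                    kvecs, mu, want_forces)
        if ok == 0:
            raise PotentialError(
                "periodic evaluation failed (hard-floor contact or "
                "non-convergent induction)"
            )
        terms = {
            "one_body": float(et[0]),
            "coulomb": float(et[1]),
            "induction": float(et[2]),
            "dispersion": float(et[3]),
            "short2b": float(et[4]),
            "short3b": float(et[5]),
        }
        if self.fitted2b is not None:
            e2, f2 = self.fitted2b.cluster_energy_forces(
                coords, self.mol_table, want_forces, box_edge=box_edge)
            terms["short2b"] = e2
            if want_forces:
                F = F + f2
        if self.fitted3b is not None:
            e3, f3 = self.fitted3b.cluster_energy_forces(
                coords, self.mol_table, want_forces, box_edge=box_edge)
            terms["short3b"] = e3
            if want_forces:
                F = F + f3
        terms["baseline"] = (terms["coulomb"] + terms["induction"]
                             + terms["dispersion"])
        terms["total"] = (terms["one_body"] + terms["baseline"]
                          + terms["short2b"] + terms["short3b"])
        return terms, (F if want_forces else None), mu
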