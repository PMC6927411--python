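"""Energies and analytic forces for non-periodic water clusters.

Implements the four-term architecture of the model
(one-body + classical many-body baseline + switched short-range 2B + 3B):

* one-body: harmonic stretch/bend with a cubic stretch correction;
* baseline: intermolecular point-charge Coulomb, self-consistent Thole-damped
  induced dipoles on the oxygens, and Tang-Toennies-damped O-O dispersion;
* short 2B: Born-Mayer O-O repulsion times a quintic switch;
* short 3B: Axilrod-Teller-Muto O triple-dipole term times pair switches.

All routines return (energy in kcal/mol, forces in kcal/mol/A).  Induced
dipoles are obtained from a dense linear solve; the induction force uses the
variational (Hellmann-Feynman) property of the converged dipoles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ..constants import COULOMB
from .params import WaterParams
from .switching import switch


class PotentialError(RuntimeError):
    """The potential is undefined or ill-conditioned for this geometry."""


# ---------------------------------------------------------------------------
# topology helpers (cached per cluster size / molecule layout)

_PAIR_CACHE: dict = {}


def molecule_atom_table(mol_index: np.ndarray) -> np.ndarray:
    """(n_mol, 3) atom indices, O first, per molecule."""
    n_mol = int(mol_index.max()) + 1
    table = np.empty((n_mol, 3), dtype=int)
    for m in range(n_mol):
        table[m] = np.flatnonzero(mol_index == m)
    return table


def intermolecular_pairs(mol_index: np.ndarray):
    """Index arrays (ia, ib) over all atom pairs in different molecules."""
    key = mol_index.tobytes()
    if key not in _PAIR_CACHE:
        n = len(mol_index)
        ia, ib = np.triu_indices(n, k=1)
        keep = mol_index[ia] != mol_index[ib]
        _PAIR_CACHE[key] = (ia[keep].copy(), ib[keep].copy())
    return _PAIR_CACHE[key]


def atom_charges(elements, p: WaterParams) -> np.ndarray:
    return np.array([p.q_o if e == "O" else p.q_h for e in elements])


# ---------------------------------------------------------------------------
# one-body

def bonded_energy_forces(coords, mol_table, p: WaterParams,
                         want_forces=True):
    """Intramolecular stretch + bend energy (zero at the reference monomer)."""
    o, h1, h2 = mol_table[:, 0], mol_table[:, 1], mol_table[:, 2]
    F = np.zeros_like(coords) if want_forces else None
    E = 0.0
    d1 = coords[h1] - coords[o]
    d2 = coords[h2] - coords[o]
    r1 = np.linalg.norm(d1, axis=1)
    r2 = np.linalg.norm(d2, axis=1)
    for (d, r, h) in ((d1, r1, h1), (d2, r2, h2)):
        dr = r - p.r0
        E += np.sum(0.5 * p.k_r * dr**2 + p.k_cub * dr**3)
        if want_forces:
            dEdr = p.k_r * dr + 3.0 * p.k_cub * dr**2
            fvec = (dEdr / r)[:, None] * d
            np.add.at(F, h, -fvec)
            np.add.at(F, o, fvec)
    u1 = d1 / r1[:, None]
    u2 = d2 / r2[:, None]
    cos_t = np.clip(np.sum(u1 * u2, axis=1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dth = theta - p.theta0
    E += np.sum(0.5 * p.k_theta * dth**2)
    if want_forces:
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        dEdth = p.k_theta * dth
        g1 = (cos_t[:, None] * u1 - u2) / (sin_t * r1)[:, None]
        g2 = (cos_t[:, None] * u2 - u1) / (sin_t * r2)[:, None]
        np.add.at(F, h1, -dEdth[:, None] * g1)
        np.add.at(F, h2, -dEdth[:, None] * g2)
        np.add.at(F, o, dEdth[:, None] * (g1 + g2))
    return float(E), F


# ---------------------------------------------------------------------------
# baseline: permanent Coulomb, dispersion

def coulomb_energy_forces(coords, q, ia, ib, p: WaterParams,
                          want_forces=True):
    d = coords[ia] - coords[ib]
    r = np.linalg.norm(d, axis=1)
    interacting = (p.q_h != 0.0 or p.alpha_o > 0.0 or p.c6_oo != 0.0
                   or p.bm_a != 0.0 or p.bm_a_oh != 0.0
                   or p.bm_a_hh != 0.0 or p.c9 != 0.0)
    if interacting and len(r) and r.min() < p.hard_floor:
        raise PotentialError(
            f"atoms closer than the {p.hard_floor} A hard floor"
        )
    qq = COULOMB * q[ia] * q[ib]
    E = float(np.sum(qq / r))
    F = None
    if want_forces:
        F = np.zeros_like(coords)
        fvec = (qq / r**3)[:, None] * d
        np.add.at(F, ia, fvec)
        np.add.at(F, ib, -fvec)
    return E, F


def _tt6(x):
    """Tang-Toennies f6 damping and derivative: f = 1 - e^-x sum x^k/k!.

    Clipped at x=60 where f = 1 to 15 digits; avoids 0*inf overflow.
    """
    x = np.minimum(x, 60.0)
    terms = np.ones_like(x)
    s = np.ones_like(x)
    for k in range(1, 7):
        terms = terms * x / k
        s = s + terms
    ex = np.exp(-x)
    f = 1.0 - ex * s
    df = ex * terms  # e^-x x^6/720, times d x/dr applied by caller
    return f, df


def dispersion_energy_forces(coords, oxy, p: WaterParams, want_forces=True,
                             c6=None):
    c6 = p.c6_oo if c6 is None else c6
    io, jo = np.triu_indices(len(oxy), k=1)
    a, b = oxy[io], oxy[jo]
    d = coords[a] - coords[b]
    r = np.linalg.norm(d, axis=1)
    f, df = _tt6(p.b_disp * r)
    E = float(np.sum(-c6 * f / r**6))
    F = None
    if want_forces:
        F = np.zeros_like(coords)
        dEdr = -c6 * (df * p.b_disp / r**6 - 6.0 * f / r**7)
        fvec = -(dEdr / r)[:, None] * d
        np.add.at(F, a, fvec)
        np.add.at(F, b, -fvec)
    return E, F


# ---------------------------------------------------------------------------
# short-range 2B

def born_mayer_energy_forces(coords, mol_table, p: WaterParams,
                             want_forces=True):
    """Switched Born-Mayer exchange repulsion over all intermolecular atom
    pairs of each molecule pair; the quintic switch acts on the pair's O-O
    distance (as in the fitting basis)."""
    n_mol = mol_table.shape[0]
    mi, mj = np.triu_indices(n_mol, k=1)
    if len(mi) == 0:
        return 0.0, (np.zeros_like(coords) if want_forces else None)
    pref = np.array([[p.bm_a, p.bm_a_oh, p.bm_a_oh],
                     [p.bm_a_oh, p.bm_a_hh, p.bm_a_hh],
                     [p.bm_a_oh, p.bm_a_hh, p.bm_a_hh]])
    d_oo = coords[mol_table[mi, 0]] - coords[mol_table[mj, 0]]
    r_oo = np.linalg.norm(d_oo, axis=1)
    s, ds = switch(r_oo, p.sw2_rin, p.sw2_rout)
    esum = np.zeros(len(mi))
    slot_data = []
    for ai in range(3):
        for bj in range(3):
            a = mol_table[mi, ai]
            b = mol_table[mj, bj]
            d = coords[a] - coords[b]
            r = np.linalg.norm(d, axis=1)
            e = pref[ai, bj] * np.exp(-p.bm_b * r)
            esum += e
            if want_forces:
                slot_data.append((a, b, d, r, e))
    E = float(np.sum(esum * s))
    F = None
    if want_forces:
        F = np.zeros_like(coords)
        for a, b, d, r, e in slot_data:
            dEdr = -p.bm_b * e * s
            fvec = -(dEdr / r)[:, None] * d
            np.add.at(F, a, fvec)
            np.add.at(F, b, -fvec)
        # switch derivative acts along the O-O axis
        dEdr_oo = ds * esum
        fvec = -(dEdr_oo / r_oo)[:, None] * d_oo
        np.add.at(F, mol_table[mi, 0], fvec)
        np.add.at(F, mol_table[mj, 0], -fvec)
    return E, F


# ---------------------------------------------------------------------------
# short-range 3B (Axilrod-Teller-Muto, switched)

def atm_energy_forces(coords, oxy, p: WaterParams, want_forces=True,
                      c9=None):
    c9 = p.c9 if c9 is None else c9
    n = len(oxy)
    E = 0.0
    F = np.zeros_like(coords) if want_forces else None
    if n < 3 or c9 == 0.0:
        return 0.0, F
    triples = np.array(list(combinations(range(n), 3)), dtype=int)
    i1, i2, i3 = oxy[triples[:, 0]], oxy[triples[:, 1]], oxy[triples[:, 2]]
    r1, r2, r3 = coords[i1], coords[i2], coords[i3]
    d12, d13, d23 = r1 - r2, r1 - r3, r2 - r3
    s12 = np.linalg.norm(d12, axis=1)
    s13 = np.linalg.norm(d13, axis=1)
    s23 = np.linalg.norm(d23, axis=1)
    a, b, c = s12**2, s13**2, s23**2
    u, v, w = a + b - c, a + c - b, b + c - a
    P = u * v * w
    abc = a * b * c
    g1 = abc**-1.5
    g2 = abc**-2.5
    E0 = c9 * (g1 + 0.375 * P * g2)
    sw12, dsw12 = switch(s12, p.sw3_rin, p.sw3_rout)
    sw13, dsw13 = switch(s13, p.sw3_rin, p.sw3_rout)
    sw23, dsw23 = switch(s23, p.sw3_rin, p.sw3_rout)
    S = sw12 * sw13 * sw23
    E = float(np.sum(E0 * S))
    if want_forces:
        g3 = abc**-3.5
        # dP/d(a,b,c) with u=a+b-c, v=a+c-b, w=b+c-a
        Pa = v * w + u * w - u * v   # du/da=1, dv/da=1, dw/da=-1
        Pb = v * w - u * w + u * v   # du/db=1, dv/db=-1, dw/db=1
        Pc = -v * w + u * w + u * v  # du/dc=-1, dv/dc=1, dw/dc=1
        dE0da = c9 * (-1.5 * g2 * b * c
                      + 0.375 * (Pa * g2 - 2.5 * P * g3 * b * c))
        dE0db = c9 * (-1.5 * g2 * a * c
                      + 0.375 * (Pb * g2 - 2.5 * P * g3 * a * c))
        dE0dc = c9 * (-1.5 * g2 * a * b
                      + 0.375 * (Pc * g2 - 2.5 * P * g3 * a * b))
        dEdr12 = dE0da * 2.0 * s12 * S + E0 * dsw12 * sw13 * sw23
        dEdr13 = dE0db * 2.0 * s13 * S + E0 * sw12 * dsw13 * sw23
        dEdr23 = dE0dc * 2.0 * s23 * S + E0 * sw12 * sw13 * dsw23
        for (dd, ss, dEdr, ii, jj) in (
            (d12, s12, dEdr12, i1, i2),
            (d13, s13, dEdr13, i1, i3),
            (d23, s23, dEdr23, i2, i3),
        ):
            fvec = -(dEdr / ss)[:, None] * dd
            np.add.at(F, ii, fvec)
            np.add.at(F, jj, -fvec)
    return E, F


# ---------------------------------------------------------------------------
# induction

def _thole_lambdas(r, p: WaterParams):
    """Thole exponential damping factors and radial derivatives.

    s = a r^3 / alpha; lambda3 = 1 - e^-s (charge-dipole and the isotropic
    part), lambda5 = 1 - (1+s) e^-s (the rr^T part).
    """
    s = np.minimum(p.thole_a * r**3 / p.alpha_o, 60.0)
    es = np.exp(-s)
    lam3 = 1.0 - es
    lam5 = 1.0 - (1.0 + s) * es
    dsdr = 3.0 * s / r
    dlam3 = dsdr * es
    dlam5 = dsdr * s * es
    return lam3, lam5, dlam3, dlam5


def _permanent_field(coords, q, oxy, mol_index, p: WaterParams):
    """Damped field of the permanent charges at the O polarizable sites,
    plus the (site, atom) pair arrays needed for the force later."""
    n_o = len(oxy)
    site_mol = mol_index[oxy]
    si, aj = np.meshgrid(np.arange(n_o), np.arange(len(coords)),
                         indexing="ij")
    mask = mol_index[aj] != site_mol[:, None]
    si, aj = si[mask], aj[mask]
    R = coords[oxy[si]] - coords[aj]
    r = np.linalg.norm(R, axis=1)
    lam3, lam5, dlam3, _ = _thole_lambdas(r, p)
    g1 = lam3 / r**3
    field = np.zeros((n_o, 3))
    np.add.at(field, si, (COULOMB * q[aj] * g1)[:, None] * R)
    return field, (si, aj, R, r, g1, dlam3, lam3)


def _dipole_tensor(coords, oxy, p: WaterParams):
    """Dense damped dipole-dipole interaction tensor T (3n x 3n)."""
    n_o = len(oxy)
    T = np.zeros((n_o, 3, n_o, 3))
    io, jo = np.triu_indices(n_o, k=1)
    R = coords[oxy[io]] - coords[oxy[jo]]
    r = np.linalg.norm(R, axis=1)
    lam3, lam5, _, _ = _thole_lambdas(r, p)
    blocks = COULOMB * (
        3.0 * lam5[:, None, None] * R[:, :, None] * R[:, None, :]
        / r[:, None, None] ** 5
        - lam3[:, None, None] * np.eye(3)[None] / r[:, None, None] ** 3
    )
    T[io, :, jo, :] = blocks
    T[jo, :, io, :] = blocks
    return T.reshape(3 * n_o, 3 * n_o)


def induced_dipoles_dense(coords, q, oxy, mol_index, p: WaterParams):
    """Solve the self-consistent dipole equations by a direct dense solve.

    Returns (mu (n_o,3), induction energy, field context for forces).
    Raises :class:`PotentialError` when the polarization response matrix is
    not positive definite (polarization catastrophe).
    """
    field, ctx = _permanent_field(coords, q, oxy, mol_index, p)
    n_o = len(oxy)
    # mu[e*A] = alpha[A^3] * E[e/A^2]; fields here carry the Coulomb
    # prefactor (kcal/mol per e*A), hence the COULOMB/alpha diagonal.
    A = np.eye(3 * n_o) * (COULOMB / p.alpha_o) \
        - _dipole_tensor(coords, oxy, p)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(A)
        raise PotentialError(
            "polarization catastrophe: response matrix has smallest "
            f"eigenvalue {w.min():.3e} <= 0"
        )
    mu = np.linalg.solve(A, field.reshape(-1)).reshape(n_o, 3)
    e_ind = -0.5 * float(np.sum(mu * field))
    return mu, e_ind, ctx


def induction_energy_forces(coords, q, oxy, mol_index, p: WaterParams,
                            want_forces=True):
    if p.alpha_o <= 0 or len(oxy) < 2:
        F = np.zeros_like(coords) if want_forces else None
        return 0.0, F, np.zeros((len(oxy), 3))
    mu, e_ind, ctx = induced_dipoles_dense(coords, q, oxy, mol_index, p)
    if not want_forces:
        return e_ind, None, mu
    F = np.zeros_like(coords)
    # charge-field part: dE = -mu_i . dE0_i
    si, aj, R, r, g1, dlam3, lam3 = ctx
    dg1 = dlam3 / r**3 - 3.0 * lam3 / r**4
    mudotR = np.sum(mu[si] * R, axis=1)
    pref = COULOMB * q[aj]
    fvec = pref[:, None] * (g1[:, None] * mu[si]
                            + (dg1 / r * mudotR)[:, None] * R)
    np.add.at(F, oxy[si], fvec)
    np.add.at(F, aj, -fvec)
    # dipole-dipole part: E contribution -sum_{i<j} mu_i T_ij mu_j
    n_o = len(oxy)
    io, jo = np.triu_indices(n_o, k=1)
    Rd = coords[oxy[io]] - coords[oxy[jo]]
    rd = np.linalg.norm(Rd, axis=1)
    lam3d, lam5d, dlam3d, dlam5d = _thole_lambdas(rd, p)
    Ci = np.sum(mu[io] * Rd, axis=1)
    Cj = np.sum(mu[jo] * Rd, axis=1)
    B = np.sum(mu[io] * mu[jo], axis=1)
    dMdR = COULOMB * (
        (3.0 * lam5d / rd**5)[:, None] * (Cj[:, None] * mu[io]
                                          + Ci[:, None] * mu[jo])
        + ((3.0 * dlam5d * Ci * Cj / rd**6)
           - (15.0 * lam5d * Ci * Cj / rd**7)
           - (dlam3d * B / rd**4)
           + (3.0 * lam3d * B / rd**5))[:, None] * Rd
    )
    np.add.at(F, oxy[io], dMdR)
    np.add.at(F, oxy[jo], -dMdR)
    return e_ind, F, mu


# ---------------------------------------------------------------------------
# assembled cluster evaluation

def cluster_terms(coords, mol_index, elements, p: WaterParams,
                  want_forces=True, fitted2b=None, fitted3b=None):
    """Evaluate all terms; returns (dict of term energies, forces or None).

    Term keys: ``one_body``, ``coulomb``, ``induction``, ``dispersion``,
    ``short2b``, ``short3b``.  ``baseline`` is coulomb+induction+dispersion.
    When ``fitted2b``/``fitted3b`` are given they replace the analytic
    short-range terms.
    """
    coords = np.asarray(coords, dtype=float)
    mol_table = molecule_atom_table(mol_index)
    oxy = mol_table[:, 0]
    q = atom_charges(elements, p)
    ia, ib = intermolecular_pairs(mol_index)

    energies = {}
    F = np.zeros_like(coords) if want_forces else None

    e, f = bonded_energy_forces(coords, mol_table, p, want_forces)
    energies["one_body"] = e
    if want_forces:
        F += f

    if mol_table.shape[0] > 1:
        e, f = coulomb_energy_forces(coords, q, ia, ib, p, want_forces)
        energies["coulomb"] = e
        if want_forces:
            F += f
        e, f, _ = induction_energy_forces(coords, q, oxy, mol_index, p,
                                          want_forces)
        energies["induction"] = e
        if want_forces:
            F += f
        e, f = dispersion_energy_forces(coords, oxy, p, want_forces)
        energies["dispersion"] = e
        if want_forces:
            F += f
        if fitted2b is not None:
            e, f = fitted2b.cluster_energy_forces(coords, mol_table,
                                                  want_forces)
        else:
            e, f = born_mayer_energy_forces(coords, mol_table, p,
                                            want_forces)
        energies["short2b"] = e
        if want_forces:
            F += f
        if fitted3b is not None:
            e, f = fitted3b.cluster_energy_forces(coords, mol_table,
                                                  want_forces)
        else:
            e, f = atm_energy_forces(coords, oxy, p, want_forces)
        energies["short3b"] = e
        if want_forces:
            F += f
    else:
        for k in ("coulomb", "induction", "dispersion", "short2b", "short3b"):
            energies[k] = 0.0

    energies["baseline"] = (energies["coulomb"] + energies["induction"]
                            + energies["dispersion"])
    energies["total"] = (energies["one_body"] + energies["baseline"]
                         + energies["short2b"] + energies["short3b"])
    return energies, F
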