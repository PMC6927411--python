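from dataclasses import replace

import numpy as np
import pytest

from mbwater.config import assemble, reference_monomer
from mbwater.potentials import (
    DistortionSpec,
    PotentialError,
    evaluate_energy,
    evaluate_forces,
    local_minimize,
    make_surrogate_potential,
    make_truth_potential,
    solve_induced_dipoles,
    swap_terms,
)
from mbwater.potentials.cluster import cluster_terms
from mbwater.potentials.params import WaterParams
from mbwater.potentials.switching import switch
from mbwater.synthetic import sample_dimer_set


def test_reference_monomer_energy_is_zero(truth):
    cfg = assemble([reference_monomer()])
    assert abs(evaluate_energy(truth, cfg)) < 1e-12


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        make_truth_potential(replace(WaterParams(), k_r=-1.0))
    with pytest.raises(ValueError):
        make_truth_potential(replace(WaterParams(), sw2_rout=1.0))


def test_long_range_decay(truth):
    """Two molecules at 50 A: the interaction is bounded by the model's
    leading multipole (dipole-dipole, 2 mu^2/r^3 ~ 1.3e-3 kcal/mol with
    this parameter set's 2.35 D dipole) and decays as r^-3."""
    q = truth.params.q_h
    mu = 2 * q * 0.9572 * np.cos(np.deg2rad(104.52) / 2)
    energies = {}
    for r in (50.0, 100.0):
        cfg = assemble([reference_monomer(),
                        reference_monomer() + [0.0, 0.0, r]])
        e = evaluate_energy(truth, cfg)
        bound = 2 * 332.07 * mu**2 / r**3 + 1e-9
        assert abs(e) < bound
        energies[r] = e
    # r^-3 leading decay: doubling r shrinks the energy ~8x
    ratio = abs(energies[50.0] / energies[100.0])
    assert ratio == pytest.approx(8.0, rel=0.1)


def test_h_swap_permutation_invariance(truth, dimers_small):
    for cfg in dimers_small[:5]:
        e0 = evaluate_energy(truth, cfg)
        for mol in range(cfg.n_molecules):
            swapped = cfg.copy()
            a = swapped.molecule_atoms(mol)
            swapped.coords[[a[1], a[2]]] = swapped.coords[[a[2], a[1]]]
            assert evaluate_energy(truth, swapped) == pytest.approx(
                e0, abs=1e-12)


def test_molecule_permutation_invariance(truth, trimers_small):
    cfg = trimers_small[0]
    e0 = evaluate_energy(truth, cfg)
    perm = cfg.subset([2, 0, 1])
    assert evaluate_energy(truth, perm) == pytest.approx(e0, abs=1e-12)


def test_isometry_invariance(truth, compact_hexamer):
    cfg = compact_hexamer
    e0 = evaluate_energy(truth, cfg)
    rng = np.random.default_rng(3)
    from mbwater.config import random_rotation_matrix

    R = random_rotation_matrix(rng)
    moved = cfg.copy()
    moved.coords = cfg.coords @ R.T + np.array([5.0, -3.0, 1.0])
    assert evaluate_energy(truth, moved) == pytest.approx(e0, abs=1e-10)


def test_term_sum_oracle(truth, dimers_small):
    """Total dimer energy equals an independent term-by-term hand summation
    (Coulomb + induction + damped dispersion + switched repulsion + 1B)."""
    from mbwater.constants import COULOMB
    from mbwater.potentials.cluster import _tt6

    cfg = min(dimers_small, key=lambda c: np.linalg.norm(
        c.coords[3] - c.coords[0]))
    p = truth.params
    q = np.array([p.q_o, p.q_h, p.q_h] * 2)
    pref = {(True, True): p.bm_a, (True, False): p.bm_a_oh,
            (False, True): p.bm_a_oh, (False, False): p.bm_a_hh}
    roo = np.linalg.norm(cfg.coords[3] - cfg.coords[0])
    s, _ = switch(roo, p.sw2_rin, p.sw2_rout)
    e_coul = 0.0
    e_rep = 0.0
    for a in range(3):
        for b in range(3, 6):
            r = np.linalg.norm(cfg.coords[a] - cfg.coords[b])
            e_coul += COULOMB * q[a] * q[b] / r
            e_rep += pref[(a == 0, b == 3)] * np.exp(-p.bm_b * r) * float(s)
    f6, _ = _tt6(np.array([p.b_disp * roo]))
    e_disp = -p.c6_oo * f6[0] / roo**6
    _, e_ind = solve_induced_dipoles(cfg, p)
    terms, _ = cluster_terms(cfg.coords, cfg.molecule_index, cfg.elements,
                             p, want_forces=False)
    hand = terms["one_body"] + e_coul + e_ind + e_disp + e_rep
    assert evaluate_energy(truth, cfg) == pytest.approx(hand, abs=1e-10)


def test_term_split_is_exact(truth, compact_hexamer):
    terms, _ = truth.energy_terms(compact_hexamer)
    total = (terms["one_body"] + terms["baseline"] + terms["short2b"]
             + terms["short3b"])
    assert terms["total"] == pytest.approx(total, abs=1e-12)


class TestSurrogates:
    def test_zero_distortion_is_identity(self, truth, dimers_small):
        s = make_surrogate_potential(truth, DistortionSpec(0, 0, 0))
        assert s.params == truth.params
        for cfg in dimers_small[:3]:
            assert s.energy(cfg) == pytest.approx(truth.energy(cfg),
                                                  abs=1e-12)

    def test_rep_scaling_raises_compressed_dimer(self, truth):
        s = make_surrogate_potential(truth, DistortionSpec(eps_rep=0.1))
        m1 = reference_monomer()
        m2 = reference_monomer() + [0, 0, 2.5]
        cfg = assemble([m1, m2])
        assert s.energy(cfg) > truth.energy(cfg)

    def test_3b_distortion_leaves_dimers_unchanged(self, truth,
                                                   dimers_small):
        s = make_surrogate_potential(truth, DistortionSpec(eps_3b=0.2))
        for cfg in dimers_small[:5]:
            assert s.energy(cfg) == pytest.approx(truth.energy(cfg),
                                                  abs=1e-12)

    def test_invalid_spec_rejected(self, truth):
        with pytest.raises(ValueError):
            make_surrogate_potential(truth, DistortionSpec(eps_rep=-1.5))


class TestForces:
    def test_net_force_and_torque_vanish(self, truth, compact_hexamer):
        F = evaluate_forces(truth, compact_hexamer)
        assert np.abs(F.sum(axis=0)).max() < 1e-8
        torque = np.cross(compact_hexamer.coords, F).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_forces_match_richardson_central_difference(self, truth,
                                                        compact_hexamer):
        cfg = compact_hexamer.copy()
        rng = np.random.default_rng(11)
        cfg.coords = cfg.coords + rng.normal(scale=0.03,
                                             size=cfg.coords.shape)
        bound = truth.bound(cfg)
        _, F = bound.terms(cfg.coords, want_forces=True)
        h = 1e-4
        for _ in range(8):
            i = int(rng.integers(cfg.n_atoms))
            d = int(rng.integers(3))

            def fd(step):
                cp = cfg.coords.copy()
                cp[i, d] += step
                cm = cfg.coords.copy()
                cm[i, d] -= step
                return -(bound.energy(cp) - bound.energy(cm)) / (2 * step)

            rich = (4.0 * fd(h / 2) - fd(h)) / 3.0
            assert abs(rich - F[i, d]) / max(1.0, abs(rich)) < 1e-6


class TestInduction:
    def test_single_molecule_zero(self, truth):
        cfg = assemble([reference_monomer()])
        mu, e = solve_induced_dipoles(cfg, truth.params)
        assert np.abs(mu).max() == 0.0
        assert e == 0.0

    def test_far_separation_negligible(self, truth):
        cfg = assemble([reference_monomer(),
                        reference_monomer() + [0, 0, 50.0]])
        _, e = solve_induced_dipoles(cfg, truth.params)
        assert abs(e) < 1e-6

    def test_induction_energy_nonpositive(self, truth, dimers_small):
        for cfg in dimers_small[:10]:
            _, e = solve_induced_dipoles(cfg, truth.params)
            assert e <= 0.0

    def test_iterative_periodic_matches_dense_solve(self, truth,
                                                    minimized_dimer):
        """The periodic SCF iteration against the dense linear-system
        oracle, on a dimer in a large box where images are negligible."""
        per = minimized_dimer.copy()
        per.coords = per.coords + 20.0
        per.box_edge = 60.0
        pot = make_truth_potential(replace(truth.params, cutoff=25.0))
        terms, _ = pot.bound(per).terms(per.coords, want_forces=False)
        _, e_dense = solve_induced_dipoles(minimized_dimer, truth.params)
        assert terms["induction"] == pytest.approx(e_dense, abs=1e-7)


class TestSwitching:
    def test_limits_and_continuity(self):
        s, ds = switch(np.array([5.5, 7.5, 5.0, 8.0]), 5.5, 7.5)
        np.testing.assert_allclose(s, [1, 0, 1, 0], atol=1e-15)
        np.testing.assert_allclose(ds, 0, atol=1e-15)
        r = np.array([5.5 - 1e-9, 5.5 + 1e-9, 7.5 - 1e-9, 7.5 + 1e-9])
        s, ds = switch(r, 5.5, 7.5)
        assert abs(s[0] - s[1]) < 1e-8
        assert abs(s[2] - s[3]) < 1e-8
        assert abs(ds[0] - ds[1]) < 1e-8

    def test_energy_smooth_across_switch_radius(self, truth):
        """No jump in energy or force at the 2B switching boundaries; the
        residual is the smooth slope/curvature over the 2e-9 A gap."""
        for r0 in (5.5, 7.5):
            cfgs = [assemble([reference_monomer(),
                              reference_monomer() + [0, 0, r0 + eps]])
                    for eps in (-1e-9, 1e-9)]
            e = [truth.energy(c) for c in cfgs]
            f = [truth.forces(c)[0] for c in cfgs]
            assert abs(e[0] - e[1]) < 1e-8
            assert np.abs(f[0] - f[1]).max() < 1e-8


class TestMinimize:
    def test_descent_and_exit_criterion(self, truth, minimized_dimer):
        assert minimized_dimer.metadata["max_force"] < 1e-5
        # already-minimized input is returned unchanged within tolerance
        again = local_minimize(truth, minimized_dimer, gtol=1e-4)
        assert np.abs(again.coords - minimized_dimer.coords).max() < 1e-3

    def test_energy_decreases(self, truth, minimized_dimer):
        perturbed = minimized_dimer.copy()
        rng = np.random.default_rng(2)
        perturbed.coords = perturbed.coords + rng.normal(
            scale=0.05, size=perturbed.coords.shape)
        e0 = truth.energy(perturbed)
        out = local_minimize(truth, perturbed, gtol=1e-4)
        assert truth.energy(out) <= e0


def test_hard_floor_raises(truth):
    m1 = reference_monomer()
    m2 = reference_monomer() + [0.0, 0.0, 0.1]
    cfg = assemble([m1, m2])
    with pytest.raises(PotentialError):
        truth.energy(cfg)


def test_swap_terms_identity_and_cutoff_check(truth, surrogate,
                                              dimers_small):
    from mbwater.fitting import BasisSpec, FittedTerm, feature_count

    same = swap_terms(truth)
    for cfg in dimers_small[:3]:
        assert same.energy(cfg) == pytest.approx(truth.energy(cfg),
                                                 abs=1e-12)
    bad_spec = BasisSpec(order=2, degree=2, r_in=4.0, r_out=6.0)
    bad = FittedTerm(bad_spec, np.zeros(feature_count(bad_spec)))
    with pytest.raises(ValueError):
        swap_terms(truth, two_body=bad)
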