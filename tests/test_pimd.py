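import numpy as np
import pytest

from mbwater import pimd
from mbwater.constants import KB_MDU, KCAL_TO_MDU


def zero_potential(coords, box):
    return 0.0, np.zeros_like(coords)


class TestNormalModes:
    def test_p1_identity(self):
        assert pimd.normal_mode_matrix(1) == pytest.approx(np.ones((1, 1)))

    @pytest.mark.parametrize("P", [2, 3, 8, 32])
    def test_orthogonality_and_roundtrip(self, P):
        C = pimd.normal_mode_matrix(P)
        np.testing.assert_allclose(C @ C.T, np.eye(P), atol=1e-12)
        rng = np.random.default_rng(P)
        block = rng.normal(size=(P, 5, 3))
        back = pimd.from_normal_modes(pimd.to_normal_modes(block))
        np.testing.assert_allclose(back, block, atol=1e-12)
        # Parseval
        modes = pimd.to_normal_modes(block)
        assert np.sum(modes**2) == pytest.approx(np.sum(block**2),
                                                 abs=1e-10)

    def test_centroid_row(self):
        block = np.arange(8.0).reshape(8, 1, 1)
        modes = pimd.to_normal_modes(block)
        assert modes[0, 0, 0] == pytest.approx(np.sqrt(8) * block.mean())

    def test_frequencies(self):
        f = pimd.normal_mode_frequencies(4, 300.0)
        assert f[0] == 0.0
        assert f[1] == pytest.approx(f[3])
        beta = 1.0 / (KB_MDU * 300.0)
        from mbwater.constants import HBAR_MDU

        w_p = 4 / (beta * HBAR_MDU)
        np.testing.assert_allclose(
            f, 2 * w_p * np.sin(np.pi * np.minimum(np.arange(4),
                                                   4 - np.arange(4)) / 4))


class TestInit:
    def test_beads_at_classical_positions(self, minimized_dimer):
        spec = pimd.SimulationSpec(n_beads=4, seed=1)
        st = pimd.init_ring_polymer(minimized_dimer, spec)
        for s in range(4):
            np.testing.assert_array_equal(st.x[s], minimized_dimer.coords)

    def test_seeded_determinism(self, minimized_dimer):
        spec = pimd.SimulationSpec(n_beads=4, seed=9)
        a = pimd.init_ring_polymer(minimized_dimer, spec)
        b = pimd.init_ring_polymer(minimized_dimer, spec)
        np.testing.assert_array_equal(a.p, b.p)

    def test_momentum_variance(self):
        spec = pimd.SimulationSpec(n_beads=8, seed=3, temperature=200.0)
        masses = np.full(200, 2.5)
        st = pimd.init_ring_polymer(np.zeros((200, 3)), spec, masses=masses)
        var = st.p.var()
        expect = 2.5 * KB_MDU * 200.0 * 8
        assert var == pytest.approx(expect, rel=0.05)

    def test_cutoff_box_validation(self, truth):
        from mbwater.synthetic import build_liquid_box

        box = build_liquid_box(8, 0.997, seed=1)
        spec = pimd.SimulationSpec(n_beads=1, cutoff=50.0)
        with pytest.raises(ValueError):
            pimd.init_ring_polymer(box, spec)


class TestDynamics:
    def test_free_particle_ballistic_and_mode_energy_conservation(self):
        spec = pimd.SimulationSpec(ensemble="nve", n_beads=8, dt=0.2,
                                   seed=3, temperature=100.0)
        st = pimd.init_ring_polymer(np.zeros((1, 3)), spec,
                                    masses=np.array([2.0]),
                                    thermal_spread=True)
        x0 = pimd.to_normal_modes(st.x)[0].copy()
        p0 = pimd.to_normal_modes(st.p)[0].copy()
        h0 = pimd.kinetic_energy(st) + pimd.spring_energy(st, spec)
        for _ in range(200):
            pimd.step(st, zero_potential, spec)
        h1 = pimd.kinetic_energy(st) + pimd.spring_energy(st, spec)
        xc = pimd.to_normal_modes(st.x)[0]
        np.testing.assert_allclose(xc, x0 + 200 * 0.2 * p0 / 2.0,
                                   atol=1e-10)
        assert abs(h1 - h0) / h0 < 1e-10

    def test_p1_reduces_to_classical_velocity_verlet(self):
        k_ho = 0.8  # kcal/mol/A^2
        m = 1.5

        def ho(coords, box):
            return 0.5 * k_ho * np.sum(coords**2), -k_ho * coords

        spec = pimd.SimulationSpec(ensemble="nve", n_beads=1, dt=0.4,
                                   seed=5)
        st = pimd.init_ring_polymer(np.array([[1.0, -0.3, 0.2]]), spec,
                                    masses=np.array([m]))
        x = st.x[0].copy()
        p = st.p[0].copy()
        kmd = k_ho * KCAL_TO_MDU
        for _ in range(300):
            p = p + 0.2 * (-kmd * x)
            x = x + 0.4 * p / m
            p = p + 0.2 * (-kmd * x)
        for _ in range(300):
            pimd.step(st, ho, spec)
        np.testing.assert_allclose(st.x[0], x, atol=1e-12)
        np.testing.assert_allclose(st.p[0], p, atol=1e-12)

    def test_nvt_thermostats_hold_temperature(self, minimized_dimer,
                                              truth):
        spec = pimd.SimulationSpec(ensemble="nvt", n_beads=4, dt=0.2,
                                   n_steps=2000, seed=7, stride=50)
        traj = pimd.run(minimized_dimer, truth, spec)
        t_mean = traj.scalars.temperature_K.iloc[10:].mean()
        assert t_mean == pytest.approx(298.15, rel=0.15)

    def test_run_zero_steps_single_frame(self, minimized_dimer, truth):
        spec = pimd.SimulationSpec(ensemble="nve", n_beads=2, n_steps=0,
                                   seed=1)
        traj = pimd.run(minimized_dimer, truth, spec)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0][0],
                                      minimized_dimer.coords)

    def test_run_reproducible(self, minimized_dimer, truth):
        spec = pimd.SimulationSpec(ensemble="nvt", n_beads=2, dt=0.2,
                                   n_steps=50, seed=11, stride=10)
        a = pimd.run(minimized_dimer, truth, spec)
        b = pimd.run(minimized_dimer, truth, spec)
        np.testing.assert_array_equal(a.frames[-1], b.frames[-1])
        assert a.scalars.equals(b.scalars)


class TestNPT:
    def test_huge_piston_mass_decouples_to_nvt(self):
        from dataclasses import replace

        from mbwater.potentials import make_truth_potential
        from mbwater.potentials.params import WaterParams
        from mbwater.synthetic import build_liquid_box

        box = build_liquid_box(8, 0.6, seed=5)
        truth = make_truth_potential(replace(WaterParams(), cutoff=3.5))
        spec_npt = pimd.SimulationSpec(ensemble="npt", n_beads=1, dt=0.4,
                                       n_steps=40, seed=13, cutoff=3.5,
                                       tau_barostat=1e8, stride=40)
        spec_nvt = pimd.SimulationSpec(ensemble="nvt", n_beads=1, dt=0.4,
                                       n_steps=40, seed=13, cutoff=3.5,
                                       stride=40)
        a = pimd.run(box, truth, spec_npt)
        b = pimd.run(box, truth, spec_nvt)
        assert a.box_edges[-1] == pytest.approx(box.box_edge, rel=1e-9)
        np.testing.assert_allclose(a.frames[-1], b.frames[-1], atol=1e-8)

    def test_ideal_gas_density(self):
        from dataclasses import replace

        from mbwater.constants import ATM_TO_KCAL_A3, KB
        from mbwater.potentials import make_truth_potential
        from mbwater.potentials.params import WaterParams
        from mbwater.synthetic import build_liquid_box

        pot = make_truth_potential(replace(
            WaterParams(), q_h=0.0, alpha_o=0.0, c6_oo=0.0, bm_a=0.0,
            c9=0.0, cutoff=3.0))
        box = build_liquid_box(16, 0.05, seed=2)
        spec = pimd.SimulationSpec(ensemble="npt", temperature=300.0,
                                   pressure=20.0, dt=1.0, n_beads=1,
                                   n_steps=20000, seed=4, stride=20,
                                   cutoff=3.0, tau_thermostat=100.0,
                                   tau_barostat=500.0)
        traj = pimd.run(box, pot, spec)
        sc = traj.scalars.iloc[len(traj.scalars) // 3:]
        v_mean = (sc.box_edge_A**3).mean()
        v_ideal = 16 * KB * 300.0 / (20.0 * ATM_TO_KCAL_A3)
        assert v_mean == pytest.approx(v_ideal, rel=0.10)


def test_estimators_on_static_state(minimized_dimer, truth):
    """A freshly initialized state (beads coincident) has zero spring
    energy, so the primitive estimator equals 3NP/(2 beta)."""
    spec = pimd.SimulationSpec(ensemble="nve", n_beads=4, seed=2)
    st = pimd.init_ring_polymer(minimized_dimer, spec)
    beta = 1.0 / (KB_MDU * spec.temperature)
    expect = 1.5 * 6 * 4 / beta / KCAL_TO_MDU
    assert pimd.primitive_kinetic_estimator(st, spec) == pytest.approx(
        expect)
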