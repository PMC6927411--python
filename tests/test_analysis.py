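import numpy as np
import pytest

from mbwater import pimd
from mbwater.analysis import (
    compute_rdf,
    isomer_relative_energies,
    q_from_directions,
    q_tet,
    q_tet_distribution,
)
from mbwater.config import Configuration, assemble, reference_monomer


def _traj_from_frames(frames, elements, mol_index, box):
    traj = pimd.Trajectory(elements=elements, molecule_index=mol_index,
                          spec=pimd.SimulationSpec())
    for f in frames:
        traj.frames.append(f)
        traj.box_edges.append(box)
    return traj


def _water_cluster_at_oxygens(oxygens, box=None):
    mols = [reference_monomer() + o for o in oxygens]
    cfg = assemble(mols, box_edge=box)
    return cfg


class TestQtet:
    def test_perfect_tetrahedron_is_one(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        assert q_from_directions(tet[None])[0] == pytest.approx(1.0,
                                                                abs=1e-12)
        # through the molecular interface too
        oxy = np.vstack([[0.0, 0, 0], 2.8 * tet / np.sqrt(3)])
        cfg = _water_cluster_at_oxygens(oxy)
        assert q_tet(cfg, 0) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_neighbors_give_minus_three(self):
        col = np.tile([1.0, 0, 0], (4, 1))
        assert q_from_directions(col[None])[0] == pytest.approx(-3.0,
                                                                abs=1e-12)

    def test_random_directions_average_to_zero(self):
        rng = np.random.default_rng(1)
        q = q_from_directions(rng.normal(size=(100000, 4, 3)))
        se = q.std() / np.sqrt(len(q))
        assert abs(q.mean()) < 3 * se + 1e-3

    def test_upper_bound(self):
        rng = np.random.default_rng(2)
        q = q_from_directions(rng.normal(size=(5000, 4, 3)))
        assert q.max() <= 1.0 + 1e-12

    def test_needs_five_molecules(self):
        cfg = _water_cluster_at_oxygens(np.zeros((3, 3))
                                        + np.arange(3)[:, None] * 3.0)
        with pytest.raises(ValueError):
            q_tet(cfg, 0)

    def test_minimum_image_neighbors(self):
        # neighbors across the boundary are closer than in-box ones
        L = 10.0
        oxy = np.array([[0.5, 0.5, 0.5], [9.5, 0.5, 0.5], [0.5, 9.5, 0.5],
                        [0.5, 0.5, 9.5], [9.5, 9.5, 0.5], [5.0, 5.0, 5.0]])
        cfg = _water_cluster_at_oxygens(oxy, box=L)
        # all four nearest neighbors of molecule 0 are wrapped images
        val = q_tet(cfg, 0)
        assert np.isfinite(val) and val <= 1.0


class TestQtetDistribution:
    def test_normalization_and_recount(self, truth):
        from mbwater.synthetic import build_liquid_box

        box = build_liquid_box(8, 0.9, seed=3)
        frames = [box.coords[None].copy() for _ in range(3)]
        traj = _traj_from_frames(frames, box.elements, box.molecule_index,
                                 box.box_edge)
        dist = q_tet_distribution(traj)
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.probabilities * widths) == pytest.approx(
            1.0, abs=1e-10)
        # single-bead trajectory equals an independent per-config recount
        qs = [q_tet(Configuration(box.elements, traj.frames[0][0],
                                  box.molecule_index, box.box_edge), m)
              for m in range(8)]
        hist, _ = np.histogram(np.repeat(qs, 3), bins=dist.bin_edges,
                               density=True)
        np.testing.assert_allclose(dist.probabilities, hist, atol=1e-10)

    def test_tetrahedral_lattice_concentrates_top_bins(self):
        # ice-like: central molecule plus 4 tetrahedral neighbors, replicated
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3)
        oxy = np.vstack([[0.0, 0, 0], 2.75 * tet])
        cfg = _water_cluster_at_oxygens(oxy)
        assert q_tet(cfg, 0) > 0.99

    def test_empty_rejected(self):
        traj = _traj_from_frames([], ["O", "H", "H"], np.zeros(3, int),
                                 None)
        with pytest.raises(ValueError):
            q_tet_distribution(traj)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(5)
        L = 12.0
        n = 60
        frames = []
        for _ in range(40):
            oxy = rng.uniform(0, L, size=(n, 3))
            mols = np.concatenate([reference_monomer() + o for o in oxy])
            frames.append(mols[None])
        elements = ["O", "H", "H"] * n
        traj = _traj_from_frames(frames, elements,
                                 np.repeat(np.arange(n), 3), L)
        rdf = compute_rdf(traj, "OO", bin_width=0.25)
        sel = rdf.r > 1.0
        assert np.abs(rdf.g[sel] - 1.0).max() < 0.35  # ~3 sigma per bin
        assert abs(rdf.g[sel].mean() - 1.0) < 0.02

    def test_two_fixed_atoms_single_bin(self):
        L = 20.0
        d = 3.33
        mols = np.concatenate([reference_monomer(),
                               reference_monomer() + [d, 0, 0]])
        elements = ["O", "H", "H"] * 2
        traj = _traj_from_frames([mols[None]], elements,
                                 np.repeat(np.arange(2), 3), L)
        rdf = compute_rdf(traj, "OO", bin_width=0.05)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert rdf.r[occupied[0]] == pytest.approx(d, abs=0.05)

    def test_pair_count_integral(self):
        rng = np.random.default_rng(6)
        L = 10.0
        n = 40
        frames = []
        for _ in range(20):
            oxy = rng.uniform(0, L, size=(n, 3))
            mols = np.concatenate([reference_monomer() + o for o in oxy])
            frames.append(mols[None])
        traj = _traj_from_frames(frames, ["O", "H", "H"] * n,
                                 np.repeat(np.arange(n), 3), L)
        rdf = compute_rdf(traj, "OO", bin_width=0.1)
        # integrate the ideal-gas-normalized histogram back to pair count
        from mbwater.analysis import _cube_shell_area

        shell = _cube_shell_area(rdf.r, L) * np.diff(rdf.bin_edges)
        pairs = np.sum(rdf.g * shell) / L**3 * (n * (n - 1) / 2)
        expect_frac = np.sum(shell) / L**3  # fraction of MI volume covered
        assert pairs == pytest.approx(n * (n - 1) / 2 * expect_frac,
                                      rel=0.05)

    def test_r_max_validation(self):
        L = 10.0
        mols = np.concatenate([reference_monomer(),
                               reference_monomer() + [3, 0, 0]])
        traj = _traj_from_frames([mols[None]], ["O", "H", "H"] * 2,
                                 np.repeat(np.arange(2), 3), L)
        with pytest.raises(ValueError):
            compute_rdf(traj, "OO", r_max=8.0)


class TestIsomerTable:
    def test_lowest_is_zero_and_deviations(self, truth, surrogate,
                                           minimized_hexamers):
        table = isomer_relative_energies(
            {"truth": truth, "surrogate": surrogate}, minimized_hexamers,
            parent_map={"truth": "surrogate"})
        assert table["truth"].min() == pytest.approx(0.0, abs=1e-12)
        assert table["surrogate"].min() == pytest.approx(0.0, abs=1e-12)
        col = "dev_from_surrogate|truth"
        np.testing.assert_allclose(table[col],
                                   table["truth"] - table["surrogate"])

    def test_unminimized_inputs_flagged(self, truth):
        from mbwater.synthetic import hexamer_templates

        raw = {"prism": hexamer_templates()["prism"]}
        table = isomer_relative_energies({"truth": truth}, raw)
        assert table.attrs["warnings"]

    def test_deviation_matches_mbe_totals(self, truth, surrogate,
                                          minimized_hexamers):
        """Independent oracle: energy differences recomputed by subtracting
        two full many-body decomposition totals."""
        from mbwater import mbe

        cfg = minimized_hexamers["cyclic"]
        dev = surrogate.energy(cfg) - truth.energy(cfg)
        dec_s = mbe.decompose(cfg, surrogate, 6)
        dec_t = mbe.decompose(cfg, truth, 6)
        dev_mbe = (sum(dec_s.order_sums.values())
                   - sum(dec_t.order_sums.values()))
        assert dev == pytest.approx(dev_mbe, abs=1e-10)
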