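"""Composed pipelines: the hexamer term-swapping study and the scaled-down
liquid simulation with structural diagnostics.

These functions chain the synthetic generators, fitting, term swapping,
minimization, path-integral dynamics and structural analysis into the
reproducible end-to-end experiments the analysis scripts and the acceptance
checks drive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import pimd
from .analysis import compute_rdf, isomer_relative_energies, \
    q_from_directions, q_tet_distribution
from .fitting import error_stats, fit_replacement_terms
from .potentials import (
    DistortionSpec,
    local_minimize,
    make_surrogate_potential,
    make_truth_potential,
    swap_terms,
)
from .synthetic import (
    build_liquid_box,
    hexamer_templates,
    label_set,
    sample_dimer_set,
    sample_trimer_set,
)

#: the moderate distortion used for the headline hexamer experiment
DEFAULT_DISTORTION = DistortionSpec(eps_rep=0.05, eps_disp=0.05,
                                    eps_3b=0.10, label="surrogate")


def tetrahedral_reference_values(seed: int, n_random: int = 100_000):
    """The two analytic anchors of the tetrahedral order parameter.

    Returns (q at exact tetrahedral geometry, mean q over ``n_random``
    sets of four uniformly random neighbor directions, standard error).
    """
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                   dtype=float)
    q_perfect = float(q_from_directions(tet[None])[0])
    rng = np.random.default_rng(seed)
    q_rand = q_from_directions(rng.normal(size=(n_random, 4, 3)))
    return q_perfect, float(q_rand.mean()), float(
        q_rand.std() / np.sqrt(n_random))


@dataclass
class HexamerStudy:
    """Outputs of the term-swapping chemical-accuracy experiment."""

    table: pd.DataFrame            # relative energies per potential
    max_abs_deviation: float       # hybrids vs full surrogate, kcal/mol
    fit_rmsd_2b: float
    fit_rmsd_3b: float
    isomers: dict


def hexamer_hybrid_study(seed: int, n_dimers: int = 2000,
                         n_trimers: int = 2000,
                         distortion: DistortionSpec = DEFAULT_DISTORTION,
                         gtol: float = 1e-4) -> HexamerStudy:
    """Fit 2B/3B terms to surrogate labels, build the (2B+3B)/(2B)/(3B)
    hybrids, and compare hexamer-isomer relative energies against the full
    surrogate.

    The isomer templates are locally minimized under the truth potential
    (the geometry-defining level); all potentials are then evaluated at
    those frozen geometries.
    """
    truth = make_truth_potential()
    surrogate = make_surrogate_potential(truth, distortion)
    dimers = sample_dimer_set(n_dimers, (2.2, 8.0), seed=seed)
    trimers = sample_trimer_set(n_trimers, (2.4, 6.5), seed=seed + 1)
    lab2 = label_set(dimers, surrogate, order=2)
    lab3 = label_set(trimers, surrogate, order=3)
    f2, f3 = fit_replacement_terms(truth, lab2, lab3)
    hybrids = {
        "(2B+3B)": swap_terms(truth, two_body=f2, three_body=f3),
        "(2B)": swap_terms(truth, two_body=f2),
        "(3B)": swap_terms(truth, three_body=f3),
    }
    isomers = {name: local_minimize(truth, cfg, gtol=gtol)
               for name, cfg in hexamer_templates().items()}
    pots = {"surrogate": surrogate, **hybrids}
    table = isomer_relative_energies(
        pots, isomers,
        parent_map={name: "surrogate" for name in hybrids})
    dev_cols = [c for c in table.columns if c.startswith("dev_from_")]
    max_dev = float(table[dev_cols].abs().to_numpy().max())
    st2 = error_stats(hybrids["(2B)"], lab2)
    st3 = error_stats(hybrids["(3B)"], lab3)
    return HexamerStudy(
        table=table,
        max_abs_deviation=max_dev,
        fit_rmsd_2b=st2.rmsd,
        fit_rmsd_3b=st3.rmsd,
        isomers=isomers,
    )


@dataclass
class LiquidRun:
    """Outputs of a scaled-down liquid simulation."""

    trajectory: pimd.Trajectory
    mean_temperature: float
    temperature_se: float
    rdf_oo: object
    qtet: object
    g_tail_mean: float   # mean g_OO over the long-range window
    tail_window: tuple


def liquid_sanity_run(seed: int, n_molecules: int = 32, n_beads: int = 8,
                      n_steps: int = 50_000, dt: float = 0.2,
                      temperature: float = 298.15, cutoff: float = 4.5,
                      density: float = 0.997, equil_fraction: float = 0.4,
                      stride: int = 25,
                      tail_window: tuple = (6.0, 6.9)) -> LiquidRun:
    """NVT path-integral run of a small ambient-water box plus structural
    diagnostics (O-O RDF, P(q_tet), temperature statistics).

    The first ``equil_fraction`` of the trajectory is discarded as
    equilibration from the lattice start.
    """
    box = build_liquid_box(n_molecules, density, seed=seed)
    potential = make_truth_potential(
        replace(make_truth_potential().params, cutoff=cutoff))
    spec = pimd.SimulationSpec(
        ensemble="nvt", temperature=temperature, dt=dt, n_beads=n_beads,
        n_steps=n_steps, seed=seed + 10, stride=stride, cutoff=cutoff)
    traj = pimd.run(box, potential, spec)
    n_skip = int(equil_fraction * traj.n_frames)
    prod = pimd.Trajectory(elements=traj.elements,
                           molecule_index=traj.molecule_index, spec=spec)
    prod.frames = traj.frames[n_skip:]
    prod.box_edges = traj.box_edges[n_skip:]
    sc = traj.scalars.iloc[n_skip:]
    t_series = sc.temperature_K.to_numpy()
    blocks = np.array_split(t_series, 10)
    block_means = np.array([b.mean() for b in blocks])
    t_se = float(block_means.std(ddof=1) / np.sqrt(len(blocks)))
    rdf = compute_rdf(prod, "OO", bin_width=0.05)
    qd = q_tet_distribution(prod)
    sel = (rdf.r >= tail_window[0]) & (rdf.r <= tail_window[1])
    g_tail = float(rdf.g[sel].mean())
    traj_out = traj
    return LiquidRun(
        trajectory=traj_out,
        mean_temperature=float(t_series.mean()),
        temperature_se=t_se,
        rdf_oo=rdf,
        qtet=qd,
        g_tail_mean=g_tail,
        tail_window=tail_window,
    )
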