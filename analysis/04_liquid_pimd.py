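#!/usr/bin/env python
"""Short path-integral MD runs of the small ambient-water box.

Desk-scale stand-ins for the production simulations (256 molecules,
32 beads, 1 ns): 32 molecules with a handful of beads for a few
picoseconds, NVT at 298.15 K, under the truth potential and under a
(2B+3B) hybrid fitted to the moderate surrogate.  Trajectory scalars go to
results/; bead-resolved trajectories go to scratch/ (they are bulky and
regenerable).
"""

from dataclasses import replace
from pathlib import Path

from mbwater import pimd
from mbwater.fitting import fit_replacement_terms
from mbwater.io import RunManifest, save_table, write_trajectory_xyz
from mbwater.potentials import (
    make_surrogate_potential,
    make_truth_potential,
    swap_terms,
)
from mbwater.synthetic import (
    build_liquid_box,
    label_set,
    sample_dimer_set,
    sample_trimer_set,
)
from mbwater.workflows import DEFAULT_DISTORTION

SEED = 2024
N_MOLECULES = 32
N_BEADS = 2          # production value is 32; 2 already shows the spread
N_STEPS = 3000       # 0.6 ps at dt = 0.2 fs: a demonstration, not production
CUTOFF = 4.5         # half the 32-molecule box edge is 4.93 A
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def build_hybrid():
    truth = make_truth_potential(
        replace(make_truth_potential().params, cutoff=CUTOFF))
    surrogate = make_surrogate_potential(truth, DEFAULT_DISTORTION)
    dimers = sample_dimer_set(1000, (2.2, 8.0), seed=SEED)
    trimers = sample_trimer_set(1000, (2.4, 6.5), seed=SEED + 1)
    f2, f3 = fit_replacement_terms(
        truth, label_set(dimers, surrogate, order=2),
        label_set(trimers, surrogate, order=3))
    return truth, swap_terms(truth, two_body=f2, three_body=f3)


def main():
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    box = build_liquid_box(N_MOLECULES, 0.997, seed=SEED)
    truth, hybrid = build_hybrid()
    spec = pimd.SimulationSpec(
        ensemble="nvt", temperature=298.15, dt=0.2, n_beads=N_BEADS,
        n_steps=N_STEPS, seed=SEED, stride=25, cutoff=CUTOFF)
    outputs = []
    for tag, pot in (("truth", truth), ("hybrid_2b3b", hybrid)):
        print(f"running {tag}: {N_MOLECULES} molecules, {N_BEADS} beads, "
              f"{N_STEPS * spec.dt / 1000:.1f} ps NVT ...")
        traj = pimd.run(box, pot, spec, progress=True)
        sc = traj.scalars.iloc[traj.n_frames // 3:]
        print(f"  mean T {sc.temperature_K.mean():.1f} K, "
              f"mean V {sc.potential_kcal.mean():.1f} kcal/mol")
        save_table(OUT / f"liquid_scalars_{tag}.tsv", traj.scalars)
        write_trajectory_xyz(SCRATCH / f"liquid_{tag}.xyz", traj, stride=8)
        outputs.append(str(OUT / f"liquid_scalars_{tag}.tsv"))
    RunManifest(command="04_liquid_pimd", seeds={"seed": SEED},
                potential_tags=["truth", "(2B+3B)-surrogate"],
                outputs=outputs).write(OUT / "manifest_04.json")


if __name__ == "__main__":
    main()
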