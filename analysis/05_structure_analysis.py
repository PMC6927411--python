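#!/usr/bin/env python
"""Structural diagnostics of the liquid runs: bead-averaged O-O RDFs and
normalized tetrahedral-order-parameter distributions.

Reads the trajectories written by 04_liquid_pimd.py from scratch/ and
writes plot-ready two-column tables under results/.  The comparison of the
truth and hybrid curves is the desk-scale analog of overlaying structural
observables from reference and surrogate-derived potentials.
"""

from pathlib import Path

import numpy as np

from mbwater.analysis import compute_rdf, q_tet_distribution
from mbwater.io import RunManifest, read_trajectory_xyz, save_table

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
EQUIL_FRACTION = 0.33


def main():
    OUT.mkdir(exist_ok=True)
    outputs = []
    for tag in ("truth", "hybrid_2b3b"):
        path = SCRATCH / f"liquid_{tag}.xyz"
        if not path.exists():
            raise SystemExit(
                f"{path} not found; run analysis/04_liquid_pimd.py first")
        traj = read_trajectory_xyz(path)
        skip = int(EQUIL_FRACTION * traj.n_frames)
        traj.frames = traj.frames[skip:]
        traj.box_edges = traj.box_edges[skip:]
        rdf = compute_rdf(traj, "OO", bin_width=0.05)
        qd = q_tet_distribution(traj)
        save_table(OUT / f"rdf_oo_{tag}.tsv", rdf.to_frame())
        save_table(OUT / f"qtet_{tag}.tsv", qd.to_frame())
        outputs += [str(OUT / f"rdf_oo_{tag}.tsv"),
                    str(OUT / f"qtet_{tag}.tsv")]
        peak_r = rdf.r[np.argmax(rdf.g)]
        qmode = qd.to_frame().loc[lambda d: d.probability.idxmax(),
                                  "q_tet"]
        print(f"{tag:12s}: first O-O peak at {peak_r:.2f} A "
              f"(g={rdf.g.max():.2f}); P(q_tet) mode at q={qmode:.2f}; "
              f"{qd.n_samples} q samples")
    RunManifest(command="05_structure_analysis",
                outputs=outputs).write(OUT / "manifest_05.json")


if __name__ == "__main__":
    main()
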