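#!/usr/bin/env python
"""Generate every synthetic input of the study: dimer/trimer training sets,
the hexamer isomer templates, and an ambient liquid box.

Writes extended-XYZ files under scratch/data/ (bulky and regenerable from
the seed) plus a manifest.  Sizes are desk scale: 2000 dimers and 2000
trimers (the full study's training sets are two orders of magnitude
larger), one 32-molecule box.
"""

from pathlib import Path

from mbwater.io import RunManifest, write_xyz
from mbwater.synthetic import (
    build_liquid_box,
    hexamer_templates,
    sample_dimer_set,
    sample_trimer_set,
)

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    dimers = sample_dimer_set(2000, (2.2, 8.0), seed=SEED)
    write_xyz(OUT / "dimers.xyz", dimers)
    print(f"dimers: {len(dimers)} configurations, O-O uniform in 2.2-8.0 A")

    trimers = sample_trimer_set(2000, (2.4, 6.5), seed=SEED + 1)
    write_xyz(OUT / "trimers.xyz", trimers)
    print(f"trimers: {len(trimers)} configurations, all O-O in 2.4-6.5 A")

    for name, cfg in hexamer_templates().items():
        write_xyz(OUT / f"hexamer_{name}.xyz", cfg, extra={"isomer": name})
    print("hexamer templates: prism, cage, book, cyclic")

    box = build_liquid_box(32, 0.997, seed=SEED + 2)
    write_xyz(OUT / "liquid_box32.xyz", box)
    print(f"liquid box: 32 molecules, edge {box.box_edge:.3f} A "
          f"(0.997 g/cm^3)")

    RunManifest(command="01_generate_inputs", seeds={"seed": SEED},
                outputs=[str(p) for p in sorted(OUT.glob("*.xyz"))]
                ).write(OUT / "manifest_01.json")


if __name__ == "__main__":
    main()
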