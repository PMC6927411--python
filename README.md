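# mbwater

Desk-scale toolkit for dissecting how low-order many-body interactions
shape the structure of liquid water: many-body expansion (MBE) of cluster
energies, fitting of swappable permutation-invariant 2B/3B potential
terms to reference data of differing fidelity, normal-mode path-integral
molecular dynamics (PIMD) of the resulting hybrid potentials, and the
structural diagnostics (radial distribution functions, tetrahedral order
parameter) that reveal the consequences.

## The science

The total energy of `N` water molecules decomposes exactly as

    E_N = Σᵢ E^1B(i) + Σ_{i<j} E^2B(i,j) + Σ_{i<j<k} E^3B(i,j,k) + …

with the n-body terms defined recursively (each subset's energy minus all
lower-order terms of its sub-subsets).  For water this expansion converges
fast — the 2B term carries ~80% of the interaction energy and 3B most of
the rest — so a potential that represents 2B and 3B accurately, with a
classical polarizable baseline for everything higher, can reach the
accuracy of the reference data it was fitted to.

Because high-level quantum reference data are not reproducible at desk
scale, this package ships a synthetic **truth potential** (flexible
monomers, fixed point charges, self-consistent Thole-damped induced
dipoles on the oxygens, damped dispersion, switched Born–Mayer 2B
repulsion and a switched Axilrod–Teller–Muto 3B term) standing in for the
high-level reference, plus **surrogate potentials** that rescale the
short-range repulsion, dispersion and 3B strength to mimic the
rung-dependent error of approximate density functionals.  Swapping fitted
2B and/or 3B terms into the truth baseline produces the (2B+3B)-, (2B)-
and (3B)-hybrid families whose hexamer energetics and liquid structure the
analysis chain compares.

The PIMD engine propagates ring polymers in the normal-mode
representation (exact free-ring-polymer evolution, velocity-Verlet force
kicks, massive Nosé–Hoover chains of four per degree of freedom, optional
isotropic barostat); one bead with no thermostat reduces exactly to
classical MD.  The tetrahedral order parameter

    q_tet = 1 − (3/8) Σ_{j<k≤4} (cos ψ_jk + 1/3)²

is 1 in a perfect tetrahedral environment and averages to 0 over random
ones; its bead-averaged distribution P(q_tet) and the O–O RDF are the
structural observables.

## Worked example

```python
from mbwater import mbe
from mbwater.potentials import make_truth_potential, local_minimize
from mbwater.synthetic import hexamer_templates

pot = make_truth_potential()
hexamer = local_minimize(pot, hexamer_templates()["cage"], gtol=1e-4)
dec = mbe.decompose(hexamer, pot, max_order=6)
for n, s in sorted(dec.order_sums.items()):
    print(n, round(s, 4))
print({k: round(v, 1) for k, v in dec.order_fractions().items()})
```

prints, for the minimized cage-template hexamer,

```
1 1.1197
2 -23.7889
3 -1.9475
4 -0.0713
5 0.0024
6 0.0
{2: 92.2, 3: 7.5, 4: 0.3, 5: -0.0, 6: -0.0}
```

i.e. the 2B term carries 92.2% of the interaction energy and 3B 7.5%,
with everything above 3B essentially negligible — the rapid MBE
convergence that motivates building potentials from fitted low-order
terms.  (Real water is somewhat more cooperative, with 3B near 15–20%;
see the methods note on how this model's induction was tempered.)  The
telescoping residual `dec.reconstruction_error()` is ~1e-14 kcal/mol.

## Analysis chain

Numbered drivers under `analysis/` rerun the study end to end and write
tables under `results/` (bulky regenerable artifacts go to `scratch/`):

1. `01_generate_inputs.py` — dimer/trimer training sets, hexamer
   templates, ambient liquid box.
2. `02_fit_surrogate_terms.py` — fit 2B/3B terms per surrogate rung;
   correlation statistics against truth labels.
3. `03_hexamer_isomers.py` — hexamer isomer relative energies of the
   hybrids vs their parent surrogate (chemical-accuracy test).
4. `04_liquid_pimd.py` — short NVT PIMD runs of the liquid box under the
   truth and a (2B+3B) hybrid potential.
5. `05_structure_analysis.py` — O–O RDFs and P(q_tet) from those runs.
6. `06_mbe_and_cbs.py` — MBE order fractions, stratified mixed-level
   totals, CBS two-point extrapolation and counterpoise arithmetic.

A CLI exposes the same operations (`mbwater generate|fit|decompose|
extrapolate|simulate|analyze|hexamers`).

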