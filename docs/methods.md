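# Methods

This note documents the models, algorithms and numerical choices behind
`mbwater`, in the spirit of a simulation package's model documentation.
Everything quantitative stated here is computed by the test suite or the
analysis scripts; nothing is quoted from external data.

## 1. The truth potential and its surrogates

High-level electronic-structure reference data are not reproducible at
desk scale, so the role of the reference level is played by an analytic
**truth potential** with the same architecture as data-driven many-body
water potentials: a one-body (intramolecular) term, a classical many-body
baseline that contributes at every order of the expansion, and switched
short-range 2B and 3B corrections.

**One-body.** Harmonic O–H stretches with a cubic correction and a
harmonic bend about the gas-phase monomer geometry (r_OH = 0.9572 Å,
HOH = 104.52°).  The reference monomer is the exact minimum with energy
zero, so the in-cluster and isolated-optimized monomer references of the
1B term coincide numerically; both conventions are exposed.  The cubic
coefficient is kept mild (−300 kcal/mol/Å³): a cubic-only truncation has
an unphysical dissociation barrier at Δr = k_r/(3|k₃|), and this value
puts that barrier (~240 kcal/mol at Δr ≈ 1.2 Å) far beyond thermal reach
even at the elevated bead temperatures of path-integral sampling.  (A
steeper, more Morse-like value of ~−1200 puts the barrier at Δr ≈ 0.29 Å
and ~16 kcal/mol, which ring-polymer transients at T_P = P·T can cross.)

**Baseline.** Fixed point charges (q_H = +0.38 e, q_O = −0.76 e; gas
monomer dipole 2.14 D), one isotropic polarizable site per oxygen
(α = 1.1 Å³) solved self-consistently with Thole exponential damping
(a = 0.4, damping length α^{1/3}), and Tang–Toennies-damped C₆
dispersion on O–O pairs (C₆ = 500 kcal/mol Å⁶).  Induction is the main
carrier of ≥3B physics.  These cohesion parameters were deliberately
tempered relative to typical effective water models: stronger settings
(q_H = 0.42, α = 1.4, C₆ = 625) produce a condensed phase that
crystallizes at 298.15 K and 0.997 g/cm³ — a 64-molecule box develops
deep long-range g(r) oscillations — and a stand-in for ambient liquid
water must actually be a liquid at ambient conditions.  With the shipped
values the 64-molecule box diffuses (D ≈ 0.2 Å²/ps) and its O–O RDF
decays to 1 (mean 0.996 over 6.0–6.9 Å).
For clusters the dipole equations are solved by a dense Cholesky solve
(non-positive-definite response ⇒ a polarization-catastrophe error with
the smallest-eigenvalue diagnostic); induction forces use the variational
(Hellmann–Feynman) property of the converged dipoles.

**Short-range 2B.** Born–Mayer exchange walls on *all* intermolecular
atom pairs of a molecule pair — O–O (A = 1.3·10⁵ kcal/mol), O–H (1200)
and H–H (200), common decay b = 4/λ with λ = 1.1 Å — multiplied by a
quintic switch s(x) = 1 − 10x³ + 15x⁴ − 6x⁵ on the pair's O–O distance
(r_in = 5.5 Å, r_out = 7.5 Å).  Two deliberate choices here:

* *O–H and H–H walls.*  With repulsion on O–O only, the cooperative
  polarizable baseline collapses compact clusters into overcoordinated
  blobs (hexamer O–O ≈ 2.5 Å): nothing stops an H sliding onto a
  neighboring O.  The O–H wall is what keeps hydrogen bonds directional;
  with it the four hexamer templates relax to four distinct minima
  spread over ~3.8 kcal/mol.
* *Decay commensurate with the fitting basis.*  b = 4/λ makes every
  Born–Mayer wall exactly representable by the degree-4 exponential
  fitting basis (ξ⁴ = e^{−4r/λ}), so noise-free surrogate 2B labels can
  be fitted essentially exactly and the hexamer experiment isolates the
  3B approximation error.  b = 3.64 Å⁻¹ is also simply a physically
  sensible wall steepness.

**Short-range 3B.** An Axilrod–Teller–Muto triple-dipole term on oxygen
triples (C₉ = 250 kcal/mol Å⁹) times the product of pair switches
(r_in = 2.5 Å, r_out = 4.5 Å).  Because induction carries most of the 3B
energy, this explicit term is a small correction; surrogate distortions
of it are correspondingly mild (see §6, limitations).

**Surrogates.** A `DistortionSpec` rescales the Born–Mayer prefactors by
(1+eps_rep), C₆ by (1+eps_disp) and C₉ by (1+eps_3b), leaving
electrostatics, induction and the 1B term untouched — a controllable
caricature of rung-dependent functional error.  Four named settings
(`gga`, `meta-gga`, `hybrid`, `rsh`) reproduce the qualitative ordering
seen across functional rungs for water, including a meta-GGA that
outperforms the hybrid and a range-separated hybrid that is excellent at
2B but keeps a 3B-level error.  The headline experiments use the moderate
(0.05, 0.05, 0.10) distortion.

**Periodic evaluation.** Permanent electrostatics use a standard Ewald
sum (real-space screening κ = 3.2/r_c, reciprocal cutoff from a slightly
looser accuracy parameter 2.8 — validated against the rocksalt Madelung
constant to ~5·10⁻⁶ relative).  Dispersion, the repulsion walls, the 3B
term and the induction tensors are minimum-image truncated at the cutoff
with a 1 Å quintic taper; long-range induction beyond the cutoff is
neglected.  No dispersion tail corrections.  The self-consistent dipoles
are iterated with 0.65 mixing to 10⁻⁹, warm-started along trajectories by
linear extrapolation from the two previous solutions.  The hot loops are
numba-compiled.

## 2. Many-body expansion

`mbe` enumerates subsets, evaluates frozen-geometry sub-cluster energies,
and forms n-body terms either by the recursive definition or by the
Möbius (alternating-sum) closed form; both are implemented and agree to
round-off.  The telescoping identity (order sums reconstruct the total
energy) holds to <10⁻¹⁰ kcal/mol for any potential in the package; a
strictly pairwise parameterization (no induction, no 3B term) has all
≥3B terms at round-off, which is the sharpest internal consistency check
of the machinery.  Full-order decompositions refuse N > 12 molecules
(2^N subsets) unless forced.  `samba_energy` assembles a stratified total
from order-resolved sums computed at different levels (e.g. orders 1–3 at
the truth level, >3B at a surrogate), reusing one decomposition per
distinct level.

## 3. Fitting and term swapping

The fitting basis consists of monomials (total degree ≤ 4 at 2B, ≤ 2 at
3B) in the exponential variables ξ_ab = e^{−r_ab/λ} over all
intermolecular atom pairs (9 for a dimer, 27 for a trimer), symmetrized
by explicit orbit averaging over the full permutation group (H swaps and
molecule exchange; 8 elements for dimers, 48 for trimers) and multiplied
by the order's switching function.  Orbit averaging was chosen over
invariant-monomial generation because it is trivially auditable at these
group sizes; the orbit counts (129 features at 2B, 27 at 3B) are verified
against an independent Burnside-lemma count in the tests.  Fits are
deterministic ridge-regularized least squares on norm-scaled columns
(default ridge 10⁻⁸; ridge 0 with a rank-deficient design raises an
error instructing a nonzero ridge).

What a swapped-in short-range term must represent is the part of the
reference n-body energy not already carried by the base potential's
baseline; `fit_replacement_terms` subtracts the baseline's n-body
contribution (base potential with its short-range term removed) before
fitting.  `swap_terms` then replaces the 2B and/or 3B term of the base,
after checking that the fitted term's switching radii match the base —
everything else is taken from the base, producing the (2B+3B)/(2B)/(3B)
hybrid families.

Residual scales observed in the shipped experiment (moderate surrogate,
2000+2000 noise-free training points): 2B fit RMSD ~1.3·10⁻⁴ kcal/mol
(the Born–Mayer part is in-basis; the small residual is the distorted
dispersion shape), 3B fit RMSD ~1.4·10⁻⁴ kcal/mol (the ATM shape is
genuinely out of basis).

## 4. Path-integral molecular dynamics

The engine samples the ring-polymer Hamiltonian H_P = Σ p²/2m +
Σ (m/2) ω_P² (x_s − x_{s+1})² + Σ V(x_s) at the elevated temperature
T_P = P·T (ω_P = P/βħ), the convention in which all thermostats target
k_B T_P and the free-ring-polymer mode frequencies are
ω_k = 2/(β_P ħ) sin(kπ/P).  Integration is the standard splitting: half
thermostat, half force kick, exact normal-mode evolution of the free ring
polymer over dt, half kick, half thermostat.  All normal-mode masses are
the physical masses.  With P = 1 and no thermostat the stepper reproduces
a classical velocity-Verlet reference bit-for-bit.

*Thermostats.*  One Nosé–Hoover chain of four per Cartesian degree of
freedom of every normal mode ("massive" NHC), integrated with a
three-term Suzuki–Yoshida cycle.  Thermostat masses Q = k_B T_P τ²
with τ = 50 fs for the centroid mode and τ_k = 1/ω_k for internal modes.

*Barostat.*  Isotropic Martyna–Tobias–Klein-type coupling to the centroid
mode only: piston mass W = 3(N+1) k_B T_P τ_p² (τ_p = 500 fs default),
its own four-link chain, and the extended-system pressure balance
P_int = P·P_ext appropriate to the T_P sampling convention (the physical
instantaneous pressure reported is P_int/P).  The potential part of the
virial is obtained from a central-difference volume derivative of the
bead-summed potential (δ ln V = 10⁻⁶) under centroid scaling — robust for
arbitrary potentials at the cost of two extra energy evaluations per
step.  Validated against the ideal-gas equation of state and the
infinite-piston-mass NVT decoupling limit.

*Estimators.*  Primitive kinetic estimator 3NP/2β − E_spring/P and
centroid-virial estimator 3N/2β − (1/2P) Σ (x_s − x̄)·F_s.  For a 1D
harmonic oscillator at finite P both have the closed-form expectation
Σ_k ω²/(ω_k²+ω²)/(2β) per dimension, derived from the Gaussian mode
covariances; the NVT tests check both estimators against it (and against
the classical value they must *not* match).

*Degrees of freedom.*  The temperature estimator counts all 3NP bead
degrees of freedom (each carries k_B T_P/2); net-momentum subtraction is
not applied since every mode is individually thermostatted.

## 5. Structural analysis

`q_tet` uses the four nearest oxygen neighbors (minimum image when
periodic; ties broken by molecule index via stable sort).  Analytic
anchors: q = 1 at exact tetrahedral directions, mean 0 over uniformly
random directions (E[(cos ψ + 1/3)²] = 4/9 makes the expectation vanish
identically), q = −3 in the degenerate all-collinear limit, and q ≤ 1
always.  P(q_tet) is histogrammed over every molecule, frame and bead and
normalized to unit integral (default bin 0.02).

RDFs are same-bead pair histograms (the standard path-integral estimator
for static pair correlations; cross-bead pairs are excluded), averaged
over beads and frames, and normalized by the *exact minimum-image
ideal-gas shell measure of a cubic box*: 4πr² for r ≤ L/2 and
4πr² − 12πr(r − L/2) for L/2 < r < L/√2 (spherical caps cut by the six
faces; the caps start overlapping only at L/√2).  This extends the valid
range of g(r) from L/2 to L/√2 — for the 32-molecule ambient box
(L = 9.87 Å) that is 6.98 Å, which is what makes the long-range window
6.0–6.9 Å measurable at all.  The ideal-gas flatness test doubles as a
validation of this normalization.

`isomer_relative_energies` evaluates each named potential at shared
frozen geometries (minimized under a designated geometry-defining
potential — the truth level in the shipped experiments), shifts each
column so its lowest isomer is zero, and reports per-hybrid deviations
from a parent potential.  Geometries whose maximum force exceeds a
tolerance are flagged in the table metadata rather than rejected.

## 6. Synthetic data: what it emulates and what it does not

Dimer/trimer training sets are uniform in O–O separation and uniform on
the rotation group, with Gaussian intramolecular distortions
(σ = 0.02 Å / 2°) and a 1.2 Å contact-rejection floor; liquid boxes are
jittered lattices with random orientations packed greedily to a 1.5 Å
contact floor at 0.997 g/cm³.  The hexamer templates are geometric
idealizations of the prism, cage, book and cyclic motifs (the book fold
is 120°, chosen so the template relaxes into a bound compact minimum
rather than fragmenting), intended only as minimization starting points.
None of this emulates Boltzmann- or dynamics-derived sampling of real
training sets, and the truth potential is *not* a fit to real water —
passing tests demonstrate the correctness and internal consistency of
the machinery (expansion, fitting, swapping, sampling, estimators), not
agreement with experimental water properties.  Two caveats specific to
this model: its tempered induction makes the hexamer 3B fraction ~8% of
the interaction energy (real water sits nearer 15–20%), and eps_3b
distortions therefore produce much smaller 3B label changes
(~10⁻³ kcal/mol RMSD) than eps_rep/eps_disp produce at 2B (~0.06–0.75
kcal/mol across the shipped rungs).

## 7. Problem sizes and numerical tolerances

Desk-scale defaults chosen for the shipped experiments: 2000 dimers /
2000 trimers per training set; hexamers minimized to max |F| < 10⁻⁴
kcal/mol/Å (L-BFGS-B with analytic gradients, up to five restarts;
~10⁻⁵ is the practical floor set by energy round-off in the summed
terms); the liquid sanity run uses 32 molecules, 8 beads, 10 ps at
dt = 0.2 fs and a 4.5 Å cutoff (half the box edge), discarding the first
40% as equilibration from the lattice start.  Self-consistent dipoles:
10⁻⁹ max-component tolerance (periodic iteration) or direct solve
(clusters).  Ring-polymer NVE conservation: bounded O(dt²) oscillation
~10⁻³ relative at dt = 0.2 fs with secular drift (half-window mean
difference) below 10⁻⁵ over 10⁴ steps.  Force-consistency checks use
Richardson-extrapolated central differences because the plain h = 10⁻⁴
stencil's truncation error (h²/6·E''' ≈ 10⁻⁵ from the cubic stretch
term) exceeds the 10⁻⁶ comparison threshold.

## 8. Known limitations

* The truth model's parameters are defined, not fitted; its liquid is
  water-like but not water.
* In the 32-molecule box the RDF window beyond L/2 (6.0–6.9 Å), though
  correctly normalized, samples only near-corner minimum-image
  directions where pairs sit close to two nearly equidistant periodic
  images; for a liquid with a structured first shell the measured g
  there is genuinely enhanced by ~10% over the large-box value.  Long-
  range g(r) statements should be read from the 64-molecule geometry.
* Long-range induction and dispersion beyond the cutoff are neglected;
  periodic electrostatics are Ewald but induction is minimum-image only.
* The barostat virial is a numerical volume derivative (two extra energy
  evaluations per NPT step) rather than an analytic per-term virial.
* Fitted (swapped) terms are evaluated in periodic systems by explicit
  molecule-pair/triple enumeration in numpy — fine for short
  demonstration runs, not tuned for production trajectories.
* Ring-polymer contraction, multiple time stepping and other PIMD
  accelerations are out of scope; production-scale settings (256
  molecules, 32 beads, 1 ns) are supported by the interfaces but not by
  the desk-scale runtime budget.
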