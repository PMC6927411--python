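"""Parameter tables for the truth potential and its distorted surrogates.

The "truth" model plays the role of a high-level reference: a flexible-water
potential built from classical many-body electrostatics (fixed point charges
plus one self-consistently polarizable site per oxygen), Tang-Toennies-damped
O-O dispersion, a switched Born-Mayer 2B repulsion and a switched
Axilrod-Teller-Muto 3B term.  The default numbers below define that model;
they are physically plausible for water but are *not* a fit to real water.

Surrogates emulate lower-fidelity reference data (the rung-dependent error of
approximate exchange-correlation functionals) by fractionally rescaling the
short-range repulsion, the dispersion coefficient and the 3B term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: length scale (A) of the exponential variables used by the fitting basis;
#: the truth repulsion decay is chosen commensurate with it (see docs).
BASIS_LAMBDA = 1.1


@dataclass(frozen=True)
class WaterParams:
    """Full parameter table of a many-body water potential."""

    # one-body (intramolecular): harmonic + cubic stretch, harmonic bend
    k_r: float = 1059.162        # kcal/mol/A^2
    r0: float = 0.9572           # A
    # cubic stretch correction: kept mild so the cubic-only truncation's
    # unphysical dissociation barrier sits far above thermal reach
    k_cub: float = -300.0        # kcal/mol/A^3
    k_theta: float = 75.90       # kcal/mol/rad^2
    theta0: float = np.deg2rad(104.52)

    # permanent electrostatics
    q_h: float = 0.38            # e; q_o = -2 q_h (neutral molecules)

    # induction: one isotropic polarizable site per O, Thole-damped
    alpha_o: float = 1.1         # A^3
    thole_a: float = 0.4         # dimensionless damping strength

    # damped dispersion on O-O
    c6_oo: float = 500.0         # kcal/mol A^6
    b_disp: float = 4.0 / BASIS_LAMBDA  # A^-1, Tang-Toennies damping

    # short-range 2B: Born-Mayer exchange repulsion on all intermolecular
    # atom pairs (O-O, O-H, H-H prefactors; common decay), switched by the
    # molecule pair's O-O distance.  The O-H wall is what keeps hydrogen
    # bonds directional and prevents overcoordinated collapse.
    bm_a: float = 130000.0       # kcal/mol, O-O
    bm_a_oh: float = 1200.0      # kcal/mol, O-H
    bm_a_hh: float = 200.0       # kcal/mol, H-H
    bm_b: float = 4.0 / BASIS_LAMBDA  # A^-1
    sw2_rin: float = 5.5         # A
    sw2_rout: float = 7.5        # A

    # short-range 3B: Axilrod-Teller-Muto times product of pair switches
    c9: float = 250.0            # kcal/mol A^9
    sw3_rin: float = 2.5         # A
    sw3_rout: float = 4.5        # A

    # numerics
    hard_floor: float = 0.3      # A; the potential is undefined below this
    cutoff: float = 9.0          # A, periodic real-space cutoff

    @property
    def q_o(self) -> float:
        return -2.0 * self.q_h

    def validate(self) -> None:
        if self.k_r <= 0 or self.k_theta <= 0:
            raise ValueError("force constants must be positive")
        if self.sw2_rout <= self.sw2_rin or self.sw3_rout <= self.sw3_rin:
            raise ValueError("switch outer radius must exceed inner radius")
        if self.cutoff <= 0 or self.hard_floor <= 0:
            raise ValueError("cutoff and hard_floor must be positive")
        if self.alpha_o < 0:
            raise ValueError("polarizability must be non-negative")


@dataclass(frozen=True)
class DistortionSpec:
    """Fractional rescalings emulating functional-rung error.

    ``eps_rep`` scales the Born-Mayer 2B repulsion, ``eps_disp`` the O-O
    dispersion coefficient and ``eps_3b`` the 3B term; all must stay > -1 so
    no term flips sign.
    """

    eps_rep: float = 0.0
    eps_disp: float = 0.0
    eps_3b: float = 0.0
    label: str = "surrogate"

    def validate(self) -> None:
        for name in ("eps_rep", "eps_disp", "eps_3b"):
            if getattr(self, name) <= -1.0:
                raise ValueError(f"{name} must be > -1")

    def scaled(self, factor: float) -> "DistortionSpec":
        return replace(
            self,
            eps_rep=self.eps_rep * factor,
            eps_disp=self.eps_disp * factor,
            eps_3b=self.eps_3b * factor,
            label=f"{self.label}-x{factor:g}",
        )


def default_truth_params() -> WaterParams:
    """The named default parameter set defining the truth model."""
    return WaterParams()


#: Surrogate distortions loosely mimicking the accuracy ordering of the four
#: functional rungs studied for water: a GGA (largest 2B/3B errors), a
#: meta-GGA that outperforms the hybrid below it, a hybrid, and a
#: range-separated hybrid that is excellent at 2B but keeps a 3B error.
RUNG_SURROGATES = {
    "gga": DistortionSpec(0.12, 0.15, 0.30, label="gga"),
    "meta-gga": DistortionSpec(0.03, 0.04, 0.10, label="meta-gga"),
    "hybrid": DistortionSpec(0.06, 0.08, 0.15, label="hybrid"),
    "rsh": DistortionSpec(0.01, 0.015, 0.12, label="rsh"),
}
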