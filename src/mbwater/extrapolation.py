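"""Complete-basis-set extrapolation and counterpoise arithmetic.

Pure operations on caller-supplied energies: the inverse-cubic two-point CBS
formula for correlation-consistent basis series, and the counterpoise
correction assembled from monomer energies computed in the full cluster
basis versus their own basis.  Units pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BasisSeriesPoint:
    """One point of a basis-set series: cardinal number X and energy E_X."""

    cardinal: int
    energy: float

    def __post_init__(self):
        if self.cardinal < 2:
            raise ValueError("cardinal number must be >= 2")


def cbs_two_point(point_lo: BasisSeriesPoint,
                  point_hi: BasisSeriesPoint) -> float:
    """Two-point inverse-cubic CBS extrapolation.

    E_CBS = (X_hi^3 E_hi - X_lo^3 E_lo) / (X_hi^3 - X_lo^3); exact for any
    series of the form E_X = E_CBS + A X^-3 (e.g. cardinals 3 and 4).
    """
    xl, xh = point_lo.cardinal, point_hi.cardinal
    if xh <= xl:
        raise ValueError("high-cardinal point must have the larger cardinal")
    return (xh**3 * point_hi.energy - xl**3 * point_lo.energy) / (xh**3 - xl**3)


def counterpoise_interaction(e_complex_full_basis: float,
                             monomers_in_full_basis,
                             monomers_in_own_basis):
    """Counterpoise-corrected interaction energy and BSSE estimate.

    corrected = E_complex - sum(monomers in the full cluster basis);
    BSSE = sum(full-basis monomer - own-basis monomer), which is <= 0 for
    variational methods (the larger basis lowers each monomer energy).
    """
    full = np.asarray(monomers_in_full_basis, dtype=float)
    own = np.asarray(monomers_in_own_basis, dtype=float)
    if full.shape != own.shape:
        raise ValueError("one full-basis and one own-basis energy per monomer")
    corrected = e_complex_full_basis - full.sum()
    bsse = float((full - own).sum())
    return corrected, bsse
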