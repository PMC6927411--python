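"""Potential objects: truth model, distorted surrogates and term-swapped
hybrids, with a uniform energy/force interface for clusters and periodic
boxes.

A :class:`Potential` is a stack of four terms (one-body, classical many-body
baseline, switched short-range 2B, switched short-range 3B).  ``swap_terms``
replaces the analytic short-range terms by fitted ones while keeping all
other terms from the base model, producing the (2B+3B)/(2B)/(3B) hybrid
families.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from ..config import Configuration
from .cluster import PotentialError, cluster_terms, induced_dipoles_dense, \
    atom_charges, molecule_atom_table
from .params import DistortionSpec, WaterParams, default_truth_params

__all__ = [
    "Potential", "PotentialError", "make_truth_potential",
    "make_surrogate_potential", "swap_terms", "evaluate_energy",
    "evaluate_forces", "solve_induced_dipoles", "local_minimize",
]


@dataclass
class Potential:
    """A many-body water potential with swappable short-range terms."""

    params: WaterParams
    level_tag: str = "truth"
    fitted2b: object | None = None
    fitted3b: object | None = None

    # -- evaluation ------------------------------------------------------
    def energy_terms(self, config: Configuration,
                     want_forces: bool = False):
        """Per-term energies (kcal/mol) and optionally forces."""
        if config.box_edge is None:
            return cluster_terms(
                config.coords, config.molecule_index, config.elements,
                self.params, want_forces=want_forces,
                fitted2b=self.fitted2b, fitted3b=self.fitted3b,
            )
        return self.bound(config).terms(config.coords, want_forces)

    def energy(self, config: Configuration) -> float:
        terms, _ = self.energy_terms(config, want_forces=False)
        return terms["total"]

    def forces(self, config: Configuration) -> np.ndarray:
        _, F = self.energy_terms(config, want_forces=True)
        return F

    def bound(self, config: Configuration) -> "BoundPotential":
        """Bind topology (and periodic machinery) for repeated evaluation."""
        return BoundPotential(self, config)

    # -- metadata --------------------------------------------------------
    def with_tag(self, tag: str) -> "Potential":
        return _dc_replace(self, level_tag=tag)


class BoundPotential:
    """Topology-bound evaluator; the engine-facing force provider.

    Keeps per-key induced-dipole warm starts for periodic evaluations so the
    self-consistent solve converges in a few sweeps along a trajectory.
    """

    def __init__(self, potential: Potential, config: Configuration):
        self.potential = potential
        self.elements = list(config.elements)
        self.mol_index = config.molecule_index.copy()
        self.periodic = config.box_edge is not None
        self.box_edge = config.box_edge
        self._mu_cache: dict = {}
        if self.periodic:
            from . import periodic as _periodic
            self._ctx = _periodic.PeriodicContext(
                self.elements, self.mol_index, potential.params,
                fitted2b=potential.fitted2b, fitted3b=potential.fitted3b,
            )

    def terms(self, coords, want_forces=True, box_edge=None, key=0):
        if not self.periodic:
            return cluster_terms(
                coords, self.mol_index, self.elements,
                self.potential.params, want_forces=want_forces,
                fitted2b=self.potential.fitted2b,
                fitted3b=self.potential.fitted3b,
            )
        if box_edge is None:
            box_edge = self.box_edge
        hist = self._mu_cache.get(key)
        if hist is None:
            mu0 = None
        elif len(hist) == 2:
            # linear predictor from the two previous solutions cuts the
            # number of self-consistency sweeps roughly in half
            mu0 = 2.0 * hist[-1] - hist[-2]
        else:
            mu0 = hist[-1].copy()
        terms, F, mu = self._ctx.terms(coords, box_edge, want_forces, mu0)
        self._mu_cache[key] = ((hist[-1], mu) if hist else (mu,))
        return terms, F

    def energy_forces(self, coords, box_edge=None, key=0):
        terms, F = self.terms(coords, want_forces=True, box_edge=box_edge,
                              key=key)
        return terms["total"], F

    def energy(self, coords, box_edge=None, key=0):
        terms, _ = self.terms(coords, want_forces=False, box_edge=box_edge,
                              key=key)
        return terms["total"]


# ---------------------------------------------------------------------------
# constructors

def make_truth_potential(params: WaterParams | None = None) -> Potential:
    """The reference ("truth") potential standing in for high-level data."""
    p = params if params is not None else default_truth_params()
    p.validate()
    return Potential(params=p, level_tag="truth")


def make_surrogate_potential(truth: Potential,
                             spec: DistortionSpec) -> Potential:
    """Distort ``truth``: scale 2B repulsion, dispersion C6 and the 3B term
    by (1+eps); electrostatics, induction and the 1B term are unchanged."""
    spec.validate()
    p = truth.params
    new = _dc_replace(
        p,
        bm_a=p.bm_a * (1.0 + spec.eps_rep),
        bm_a_oh=p.bm_a_oh * (1.0 + spec.eps_rep),
        bm_a_hh=p.bm_a_hh * (1.0 + spec.eps_rep),
        c6_oo=p.c6_oo * (1.0 + spec.eps_disp),
        c9=p.c9 * (1.0 + spec.eps_3b),
    )
    return Potential(params=new, level_tag=spec.label,
                     fitted2b=truth.fitted2b, fitted3b=truth.fitted3b)


def swap_terms(base: Potential, two_body=None, three_body=None) -> Potential:
    """Replace the short-range 2B and/or 3B term of ``base`` by fitted terms;
    all other terms are taken from ``base``."""
    p = base.params
    if two_body is not None:
        if two_body.order != 2:
            raise ValueError("two_body term must have order 2")
        if not np.allclose([two_body.spec.r_in, two_body.spec.r_out],
                           [p.sw2_rin, p.sw2_rout]):
            raise ValueError(
                "2B switching radii of the fitted term do not match the base"
            )
    if three_body is not None:
        if three_body.order != 3:
            raise ValueError("three_body term must have order 3")
        if not np.allclose([three_body.spec.r_in, three_body.spec.r_out],
                           [p.sw3_rin, p.sw3_rout]):
            raise ValueError(
                "3B switching radii of the fitted term do not match the base"
            )
    parts = []
    if two_body is not None:
        parts.append("2B")
    if three_body is not None:
        parts.append("3B")
    tag = base.level_tag if not parts else (
        f"({'+'.join(parts)})-{_fit_source(two_body, three_body)}"
    )
    return Potential(
        params=p,
        level_tag=tag,
        fitted2b=two_body if two_body is not None else base.fitted2b,
        fitted3b=three_body if three_body is not None else base.fitted3b,
    )


def _fit_source(two_body, three_body):
    for t in (two_body, three_body):
        if t is not None and getattr(t, "source_tag", None):
            return t.source_tag
    return "fit"


# ---------------------------------------------------------------------------
# module-level operations

def evaluate_energy(potential: Potential, config: Configuration) -> float:
    return potential.energy(config)


def evaluate_forces(potential: Potential,
                    config: Configuration) -> np.ndarray:
    return potential.forces(config)


def solve_induced_dipoles(config: Configuration,
                          params: WaterParams | None = None):
    """Self-consistent induced dipoles (e*A) and induction energy (kcal/mol)
    for a cluster geometry."""
    p = params if params is not None else default_truth_params()
    mol_index = config.molecule_index
    oxy = molecule_atom_table(mol_index)[:, 0]
    if p.alpha_o <= 0 or len(oxy) < 2:
        return np.zeros((len(oxy), 3)), 0.0
    q = atom_charges(config.elements, p)
    mu, e_ind, _ = induced_dipoles_dense(config.coords, q, oxy, mol_index, p)
    return mu, e_ind


def local_minimize(potential: Potential, config: Configuration,
                   gtol: float = 1e-4, maxiter: int = 5000) -> Configuration:
    """Locally minimize a cluster; returns a configuration whose largest
    force component is below ``gtol`` (kcal/mol/A)."""
    if config.box_edge is not None:
        raise ValueError("local_minimize operates on clusters")
    bound = potential.bound(config)
    shape = config.coords.shape

    x0 = config.coords.ravel().copy()

    def fun(x):
        # outside the physically meaningful region, present a steep basin
        # pulling back toward the start so line searches recover
        try:
            terms, F = bound.terms(x.reshape(shape), want_forces=True)
            e = terms["total"]
            if np.isfinite(e) and np.all(np.isfinite(F)):
                return e, -F.ravel()
        except PotentialError:
            pass
        d = x - x0
        return 1e10 + 0.5 * float(d @ d), d

    e0 = bound.energy(config.coords)
    x = config.coords.ravel()
    best_x, best_g = None, np.inf
    for _ in range(5):  # restarts flush a stale L-BFGS Hessian estimate
        res = _scipy_minimize(fun, x, jac=True, method="L-BFGS-B",
                              options={"maxiter": maxiter, "ftol": 0.0,
                                       "gtol": 1e-2 * gtol, "maxls": 60})
        x = res.x
        _, F = bound.terms(x.reshape(shape), want_forces=True)
        g = float(np.abs(F).max())
        improved = g < best_g
        if improved:
            best_x, best_g = x.copy(), g
        if best_g < gtol or not improved:
            break
    if best_g >= gtol:
        raise PotentialError(
            f"minimization did not reach gtol={gtol}: max |F| = {best_g:.3e}"
        )
    coords = best_x.reshape(shape)
    if bound.energy(coords) > e0 + 1e-10:
        raise PotentialError("minimization increased the energy")
    out = config.copy()
    out.coords = coords
    out.metadata["minimized_with"] = potential.level_tag
    out.metadata["max_force"] = best_g
    return out
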