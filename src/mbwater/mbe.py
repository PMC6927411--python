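"""Many-body expansion of cluster energies.

The total energy of an N-molecule cluster decomposes exactly as

    E_N = sum_i E^1B(i) + sum_{i<j} E^2B(i,j) + sum_{i<j<k} E^3B(i,j,k) + ...

where the n-body terms are defined recursively: the n-body energy of a
subset is its sub-cluster energy minus all lower-order terms of its proper
subsets.  Equivalently, by Moebius inversion on the subset lattice,

    E^nB(S) = sum_{T subseteq S} (-1)^(|S|-|T|) E(T),

and both evaluations are implemented and cross-checked.  The 1B energy of a
molecule is its deformation energy relative to the relaxed monomer; with the
potentials in this package the relaxed monomer energy is exactly zero, so
the in-cluster and isolated-optimized monomer references coincide and both
are exposed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .config import Configuration

#: decompose refuses full-order expansions beyond this size unless forced
MAX_FULL_ORDER_MOLECULES = 12


@dataclass
class MBEDecomposition:
    """Per-subset and per-order many-body energies of one cluster."""

    subset_energies: dict          # frozenset -> E(subset), kcal/mol
    nbody_terms: dict              # frozenset -> E^nB(subset)
    order_sums: dict               # n -> sum of E^nB over subsets of size n
    max_order: int
    n_molecules: int
    total_energy: float            # E_N of the full cluster
    reference: str = "in-cluster"  # monomer reference convention

    @property
    def interaction_energy(self) -> float:
        """E_N minus the (in-cluster) monomer energies."""
        return self.total_energy - self.order_sums.get(1, 0.0)

    def order_fractions(self) -> dict:
        """Per-order percentage of the total interaction energy."""
        inter = self.interaction_energy
        if inter == 0.0:
            return {n: np.nan for n in self.order_sums if n >= 2}
        return {n: 100.0 * s / inter
                for n, s in self.order_sums.items() if n >= 2}

    def reconstruction_error(self) -> float:
        """|sum_n order_sums - E_N|; zero up to round-off (telescoping)."""
        return abs(sum(self.order_sums.values()) - self.total_energy)

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view: subset, order, energy, cumulative percent."""
        rows = []
        inter = self.interaction_energy
        for subset in sorted(self.nbody_terms, key=lambda s: (len(s), sorted(s))):
            rows.append({
                "subset": "+".join(str(i) for i in sorted(subset)),
                "order": len(subset),
                "energy": self.nbody_terms[subset],
            })
        df = pd.DataFrame(rows)
        df["cumulative_pct"] = (
            100.0 * df["energy"].cumsum() / inter if inter else np.nan
        )
        return df


def _require_cluster(config: Configuration):
    if config.box_edge is not None:
        raise ValueError("many-body expansion operates on clusters")


def _norm_subset(subset, n_mol):
    subset = tuple(subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError(f"duplicate molecule indices in {subset}")
    if any(not (0 <= i < n_mol) for i in subset):
        raise ValueError(f"molecule index out of range in {subset}")
    return frozenset(subset)


def subset_energy(config: Configuration, potential, subset) -> float:
    """Energy of the sub-cluster ``subset`` at frozen in-cluster geometry."""
    _require_cluster(config)
    s = _norm_subset(subset, config.n_molecules)
    return potential.energy(config.subset(sorted(s)))


def _subset_energies(config, potential, subsets):
    cache = {}
    for s in subsets:
        if s not in cache:
            cache[s] = potential.energy(config.subset(sorted(s)))
    return cache

def _nbody_from_energies(energy_of: dict, subset: frozenset) -> float:
    """Moebius / inclusion-exclusion closed form over a subset's lattice."""
    s = sorted(subset)
    n = len(s)
    total = 0.0
    for k in range(1, n + 1):
        sign = (-1) ** (n - k)
        for t in combinations(s, k):
            total += sign * energy_of[frozenset(t)]
    return total


def nbody_term(config: Configuration, potential, subset,
               method: str = "moebius") -> float:
    """The n-body energy of ``subset``: its sub-cluster energy minus all
    lower-order terms of proper subsets.

    ``method`` selects the evaluation route: ``"moebius"`` (alternating sum)
    or ``"recursive"`` (literal recursion); they agree to round-off.
    """
    _require_cluster(config)
    s = _norm_subset(subset, config.n_molecules)
    all_subsets = [frozenset(t) for k in range(1, len(s) + 1)
                   for t in combinations(sorted(s), k)]
    energy_of = _subset_energies(config, potential, all_subsets)
    if method == "moebius":
        return _nbody_from_energies(energy_of, s)
    if method == "recursive":
        memo = {}

        def rec(t: frozenset) -> float:
            if t not in memo:
                lower = sum(
                    rec(frozenset(u))
                    for k in range(1, len(t))
                    for u in combinations(sorted(t), k)
                )
                memo[t] = energy_of[t] - lower
            return memo[t]

        return rec(s)
    raise ValueError(f"unknown method {method!r}")


def decompose(config: Configuration, potential, max_order: int,
              force: bool = False) -> MBEDecomposition:
    """Enumerate all subsets of size <= ``max_order`` and accumulate the
    per-order sums of the many-body expansion."""
    _require_cluster(config)
    n = config.n_molecules
    if not (1 <= max_order <= n):
        raise ValueError(f"max_order must be in 1..{n}, got {max_order}")
    if n > MAX_FULL_ORDER_MOLECULES and max_order > 3 and not force:
        raise ValueError(
            f"decompose at order {max_order} for {n} molecules enumerates "
            f"{sum(comb(n, k) for k in range(1, max_order + 1))} subsets; "
            "pass force=True to proceed"
        )
    mols = range(n)
    subsets = [frozenset(t) for k in range(1, max_order + 1)
               for t in combinations(mols, k)]
    energy_of = _subset_energies(config, potential, subsets)
    nbody = {s: _nbody_from_energies(energy_of, s) for s in subsets}
    order_sums = {k: 0.0 for k in range(1, max_order + 1)}
    for s, e in nbody.items():
        order_sums[len(s)] += e
    return MBEDecomposition(
        subset_energies=dict(energy_of),
        nbody_terms=nbody,
        order_sums=order_sums,
        max_order=max_order,
        n_molecules=n,
        total_energy=potential.energy(config),
    )


def samba_energy(config: Configuration, level_map: dict,
                 max_order: int | None = None) -> float:
    """Stratified total: per-order sums evaluated with order-specific levels.

    ``level_map`` maps each order 1..N to a potential; orders sharing a
    potential reuse one decomposition.  The order sums above 3 (or any order)
    may thus be computed with a cheaper level than the low orders, mirroring
    stratified many-body evaluation of cluster energies.
    """
    _require_cluster(config)
    n = config.n_molecules
    max_order = n if max_order is None else max_order
    missing = [k for k in range(1, max_order + 1) if k not in level_map]
    if missing:
        raise ValueError(f"level_map missing orders {missing}")
    decomps = {}
    total = 0.0
    for order in range(1, max_order + 1):
        pot = level_map[order]
        key = id(pot)
        if key not in decomps:
            decomps[key] = decompose(config, pot, max_order)
        total += decomps[key].order_sums[order]
    return total
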