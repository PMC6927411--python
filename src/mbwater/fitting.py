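"""Permutation-invariant fitting of swappable short-range 2B/3B terms.

The basis consists of monomials in the exponential variables
xi_ab = exp(-r_ab / lambda) over all intermolecular atom pairs of a dimer
(9 variables) or trimer (27 variables), averaged over the full permutation
group of identical atoms and molecules (H swaps within each molecule,
molecule exchange), and multiplied by the order's switching function so the
fitted term vanishes smoothly beyond its outer radius.  Symmetrization is by
explicit orbit averaging, which is auditable at these group sizes.

Fits are deterministic ridge-regularized linear least squares.  Error
statistics (RMSD, MAE, max error, Pearson r) serve the correlation-plot
style comparison of surrogate levels against the truth reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np
from scipy import stats as _sps

from .config import Configuration, minimum_image
from .potentials.params import BASIS_LAMBDA
from .potentials.switching import switch
from .synthetic import LabeledSet


@dataclass(frozen=True)
class BasisSpec:
    """Variable transform and polynomial layout of a fitted term."""

    order: int                    # 2 or 3
    degree: int = 4               # max total monomial degree
    lam: float = BASIS_LAMBDA     # A, exponential length scale
    r_in: float = 5.5             # A, switch inner radius
    r_out: float = 7.5            # A, switch outer radius

    def __post_init__(self):
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if not 0 < self.r_in < self.r_out:
            raise ValueError("need 0 < r_in < r_out")


def default_spec(order: int) -> BasisSpec:
    """Default layouts: degree 4 at 2B, degree 2 at 3B; switch radii match
    the analytic short-range terms they are meant to replace."""
    if order == 2:
        return BasisSpec(order=2, degree=4, r_in=5.5, r_out=7.5)
    if order == 3:
        return BasisSpec(order=3, degree=2, r_in=2.5, r_out=4.5)
    raise ValueError("order must be 2 or 3")


# ---------------------------------------------------------------------------
# pair-variable layout and permutation group

def _pair_layout(order: int):
    """Canonical list of intermolecular atom pairs and O-O variable ids."""
    mols = [list(range(3 * m, 3 * m + 3)) for m in range(order)]
    pairs = []
    for mi, mj in combinations(range(order), 2):
        for a in mols[mi]:
            for b in mols[mj]:
                pairs.append((a, b))
    pair_index = {frozenset(p): i for i, p in enumerate(pairs)}
    oo_vars = [pair_index[frozenset((3 * mi, 3 * mj))]
               for mi, mj in combinations(range(order), 2)]
    return pairs, pair_index, oo_vars


def _atom_permutation_group(order: int):
    """Closure of H-swap and molecule-exchange generators (atom maps)."""
    n = 3 * order
    gens = []
    for m in range(order):
        g = list(range(n))
        g[3 * m + 1], g[3 * m + 2] = g[3 * m + 2], g[3 * m + 1]
        gens.append(tuple(g))
    for mi, mj in combinations(range(order), 2):
        g = list(range(n))
        for k in range(3):
            g[3 * mi + k], g[3 * mj + k] = g[3 * mj + k], g[3 * mi + k]
        gens.append(tuple(g))
    group = {tuple(range(n))}
    frontier = [tuple(range(n))]
    while frontier:
        new = []
        for el in frontier:
            for g in gens:
                composed = tuple(g[i] for i in el)
                if composed not in group:
                    group.add(composed)
                    new.append(composed)
        frontier = new
    return sorted(group)


def _variable_permutations(order: int):
    """The atom group acting on the canonical pair variables."""
    pairs, pair_index, _ = _pair_layout(order)
    perms = []
    for g in _atom_permutation_group(order):
        perms.append(tuple(pair_index[frozenset((g[a], g[b]))]
                           for a, b in pairs))
    return perms


def _monomials(n_vars: int, degree: int):
    """All exponent index-tuples of total degree 1..degree."""
    out = []
    for d in range(1, degree + 1):
        out.extend(combinations_with_replacement(range(n_vars), d))
    return out


def _orbits(order: int, degree: int):
    """Partition the monomials into permutation orbits.

    Returns (monomial index-tuples, list of orbits as monomial-id lists).
    """
    n_vars = len(_pair_layout(order)[0])
    monos = _monomials(n_vars, degree)
    mono_id = {m: i for i, m in enumerate(monos)}
    perms = _variable_permutations(order)
    seen = np.zeros(len(monos), dtype=bool)
    orbits = []
    for i, m in enumerate(monos):
        if seen[i]:
            continue
        members = set()
        for p in perms:
            members.add(mono_id[tuple(sorted(p[v] for v in m))])
        members = sorted(members)
        for j in members:
            seen[j] = True
        orbits.append(members)
    return monos, orbits


_ORBIT_CACHE: dict = {}


def basis_layout(spec: BasisSpec):
    key = (spec.order, spec.degree)
    if key not in _ORBIT_CACHE:
        _ORBIT_CACHE[key] = _orbits(spec.order, spec.degree)
    return _ORBIT_CACHE[key]


def feature_count(spec: BasisSpec) -> int:
    """Number of symmetrized features (monomial orbits)."""
    return len(basis_layout(spec)[1])


# ---------------------------------------------------------------------------
# evaluation helpers

def _pair_geometry(coords_batch: np.ndarray, order: int,
                   box_edge: float | None = None):
    """Displacements, distances and xi variables for a batch of
    ``order``-molecule subclusters with coordinates (m, 3*order, 3)."""
    pairs, _, oo_vars = _pair_layout(order)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    d = coords_batch[:, ia, :] - coords_batch[:, ib, :]
    if box_edge is not None:
        d = minimum_image(d, box_edge)
    r = np.linalg.norm(d, axis=2)
    return d, r, np.array(oo_vars), (ia, ib)


def _monomial_matrix(xi: np.ndarray, monos):
    """(m, n_monomials) products of xi columns; xi is (m, n_vars)."""
    cols = np.empty((xi.shape[0], len(monos)))
    for i, mono in enumerate(monos):
        v = xi[:, mono[0]].copy()
        for idx in mono[1:]:
            v *= xi[:, idx]
        cols[:, i] = v
    return cols


def _switch_product(r: np.ndarray, oo_vars: np.ndarray, spec: BasisSpec):
    """Switch value and per-OO-pair derivative factors for a batch."""
    s_all, ds_all = switch(r[:, oo_vars], spec.r_in, spec.r_out)
    S = np.prod(s_all, axis=1)
    return S, s_all, ds_all


def build_basis(config: Configuration, spec: BasisSpec) -> np.ndarray:
    """Feature vector of one dimer/trimer configuration."""
    if config.n_molecules != spec.order:
        raise ValueError(
            f"cluster has {config.n_molecules} molecules; basis order is "
            f"{spec.order}"
        )
    return design_matrix([config], spec)[0]


def design_matrix(configs, spec: BasisSpec) -> np.ndarray:
    """(n_configs, n_features) symmetrized, switched feature matrix."""
    coords = np.stack([c.coords for c in configs])
    monos, orbits = basis_layout(spec)
    _, r, oo_vars, _ = _pair_geometry(coords, spec.order)
    xi = np.exp(-r / spec.lam)
    M = _monomial_matrix(xi, monos)
    S, _, _ = _switch_product(r, oo_vars, spec)
    X = np.empty((len(configs), len(orbits)))
    for k, orbit in enumerate(orbits):
        X[:, k] = M[:, orbit].mean(axis=1)
    return X * S[:, None]


# ---------------------------------------------------------------------------
# error statistics

@dataclass
class ErrorStats:
    """Summary statistics of predictions against reference labels."""

    rmsd: float
    mae: float
    max_abs: float
    pearson_r: float
    n: int
    xy: np.ndarray = field(default=None, repr=False)  # (n, 2) ref vs pred

    def __post_init__(self):
        assert self.rmsd >= 0 and self.mae >= 0 and self.max_abs >= 0
        if np.isfinite(self.pearson_r):
            assert abs(self.pearson_r) <= 1 + 1e-12


def _predict(obj, test: LabeledSet) -> np.ndarray:
    from . import mbe

    if isinstance(obj, FittedTerm):
        coords = np.stack([c.coords for c in test.configs])
        return obj.evaluate_batch(coords)
    preds = np.empty(len(test))
    for i, cfg in enumerate(test.configs):
        if test.order == "total":
            preds[i] = obj.energy(cfg)
        elif test.order == 1:
            preds[i] = sum(
                mbe.subset_energy(cfg, obj, (m,))
                for m in range(cfg.n_molecules)
            )
        else:
            preds[i] = mbe.nbody_term(cfg, obj, tuple(range(cfg.n_molecules)))
    return preds


def error_stats(term_or_potential, test: LabeledSet) -> ErrorStats:
    """RMSD/MAE/max/Pearson-r of predictions against the labels of ``test``;
    the (reference, prediction) pairs for correlation plots ride along."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = _predict(term_or_potential, test)
    ref = test.energies
    resid = pred - ref
    if len(test) >= 2 and np.std(ref) > 0 and np.std(pred) > 0:
        r = float(_sps.pearsonr(ref, pred).statistic)
    else:
        r = np.nan
    return ErrorStats(
        rmsd=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        max_abs=float(np.max(np.abs(resid))),
        pearson_r=r,
        n=len(test),
        xy=np.column_stack([ref, pred]),
    )


# ---------------------------------------------------------------------------
# the fitted term

class FittedTerm:
    """A symmetrized polynomial short-range term with switching.

    Stores both the per-feature coefficients and the expanded per-monomial
    weights used for fast evaluation; invariant under the permutation group
    of its order by construction and exactly zero beyond ``spec.r_out``.
    """

    def __init__(self, spec: BasisSpec, coefficients: np.ndarray,
                 training_stats: ErrorStats | None = None,
                 source_tag: str = ""):
        self.spec = spec
        self.order = spec.order
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.training_stats = training_stats
        self.source_tag = source_tag
        monos, orbits = basis_layout(spec)
        if len(self.coefficients) != len(orbits):
            raise ValueError("coefficient count does not match basis size")
        w = np.zeros(len(monos))
        for c, orbit in zip(self.coefficients, orbits):
            for j in orbit:
                w[j] += c / len(orbit)
        keep = np.flatnonzero(np.abs(w) > 0)
        self._weights = w[keep]
        self._monos = [monos[j] for j in keep]

    # -- evaluation ------------------------------------------------------
    def evaluate_batch(self, coords_batch: np.ndarray,
                       box_edge: float | None = None) -> np.ndarray:
        """Term values for (m, 3*order, 3) subcluster coordinates."""
        _, r, oo_vars, _ = _pair_geometry(coords_batch, self.order, box_edge)
        xi = np.exp(-r / self.spec.lam)
        M = _monomial_matrix(xi, self._monos)
        S, _, _ = _switch_product(r, oo_vars, self.spec)
        return (M @ self._weights) * S

    def evaluate(self, config: Configuration) -> float:
        if config.n_molecules != self.order:
            raise ValueError("configuration size does not match term order")
        return float(self.evaluate_batch(config.coords[None])[0])

    def evaluate_batch_grad(self, coords_batch: np.ndarray,
                            box_edge: float | None = None):
        """Values and gradients wrt the subcluster coordinates.

        Returns (values (m,), grad (m, 3*order, 3)).
        """
        d, r, oo_vars, (ia, ib) = _pair_geometry(coords_batch, self.order,
                                                 box_edge)
        xi = np.exp(-r / self.spec.lam)
        M = _monomial_matrix(xi, self._monos)
        S, s_all, ds_all = _switch_product(r, oo_vars, self.spec)
        P = M @ self._weights
        values = P * S
        m_cfg, n_vars = xi.shape
        # dP/dxi accumulated per variable
        dP = np.zeros((m_cfg, n_vars))
        for w, mono in zip(self._weights, self._monos):
            for slot in range(len(mono)):
                others = mono[:slot] + mono[slot + 1:]
                part = np.full(m_cfg, w)
                for idx in others:
                    part = part * xi[:, idx]
                dP[:, mono[slot]] += part
        # dV/dr_p = dP/dxi_p * dxi/dr * S  (+ switch derivative on OO vars)
        dVdr = dP * (-xi / self.spec.lam) * S[:, None]
        for k, v in enumerate(oo_vars):
            s_others = S / np.where(s_all[:, k] != 0.0, s_all[:, k], np.inf)
            dVdr[:, v] += P * ds_all[:, k] * s_others
        grad = np.zeros_like(coords_batch)
        gvec = (dVdr / r)[:, :, None] * d
        np.add.at(grad, (slice(None), ia), gvec)
        np.add.at(grad, (slice(None), ib), -gvec)
        return values, grad

    # -- composition into larger clusters -------------------------------
    def cluster_energy_forces(self, coords: np.ndarray,
                              mol_table: np.ndarray, want_forces=True,
                              box_edge: float | None = None):
        """Sum the term over all molecule pairs (order 2) or triples
        (order 3) of a cluster; scatter forces back to the atoms."""
        n_mol = mol_table.shape[0]
        if n_mol < self.order:
            F = np.zeros_like(coords) if want_forces else None
            return 0.0, F
        groups = list(combinations(range(n_mol), self.order))
        atom_idx = np.array([
            np.concatenate([mol_table[m] for m in g]) for g in groups
        ])
        batch = coords[atom_idx]
        if box_edge is not None:
            # make each subcluster whole: shift molecules to the minimum
            # image of the first molecule's oxygen
            o_ref = batch[:, 0:1, :]
            for k in range(1, self.order):
                blk = slice(3 * k, 3 * k + 3)
                o_k = batch[:, 3 * k: 3 * k + 1, :]
                shift = box_edge * np.round((o_k - o_ref) / box_edge)
                batch[:, blk, :] -= shift
        if not want_forces:
            vals = self.evaluate_batch(batch)
            return float(vals.sum()), None
        vals, grads = self.evaluate_batch_grad(batch)
        F = np.zeros_like(coords)
        np.add.at(F, atom_idx.ravel(), -grads.reshape(-1, 3))
        return float(vals.sum()), F

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "degree": self.spec.degree,
            "lambda": self.spec.lam,
            "r_in": self.spec.r_in,
            "r_out": self.spec.r_out,
            "source_tag": self.source_tag,
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FittedTerm":
        spec = BasisSpec(order=int(data["order"]), degree=int(data["degree"]),
                         lam=float(data["lambda"]), r_in=float(data["r_in"]),
                         r_out=float(data["r_out"]))
        return cls(spec, np.asarray(data["coefficients"], dtype=float),
                   source_tag=data.get("source_tag", ""))


# ---------------------------------------------------------------------------
# fitting

def fit_term(train: LabeledSet, basis_spec: BasisSpec | None = None,
             ridge: float = 1e-8) -> FittedTerm:
    """Ridge-regularized least-squares fit of a short-range term.

    The labels must be n-body energies matching the basis order.  Columns are
    norm-scaled before solving for conditioning; the solve is deterministic.
    """
    if basis_spec is None:
        basis_spec = default_spec(train.order if train.order in (2, 3) else 2)
    if train.order != basis_spec.order:
        raise ValueError(
            f"training labels are order {train.order}; basis order is "
            f"{basis_spec.order}"
        )
    X = design_matrix(train.configs, basis_spec)
    y = train.energies
    n, f = X.shape
    if n < f:
        warnings.warn(
            f"{n} training points for {f} features; fit is underdetermined",
            stacklevel=2,
        )
    norms = np.linalg.norm(X, axis=0)
    if ridge <= 0 and np.any(norms == 0):
        raise np.linalg.LinAlgError(
            "degenerate normal equations at ridge=0; use a nonzero ridge"
        )
    norms = np.where(norms == 0, 1.0, norms)
    Xs = X / norms
    if ridge > 0:
        A = np.vstack([Xs, np.sqrt(ridge) * np.eye(f)])
        b = np.concatenate([y, np.zeros(f)])
    else:
        A, b = Xs, y
        if np.linalg.matrix_rank(Xs) < f:
            raise np.linalg.LinAlgError(
                "degenerate normal equations at ridge=0; use a nonzero ridge"
            )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    coeffs = sol / norms
    term = FittedTerm(basis_spec, coeffs, source_tag=train.level_tag)
    term.training_stats = error_stats(term, train)
    return term


def fit_replacement_terms(base_potential, train2b: LabeledSet | None = None,
                          train3b: LabeledSet | None = None,
                          spec2: BasisSpec | None = None,
                          spec3: BasisSpec | None = None,
                          ridge: float = 1e-8):
    """Fit short-range terms destined to replace those of ``base_potential``.

    The training labels are full n-body energies from some reference level;
    what the short-range term must represent is the part of those labels not
    already carried by the base potential's baseline (electrostatics,
    induction, dispersion).  That baseline contribution is subtracted here
    before fitting, using the base potential with its short-range term
    removed.

    Returns (two_body_term or None, three_body_term or None).
    """
    from dataclasses import replace as _dc_replace

    from .potentials.core import Potential
    from .synthetic import LabeledSet as _LS, label_set

    out2 = out3 = None
    p = base_potential.params
    if train2b is not None:
        spec2 = spec2 or BasisSpec(order=2, degree=4,
                                   r_in=p.sw2_rin, r_out=p.sw2_rout)
        stripped = Potential(params=_dc_replace(p, bm_a=0.0, bm_a_oh=0.0,
                                                bm_a_hh=0.0),
                             level_tag="baseline-only")
        base_labels = label_set(train2b.configs, stripped, order=2)
        residual = _LS(train2b.configs,
                       train2b.energies - base_labels.energies,
                       order=2, level_tag=train2b.level_tag)
        out2 = fit_term(residual, spec2, ridge)
    if train3b is not None:
        spec3 = spec3 or BasisSpec(order=3, degree=2,
                                   r_in=p.sw3_rin, r_out=p.sw3_rout)
        stripped = Potential(params=_dc_replace(p, c9=0.0),
                             level_tag="baseline-only")
        base_labels = label_set(train3b.configs, stripped, order=3)
        residual = _LS(train3b.configs,
                       train3b.energies - base_labels.energies,
                       order=3, level_tag=train3b.level_tag)
        out3 = fit_term(residual, spec3, ridge)
    return out2, out3
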