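"""Structural observables: tetrahedral order parameter, its normalized
distribution, bead-averaged radial distribution functions, and hexamer
isomer relative-energy tables.

The tetrahedral order parameter of a central water molecule is

    q_tet = 1 - (3/8) sum_{j<k<=4} (cos psi_jk + 1/3)^2

over the six angles psi_jk subtended at the central oxygen by its four
nearest oxygen neighbors: q_tet = 1 in a perfect tetrahedral environment
and averages to 0 over completely random neighbor directions (and reaches
-3 in the degenerate all-collinear limit).

RDFs are computed from same-bead pair distances (the standard path-integral
estimator for static pair correlations), normalized by the exact
minimum-image ideal-gas shell measure of a cubic box, which stays valid
beyond half the box edge up to L/sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Configuration, minimum_image

__all__ = [
    "q_tet", "q_from_directions", "q_tet_distribution", "QtetDistribution",
    "compute_rdf", "RDF", "isomer_relative_energies",
]


# ---------------------------------------------------------------------------
# tetrahedral order parameter

def q_from_directions(directions: np.ndarray) -> np.ndarray:
    """q_tet for batches of four neighbor direction vectors (n, 4, 3)."""
    d = np.asarray(directions, dtype=float)
    if d.ndim == 2:
        d = d[None]
    u = d / np.linalg.norm(d, axis=2, keepdims=True)
    cos = np.einsum("nij,nkj->nik", u, u)
    iu, ju = np.triu_indices(4, k=1)
    return 1.0 - 0.375 * np.sum((cos[:, iu, ju] + 1.0 / 3.0) ** 2, axis=1)


def _neighbor_directions(oxy: np.ndarray, center: int,
                         box_edge: float | None) -> np.ndarray:
    d = oxy - oxy[center]
    if box_edge is not None:
        d = minimum_image(d, box_edge)
    r = np.linalg.norm(d, axis=1)
    r[center] = np.inf
    # four nearest oxygens; ties broken by index via stable argsort
    order = np.argsort(r, kind="stable")[:4]
    if not np.all(np.isfinite(r[order])):
        raise ValueError("fewer than 4 neighbor oxygens")
    return d[order]


def q_tet(config: Configuration, center: int) -> float:
    """Tetrahedral order parameter of molecule ``center``."""
    if config.n_molecules < 5:
        raise ValueError("q_tet needs at least 5 molecules")
    oxy = config.oxygen_coords()
    d = _neighbor_directions(oxy, center, config.box_edge)
    return float(q_from_directions(d[None])[0])


def _q_all_molecules(oxy: np.ndarray, box_edge: float | None) -> np.ndarray:
    """q_tet of every molecule in one frame (vectorized)."""
    n = len(oxy)
    d = oxy[None, :, :] - oxy[:, None, :]
    if box_edge is not None:
        d = minimum_image(d, box_edge)
    r = np.linalg.norm(d, axis=2)
    np.fill_diagonal(r, np.inf)
    idx = np.argsort(r, axis=1, kind="stable")[:, :4]
    neigh = np.take_along_axis(d, idx[:, :, None], axis=1)
    return q_from_directions(neigh)


@dataclass
class QtetDistribution:
    """Normalized probability density of q_tet."""

    bin_edges: np.ndarray
    probabilities: np.ndarray  # density; integrates to 1
    n_samples: int

    def __post_init__(self):
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.probabilities * widths))
        if abs(total - 1.0) > 1e-10 and self.n_samples:
            raise ValueError(f"distribution not normalized: {total}")

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"q_tet": mid, "probability": self.probabilities})


def q_tet_distribution(traj, bins=None) -> QtetDistribution:
    """P(q_tet) over every molecule, frame and bead of a trajectory."""
    if bins is None:
        bins = np.arange(-3.0, 1.0 + 1e-9, 0.02)
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    oxy_idx = np.array([i for i, e in enumerate(traj.elements) if e == "O"])
    samples = []
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        box = traj.box_edges[f]
        for s in range(frame.shape[0]):
            samples.append(_q_all_molecules(frame[s][oxy_idx], box))
    q = np.concatenate(samples)
    hist, edges = np.histogram(q, bins=bins, density=True)
    return QtetDistribution(bin_edges=edges, probabilities=hist,
                            n_samples=len(q))


# ---------------------------------------------------------------------------
# radial distribution functions

_PAIR_ELEMENTS = {"OO": ("O", "O"), "OH": ("O", "H"), "HH": ("H", "H")}


def _cube_shell_area(r: np.ndarray, L: float) -> np.ndarray:
    """Surface measure of the radius-r sphere inside the minimum-image cube
    [-L/2, L/2]^3; exact for r < L/sqrt(2) (face caps do not yet overlap)."""
    area = 4.0 * np.pi * r**2
    cap = r > L / 2.0
    area[cap] -= 6.0 * 2.0 * np.pi * r[cap] * (r[cap] - L / 2.0)
    return area


@dataclass
class RDF:
    """Radial distribution function of one atom-pair kind."""

    pair_kind: str
    bin_edges: np.ndarray
    g: np.ndarray
    n_frames: int
    density: float  # number density of the second species (1/A^3)

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_A": self.r, "g": self.g})


def compute_rdf(traj, pair_kind: str = "OO", r_max: float | None = None,
                bin_width: float = 0.05) -> RDF:
    """Bead- and frame-averaged minimum-image RDF of a periodic trajectory.

    ``r_max`` defaults to just below L/sqrt(2), the validity limit of the
    cube-shell normalization.
    """
    if pair_kind not in _PAIR_ELEMENTS:
        raise ValueError(f"pair_kind must be one of {sorted(_PAIR_ELEMENTS)}")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    L0 = traj.box_edges[0]
    if L0 is None:
        raise ValueError("RDFs require a periodic trajectory")
    limit = L0 / np.sqrt(2.0) * 0.999
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds the normalization limit {limit:.3f} A"
        )
    ea, eb = _PAIR_ELEMENTS[pair_kind]
    ia = np.array([i for i, e in enumerate(traj.elements) if e == ea])
    ib = np.array([i for i, e in enumerate(traj.elements) if e == eb])
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_samples = 0
    for f in range(traj.n_frames):
        L = traj.box_edges[f]
        frame = traj.frames[f]
        for s in range(frame.shape[0]):
            c = frame[s]
            d = c[ia][:, None, :] - c[ib][None, :, :]
            d = minimum_image(d, L)
            r = np.linalg.norm(d, axis=2)
            if ea == eb:
                iu, ju = np.triu_indices(len(ia), k=1)
                r = r[iu, ju]
            else:
                r = r.ravel()
            counts += np.histogram(r, bins=edges)[0]
            n_samples += 1
    # ideal-gas normalization with the exact minimum-image shell measure
    L = traj.box_edges[0]
    V = L**3
    n_pairs = (len(ia) * (len(ia) - 1) // 2 if ea == eb
               else len(ia) * len(ib))
    mid = 0.5 * (edges[:-1] + edges[1:])
    shell = _cube_shell_area(mid, L) * np.diff(edges)
    ideal = n_pairs * shell / V
    g = counts / (n_samples * ideal)
    dens = (len(ib) if ea != eb else len(ia)) / V
    return RDF(pair_kind=pair_kind, bin_edges=edges, g=g,
               n_frames=traj.n_frames, density=dens)


# ---------------------------------------------------------------------------
# hexamer isomer tables

def isomer_relative_energies(potentials: dict, isomers: dict,
                             parent_map: dict | None = None,
                             force_tolerance: float = 1e-3) -> pd.DataFrame:
    """Relative isomer energies per potential, lowest isomer at zero.

    ``potentials`` maps name -> Potential, ``isomers`` maps isomer name ->
    (minimized) Configuration.  When ``parent_map`` maps a hybrid potential
    name to its parent's name, a ``dev_from_<parent>`` column reports the
    per-isomer deviation of relative energies from the parent.

    Isomers whose maximum force under the first potential exceeds
    ``force_tolerance`` (kcal/mol/A) are flagged in ``df.attrs['warnings']``.
    """
    names = list(isomers)
    rows = {}
    warnings_ = []
    first = next(iter(potentials.values()))
    for iso in names:
        fmax = float(np.abs(first.forces(isomers[iso])).max())
        if fmax > force_tolerance:
            warnings_.append(
                f"isomer {iso}: max force {fmax:.2e} above tolerance "
                f"{force_tolerance}"
            )
    for pname, pot in potentials.items():
        e = np.array([pot.energy(isomers[iso]) for iso in names])
        rows[pname] = e - e.min()
    df = pd.DataFrame(rows, index=names)
    if parent_map:
        for child, parent in parent_map.items():
            df[f"dev_from_{parent}|{child}"] = df[child] - df[parent]
    df.attrs["warnings"] = warnings_
    return df
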