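"""Synthetic input generation: training clusters, liquid boxes, hexamer
templates and labeled energy sets.

All reference data in this package are produced by analytic model potentials;
the generators here supply the geometries those potentials are evaluated on.
Dimer/trimer sets emulate 2B/3B training data (uniform in O-O separation,
uniform in orientation, with small thermal-like intramolecular distortions);
the liquid box emulates ambient water at a requested density; the hexamer
templates provide the prism/cage/book/cyclic starting structures for local
minimization.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    Configuration,
    assemble,
    minimum_image,
    perturbed_monomer,
    random_rotation_matrix,
    reference_monomer,
)
from .constants import AVOGADRO_PER_A3, WATER_MOLAR_MASS

#: closest allowed intermolecular atom-atom contact when sampling clusters (A)
CLUSTER_CONTACT_MIN = 1.2
#: closest allowed intermolecular contact when packing liquid boxes (A)
BOX_CONTACT_MIN = 1.5

#: ambient liquid density default, g/cm^3 at 298.15 K
DENSITY_DEFAULT = 0.997


@dataclass
class LabeledSet:
    """Configurations with reference energies from a generating potential.

    ``order`` identifies which n-body quantity the labels are (1, 2, 3, or
    "total"); ``level_tag`` names the potential that produced them ("truth"
    or a surrogate name); ``noise_sigma`` is the width of the Gaussian noise
    added on top of the noiseless labels (kcal/mol).
    """

    configs: list
    energies: np.ndarray
    order: object  # 1 | 2 | 3 | "total"
    level_tag: str
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.configs):
            raise ValueError("one energy per configuration required")
        if self.order not in (1, 2, 3, "total"):
            raise ValueError(f"invalid order {self.order!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def __len__(self):
        return len(self.configs)


def _check_range(r_range):
    lo, hi = r_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid r_range {r_range}")
    return lo, hi


def _min_intermolecular_distance(config: Configuration) -> float:
    c = config.coords
    mol = config.molecule_index
    d = c[:, None, :] - c[None, :, :]
    if config.box_edge is not None:
        d = minimum_image(d, config.box_edge)
    r = np.linalg.norm(d, axis=-1)
    inter = mol[:, None] != mol[None, :]
    return r[inter].min()


def sample_dimer_set(n: int, r_range=(2.2, 8.0), seed: int = 0,
                     sigma_r: float = 0.02,
                     sigma_theta_deg: float = 2.0) -> list:
    """Sample ``n`` water dimers with O-O distance uniform in ``r_range``.

    Molecule positions are anchored at the O atom, orientations are uniform
    on the rotation group and intramolecular geometries carry seeded Gaussian
    distortions.  Configurations with an intermolecular atom-atom contact
    below 1.2 A are rejected and resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = _check_range(r_range)
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        r = rng.uniform(lo, hi)
        mols = []
        for anchor in (np.zeros(3), _random_direction(rng) * r):
            m = perturbed_monomer(rng, sigma_r, sigma_theta_deg)
            m = m @ random_rotation_matrix(rng).T
            mols.append(m - m[0] + anchor)
        cand = assemble(mols)
        if _min_intermolecular_distance(cand) >= CLUSTER_CONTACT_MIN:
            out.append(cand)
    return out


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def sample_trimer_set(n: int, r_range=(2.4, 7.0), seed: int = 0,
                      sigma_r: float = 0.02,
                      sigma_theta_deg: float = 2.0) -> list:
    """Sample ``n`` water trimers with every O-O pair distance in ``r_range``.

    The third oxygen is placed by rejection so that both its pair distances
    fall inside the range; contacts below 1.2 A are rejected as for dimers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = _check_range(r_range)
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        r12 = rng.uniform(lo, hi)
        anchors = [np.zeros(3), np.array([r12, 0.0, 0.0])]
        # rejection placement of the third O
        for _ in range(1000):
            r13 = rng.uniform(lo, hi)
            p3 = _random_direction(rng) * r13
            r23 = np.linalg.norm(p3 - anchors[1])
            if lo <= r23 <= hi:
                anchors.append(p3)
                break
        else:  # pragma: no cover - geometrically unreachable for sane ranges
            continue
        mols = []
        for anchor in anchors:
            m = perturbed_monomer(rng, sigma_r, sigma_theta_deg)
            m = m @ random_rotation_matrix(rng).T
            mols.append(m - m[0] + anchor)
        cand = assemble(mols)
        if _min_intermolecular_distance(cand) >= CLUSTER_CONTACT_MIN:
            out.append(cand)
    return out


def box_edge_for_density(n_molecules: int, density: float) -> float:
    """Cubic box edge (A) holding ``n_molecules`` waters at ``density`` g/cm^3."""
    return (n_molecules * WATER_MOLAR_MASS / (density * AVOGADRO_PER_A3)) ** (1.0 / 3.0)


def build_liquid_box(n_molecules: int, density: float = DENSITY_DEFAULT,
                     seed: int = 0, max_retries: int = 200) -> Configuration:
    """Place waters on a jittered lattice in a periodic cubic box.

    Molecules get uniform random orientations; the jitter amplitude shrinks
    across retries until no intermolecular atom-atom contact is closer than
    1.5 A (minimum image).
    """
    if n_molecules < 2:
        raise ValueError("n_molecules must be >= 2")
    if density <= 0:
        raise ValueError("density must be positive")
    edge = box_edge_for_density(n_molecules, density)
    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = edge / n_side
    sites = np.array([
        [(i + 0.5), (j + 0.5), (k + 0.5)]
        for i in range(n_side) for j in range(n_side) for k in range(n_side)
    ]) * spacing
    ref = reference_monomer()
    for _ in range(max_retries):
        chosen = sites[rng.permutation(len(sites))[:n_molecules]]
        placed: list = []
        ok = True
        for site in chosen:
            # greedy: retry orientation/jitter per molecule against the
            # already placed ones
            for _try in range(120):
                jitter = 0.10 * spacing
                m = ref @ random_rotation_matrix(rng).T
                m = m - m[0] + site + rng.normal(scale=jitter, size=3)
                if _clashes(m, placed, edge):
                    continue
                placed.append(m)
                break
            else:
                ok = False
                break
        if ok:
            cand = assemble(placed, box_edge=edge)
            cand.metadata["density"] = density
            return cand
    raise RuntimeError(
        f"could not pack {n_molecules} molecules at {density} g/cm^3 "
        f"without contacts < {BOX_CONTACT_MIN} A"
    )


def _clashes(mol: np.ndarray, placed: list, edge: float) -> bool:
    if not placed:
        return False
    other = np.concatenate(placed)
    d = minimum_image(mol[:, None, :] - other[None, :, :], edge)
    return bool(np.linalg.norm(d, axis=-1).min() < BOX_CONTACT_MIN)


# ---------------------------------------------------------------------------
# hexamer templates

def _hexamer_oxygen_skeletons() -> dict:
    """Oxygen-atom skeletons of the low-lying hexamer motifs.

    Geometric idealizations (O-O near 2.8 A), not literature coordinates;
    each is a starting point for local minimization under a chosen potential.
    """
    d = 2.8
    # prism: two stacked triangles
    tri = d / np.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    ring = np.stack([np.cos(angles), np.sin(angles)], axis=1) * tri
    prism = np.concatenate([
        np.column_stack([ring, np.zeros(3)]),
        np.column_stack([ring, np.full(3, d)]),
    ])
    # cyclic: planar hexagon
    hexang = np.deg2rad(np.arange(6) * 60.0)
    rhex = d / (2.0 * np.sin(np.pi / 6.0))
    cyclic = np.column_stack([rhex * np.cos(hexang), rhex * np.sin(hexang),
                              np.zeros(6)])
    # book: two fused four-membered rings sharing an edge, folded 120 deg
    fold = np.deg2rad(120.0)
    book = np.array([
        [0.0, 0.0, 0.0],
        [0.0, d, 0.0],
        [d, 0.0, 0.0],
        [d, d, 0.0],
        [d + d * np.cos(np.pi - fold), 0.0, d * np.sin(np.pi - fold)],
        [d + d * np.cos(np.pi - fold), d, d * np.sin(np.pi - fold)],
    ])
    # cage: distorted prism with one triangle twisted and compressed
    cage = prism.copy()
    twist = np.deg2rad(25.0)
    rot = np.array([[np.cos(twist), -np.sin(twist), 0.0],
                    [np.sin(twist), np.cos(twist), 0.0],
                    [0.0, 0.0, 1.0]])
    cage[3:] = (cage[3:] - [0, 0, d]) @ rot.T * 0.9 + [0.4, 0.0, 0.9 * d]
    return {"prism": prism, "cage": cage, "book": book, "cyclic": cyclic}


def _orient_molecules_on_skeleton(oxygens: np.ndarray) -> Configuration:
    """Attach H atoms so each water donates toward its two nearest O neighbors."""
    from .config import R_OH_REF, THETA_HOH_REF

    mols = []
    n = len(oxygens)
    for i in range(n):
        o = oxygens[i]
        d = np.linalg.norm(oxygens - o, axis=1)
        order = np.argsort(d)
        u = oxygens[order[1]] - o
        u /= np.linalg.norm(u)
        v = oxygens[order[2]] - o
        v /= np.linalg.norm(v)
        # second OH direction: rotate u toward v to the reference HOH angle
        w = v - np.dot(u, v) * u
        nw = np.linalg.norm(w)
        if nw < 1e-8:  # collinear neighbors; pick any perpendicular
            w = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(w) < 1e-8:
                w = np.cross(u, [0.0, 1.0, 0.0])
            nw = np.linalg.norm(w)
        w /= nw
        ang = THETA_HOH_REF
        v2 = np.cos(ang) * u + np.sin(ang) * w
        h1 = o + R_OH_REF * u
        h2 = o + R_OH_REF * v2
        mols.append(np.stack([o, h1, h2]))
    return assemble(mols)


def hexamer_templates() -> dict:
    """Six-molecule cluster templates for the prism, cage, book and cyclic
    isomer motifs, keyed by name."""
    return {name: _orient_molecules_on_skeleton(sk)
            for name, sk in _hexamer_oxygen_skeletons().items()}


def hexamer_template(name: str) -> Configuration:
    templates = hexamer_templates()
    if name not in templates:
        raise KeyError(
            f"unknown hexamer isomer {name!r}; known: {sorted(templates)}"
        )
    return templates[name]


# ---------------------------------------------------------------------------
# labeling

def label_set(configs: list, potential, order, noise_sigma: float = 0.0,
              seed: int = 0) -> LabeledSet:
    """Attach n-body reference energies from ``potential`` to ``configs``.

    ``order`` 2 requires dimers and ``order`` 3 trimers; the labels are the
    corresponding many-body-expansion terms (kcal/mol), ``order`` 1 the sum of
    monomer deformation energies, and ``"total"`` the full cluster energy.
    Gaussian noise of width ``noise_sigma`` is added with the given seed.
    """
    from . import mbe

    if order not in (1, 2, 3, "total"):
        raise ValueError(f"invalid order {order!r}")
    rng = np.random.default_rng(seed)
    energies = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        n = cfg.n_molecules
        if order in (2, 3) and n != order:
            raise ValueError(
                f"order {order} labels require {order}-molecule clusters, "
                f"got {n} molecules"
            )
        if order == "total":
            energies[i] = potential.energy(cfg)
        elif order == 1:
            energies[i] = sum(
                mbe.subset_energy(cfg, potential, (m,)) for m in range(n)
            )
        else:
            energies[i] = mbe.nbody_term(cfg, potential, tuple(range(n)))
    if noise_sigma > 0:
        energies = energies + rng.normal(scale=noise_sigma, size=len(configs))
    return LabeledSet(
        configs=list(configs),
        energies=energies,
        order=order,
        level_tag=getattr(potential, "level_tag", "unknown"),
        noise_sigma=noise_sigma,
    )
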