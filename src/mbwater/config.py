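"""Molecular configurations: water clusters and periodic liquid boxes.

A :class:`Configuration` stores flat per-atom arrays plus a molecule index;
every molecule is one water (O, H, H in that order).  Cluster geometries have
``box_edge=None``; liquid boxes are cubic with periodic boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASS

#: reference (gas-phase) monomer geometry
R_OH_REF = 0.9572  # A
THETA_HOH_REF = np.deg2rad(104.52)

MAX_INTRAMOLECULAR_OH = 2.0  # A, validation bound


class ConfigurationError(ValueError):
    """Raised when a geometry violates the water-cluster contract."""


@dataclass
class Configuration:
    """Atomic coordinates partitioned into water molecules.

    Parameters
    ----------
    elements : list of str
        Atomic symbols, ``O``/``H`` only, ordered O,H,H per molecule.
    coords : (n_atoms, 3) float array
        Cartesian coordinates in angstrom.
    molecule_index : (n_atoms,) int array
        Molecule id of each atom; ids are 0..n_molecules-1.
    box_edge : float or None
        Cubic box edge in angstrom; ``None`` for a non-periodic cluster.
    """

    elements: list
    coords: np.ndarray
    molecule_index: np.ndarray
    box_edge: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)

    # -- basic geometry --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_atoms else 0

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[e] for e in self.elements])

    def molecule_atoms(self, i: int) -> np.ndarray:
        """Indices of the three atoms of molecule ``i`` (O first)."""
        return np.flatnonzero(self.molecule_index == i)

    def oxygen_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e == "O"])

    def oxygen_coords(self) -> np.ndarray:
        return self.coords[self.oxygen_indices()]

    def subset(self, molecule_ids) -> "Configuration":
        """Sub-cluster of the given molecules at frozen geometry."""
        molecule_ids = list(molecule_ids)
        atoms = np.concatenate([self.molecule_atoms(m) for m in molecule_ids])
        new_index = np.repeat(np.arange(len(molecule_ids)), 3)
        return Configuration(
            elements=[self.elements[a] for a in atoms],
            coords=self.coords[atoms].copy(),
            molecule_index=new_index,
            box_edge=None,
        )

    def copy(self) -> "Configuration":
        return replace(
            self,
            elements=list(self.elements),
            coords=self.coords.copy(),
            molecule_index=self.molecule_index.copy(),
            metadata=dict(self.metadata),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check the shared Configuration invariants; raise on violation."""
        if self.coords.shape != (self.n_atoms, 3):
            raise ConfigurationError("coords shape does not match elements")
        if len(self.molecule_index) != self.n_atoms:
            raise ConfigurationError("molecule_index length mismatch")
        if self.n_atoms % 3 != 0:
            raise ConfigurationError("atom count not a multiple of 3")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError("non-finite coordinates")
        for m in range(self.n_molecules):
            atoms = self.molecule_atoms(m)
            if len(atoms) != 3:
                raise ConfigurationError(
                    f"molecule {m} has {len(atoms)} atoms (want 3)"
                )
            symbols = [self.elements[a] for a in atoms]
            if symbols != ["O", "H", "H"]:
                raise ConfigurationError(
                    f"molecule {m} is not ordered O,H,H: {symbols}"
                )
            d = self.coords[atoms[1:]] - self.coords[atoms[0]]
            if self.box_edge is not None:
                d = minimum_image(d, self.box_edge)
            r = np.linalg.norm(d, axis=1)
            if np.any(r >= MAX_INTRAMOLECULAR_OH):
                raise ConfigurationError(
                    f"molecule {m} has O-H distance {r.max():.3f} A >= "
                    f"{MAX_INTRAMOLECULAR_OH} A"
                )
        if self.box_edge is not None and not self.box_edge > 0:
            raise ConfigurationError("box_edge must be positive")


def minimum_image(d: np.ndarray, box_edge: float) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return d - box_edge * np.round(d / box_edge)


def reference_monomer(r_oh: float = R_OH_REF,
                      theta: float = THETA_HOH_REF) -> np.ndarray:
    """Coordinates (3,3) of one water: O at origin, H's in the xz plane,
    HOH bisector along +z."""
    half = theta / 2.0
    o = np.zeros(3)
    h1 = np.array([r_oh * np.sin(half), 0.0, r_oh * np.cos(half)])
    h2 = np.array([-r_oh * np.sin(half), 0.0, r_oh * np.cos(half)])
    return np.stack([o, h1, h2])


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via normalized quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def perturbed_monomer(rng: np.random.Generator,
                      sigma_r: float = 0.02,
                      sigma_theta_deg: float = 2.0) -> np.ndarray:
    """Monomer with seeded Gaussian displacements of the internal coordinates."""
    r1 = R_OH_REF + rng.normal(scale=sigma_r)
    r2 = R_OH_REF + rng.normal(scale=sigma_r)
    th = THETA_HOH_REF + np.deg2rad(rng.normal(scale=sigma_theta_deg))
    half = th / 2.0
    o = np.zeros(3)
    h1 = np.array([r1 * np.sin(half), 0.0, r1 * np.cos(half)])
    h2 = np.array([-r2 * np.sin(half), 0.0, r2 * np.cos(half)])
    return np.stack([o, h1, h2])


def assemble(molecules: list[np.ndarray],
             box_edge: float | None = None) -> Configuration:
    """Stack per-molecule (3,3) coordinate blocks into a Configuration."""
    n = len(molecules)
    coords = np.concatenate(molecules, axis=0)
    return Configuration(
        elements=["O", "H", "H"] * n,
        coords=coords,
        molecule_index=np.repeat(np.arange(n), 3),
        box_edge=box_edge,
    )
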