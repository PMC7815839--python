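"""Core data containers: configurations, datasets, permutation groups.

A :class:`MolecularConfiguration` is the universal unit of I/O and
prediction: element symbols, Cartesian coordinates in Å, optionally an
energy (kcal/mol) and forces (kcal/mol/Å). A :class:`Dataset` is an ordered
collection sharing one species list, the training currency of the
gradient-domain force-field fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import ATOMIC_NUMBERS, mass_of

__all__ = ["MolecularConfiguration", "Dataset", "PermutationGroup"]


@dataclass
class MolecularConfiguration:
    species: tuple[str, ...]
    coordinates: np.ndarray            # (N, 3) Å
    energy: Optional[float] = None     # kcal/mol
    forces: Optional[np.ndarray] = None  # (N, 3) kcal/mol/Å

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.species)
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} species (expected ({n}, 3))"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite entries")
        if self.energy is not None:
            self.energy = float(self.energy)
            if not np.isfinite(self.energy):
                raise ValueError("energy is non-finite")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coordinates.shape:
                raise ValueError(
                    f"forces shape {self.forces.shape} does not match "
                    f"coordinates shape {self.coordinates.shape}"
                )
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("forces contain non-finite entries")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(s) for s in self.species])

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.species], dtype=int)

    def permuted(self, perm: Sequence[int]) -> "MolecularConfiguration":
        """Configuration with atoms reordered: new atom i is old atom perm[i]."""
        perm = np.asarray(perm, dtype=int)
        return MolecularConfiguration(
            species=tuple(self.species[p] for p in perm),
            coordinates=self.coordinates[perm],
            energy=self.energy,
            forces=None if self.forces is None else self.forces[perm],
        )

    def copy(self) -> "MolecularConfiguration":
        return MolecularConfiguration(
            self.species,
            self.coordinates.copy(),
            self.energy,
            None if self.forces is None else self.forces.copy(),
        )


@dataclass
class Dataset:
    """Ordered set of configurations with a common species list."""

    configurations: list[MolecularConfiguration]
    units: dict = field(default_factory=lambda: {
        "length": "Angstrom", "energy": "kcal/mol", "forces": "kcal/mol/Angstrom",
    })
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.configurations) == 0:
            raise ValueError("dataset must contain at least one configuration")
        ref = self.configurations[0].species
        for i, c in enumerate(self.configurations):
            if c.species != ref:
                raise ValueError(
                    f"configuration {i} species {c.species} differ from "
                    f"dataset species {ref}"
                )

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.configurations[i], dict(self.units),
                           dict(self.provenance))
        return self.configurations[i]

    @property
    def species(self) -> tuple[str, ...]:
        return self.configurations[0].species

    @property
    def has_energies(self) -> bool:
        return all(c.energy is not None for c in self.configurations)

    @property
    def has_forces(self) -> bool:
        return all(c.forces is not None for c in self.configurations)

    def coordinates_array(self) -> np.ndarray:
        """(M, N, 3) stack of coordinates."""
        return np.stack([c.coordinates for c in self.configurations])

    def energies_array(self) -> np.ndarray:
        if not self.has_energies:
            raise ValueError("dataset has configurations without energies")
        return np.array([c.energy for c in self.configurations])

    def forces_array(self) -> np.ndarray:
        if not self.has_forces:
            raise ValueError("dataset has configurations without forces")
        return np.stack([c.forces for c in self.configurations])

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset([self.configurations[i] for i in idx],
                       dict(self.units), dict(self.provenance))


class PermutationGroup:
    """Explicit group of atom-index permutations (symmetry prior).

    Each permutation maps new index -> old index, i.e. applying ``g`` to a
    configuration reorders atoms as ``coords[g]``. The identity is always
    included; each member must be a bijection that preserves the species
    list, so that a permuted configuration is physically indistinguishable.
    """

    def __init__(self, permutations: Sequence[Sequence[int]], n_atoms: int,
                 species: Optional[Sequence[str]] = None) -> None:
        perms = [np.asarray(p, dtype=int) for p in permutations]
        ident = np.arange(n_atoms)
        seen = set()
        checked = []
        for p in perms:
            if p.shape != (n_atoms,):
                raise ValueError(f"permutation {p} has wrong length for {n_atoms} atoms")
            if sorted(p.tolist()) != list(range(n_atoms)):
                raise ValueError(f"{p.tolist()} is not a bijection on 0..{n_atoms - 1}")
            if species is not None:
                sp = tuple(species)
                if tuple(sp[i] for i in p) != sp:
                    raise ValueError(
                        f"permutation {p.tolist()} changes the species list"
                    )
            key = tuple(p.tolist())
            if key not in seen:
                seen.add(key)
                checked.append(p)
        if tuple(ident.tolist()) not in seen:
            checked.insert(0, ident)
        self.permutations = checked
        self.n_atoms = n_atoms

    @classmethod
    def identity(cls, n_atoms: int) -> "PermutationGroup":
        return cls([], n_atoms)

    def __len__(self) -> int:
        return len(self.permutations)

    def __iter__(self):
        return iter(self.permutations)
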