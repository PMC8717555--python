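"""Domain types for the (Ala-Gly)_n crystal: cell spec, atoms, chains, crystal model.

Coordinates are Cartesian Angstrom throughout; orthorhombic cells only.  A
:class:`CrystalModel` stores wrapped coordinates (fractional in [0, 1)); chains that are
periodically closed (C-terminal carbonyl bonded to the N-terminus of the chain's own
periodic image along the propagation axis) carry a per-chain flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASSES
from .geometry import DEFAULT_GEOMETRY, RESIDUE_ATOMS

__all__ = ["TorsionTemplate", "UnitCellSpec", "AtomRecord", "ChainInfo", "Chain", "CrystalModel"]


@dataclass(frozen=True)
class TorsionTemplate:
    """Backbone torsion template (degrees) for the alternating Ala-Gly repeat.

    Defaults are the silk-I-like 3_10-helix torsions from the NMR/DFT literature on the
    (Ala-Gly)_n model: (phi, psi) = (-59, 119) for Ala and (-78, 149) for Gly.
    """

    phi_ala: float = -59.0
    psi_ala: float = 119.0
    phi_gly: float = -78.0
    psi_gly: float = 149.0

    def __post_init__(self):
        for name in ("phi_ala", "psi_ala", "phi_gly", "psi_gly"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"template angle {name}={v} outside (-180, 180]")

    def phi_psi(self, residue_name: str) -> tuple[float, float]:
        if residue_name == "ALA":
            return self.phi_ala, self.psi_ala
        if residue_name == "GLY":
            return self.phi_gly, self.psi_gly
        raise ValueError(f"unknown residue {residue_name!r}")


@dataclass(frozen=True)
class UnitCellSpec:
    """Construction parameters of the four-chain (Ala-Gly)_n silk-I orthorhombic cell.

    Cell defaults are the initial silk-I lattice parameters a = 17.8, b = 15.7558,
    c = 11.4904 Angstrom; all cell angles are fixed at 90 degrees.
    """

    a: float = 17.8
    b: float = 15.7558
    c: float = 11.4904
    n_chains: int = 4
    ag_repeats_per_chain: int = 4
    torsion_template: TorsionTemplate = field(default_factory=TorsionTemplate)
    omega: float = 180.0
    geometry: dict = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.ag_repeats_per_chain < 1:
            raise ValueError("ag_repeats_per_chain must be >= 1")

    @property
    def cell(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, PDB-convention name, residue identity, chain, position (A)."""

    element: str
    atom_name: str
    residue_index: int          # 1-based within the chain
    residue_name: str           # ALA or GLY
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        if self.residue_name not in RESIDUE_ATOMS:
            raise ValueError(f"unknown residue {self.residue_name!r}")
        if self.atom_name not in RESIDUE_ATOMS[self.residue_name]:
            raise ValueError(f"atom {self.atom_name!r} not in {self.residue_name} dictionary")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite position")


@dataclass(frozen=True)
class ChainInfo:
    chain_id: str
    start: int                  # atom index range [start, stop) in the model arrays
    stop: int
    periodic_closure: bool = True


@dataclass
class Chain:
    """An open chain fresh from the internal-coordinate builder (unwrapped coords).

    ``next_n`` is where the N of the (n+1)-th residue would go if growth continued;
    the periodic-closure machinery maps it onto the image of the first N.
    """

    positions: np.ndarray       # (n_atoms, 3)
    atom_names: list
    elements: list
    residue_names: list         # per atom
    residue_indices: np.ndarray  # per atom, 1-based
    next_n: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices[-1])

    def backbone_index(self, residue_index: int, atom_name: str) -> int:
        mask = (self.residue_indices == residue_index)
        for i in np.nonzero(mask)[0]:
            if self.atom_names[i] == atom_name:
                return int(i)
        raise KeyError(f"{atom_name} of residue {residue_index} not found")


@dataclass
class CrystalModel:
    """Assembled crystal: flat atom arrays, orthorhombic cell, per-chain ranges."""

    positions: np.ndarray       # (n_atoms, 3) wrapped Cartesian A
    elements: np.ndarray
    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_indices: np.ndarray  # 1-based within chain
    chain_ids: np.ndarray
    cell: np.ndarray            # (3,)
    chains: list = field(default_factory=list)   # list[ChainInfo]

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return sum(int(self.residue_indices[c.stop - 1]) for c in self.chains)

    def wrap(self) -> "CrystalModel":
        """Wrap coordinates into the cell (fractional in [0, 1)); idempotent."""
        frac = self.positions / self.cell
        wrapped = (frac - np.floor(frac)) * self.cell
        return replace(self, positions=wrapped)

    def mass(self) -> float:
        """Total mass in g/mol."""
        return float(sum(ATOMIC_MASSES[e] for e in self.elements))

    def chain_slice(self, chain_id: str) -> slice:
        for c in self.chains:
            if c.chain_id == chain_id:
                return slice(c.start, c.stop)
        raise KeyError(f"no chain {chain_id!r}")

    def iter_atoms(self):
        """Yield :class:`AtomRecord` views of the flat arrays."""
        for i in range(self.n_atoms):
            yield AtomRecord(
                element=str(self.elements[i]),
                atom_name=str(self.atom_names[i]),
                residue_index=int(self.residue_indices[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.positions[i],
            )

    def element_counts(self) -> dict:
        uniq, counts = np.unique(self.elements, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))
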