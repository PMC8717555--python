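"""Trajectory container: ordered frames of positions, cell, times and image counts.

Wrapped coordinates live in ``positions``; periodic wrap jumps are recorded as integer
``images`` so that unwrapped displacements are exact (``unwrapped = positions +
images * cell``).  Trajectories without a cell (e.g. rebuilt single chains) are treated
as already unwrapped.  Mean-square-displacement analysis refuses wrapped trajectories
that carry no image information — unwrapping is never inferred heuristically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "UnwrapError"]


class UnwrapError(ValueError):
    """The trajectory is wrapped but carries no image counts."""


@dataclass
class Trajectory:
    positions: np.ndarray                 # (n_frames, n_atoms, 3), wrapped if cell given
    times_ps: np.ndarray                  # (n_frames,)
    cell: np.ndarray | None = None        # (3,) orthorhombic lengths, or None
    images: np.ndarray | None = None      # (n_frames, n_atoms, 3) ints, or None
    atom_names: np.ndarray | None = None
    residue_names: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if len(self.times_ps) != self.n_frames:
            raise ValueError("times_ps length does not match frame count")
        if self.n_frames > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
        if self.images is not None:
            self.images = np.asarray(self.images)
            if self.images.shape != self.positions.shape:
                raise ValueError("images shape does not match positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def unwrapped(self) -> np.ndarray:
        """Exact unwrapped coordinates, (n_frames, n_atoms, 3)."""
        if self.cell is None:
            return self.positions
        if self.images is None:
            raise UnwrapError(
                "trajectory is wrapped but has no image counts; MSD on wrapped "
                "coordinates is invalid and heuristic unwrapping is not performed")
        return self.positions + self.images * self.cell

    def select(self, selection=None) -> np.ndarray:
        """Resolve a selection to atom indices.

        ``None``/"all" selects everything; "water-O" selects oxygen atoms of HOH
        residues (the generator's tracers are all such atoms); otherwise an explicit
        index array/boolean mask is accepted.
        """
        if selection is None or (isinstance(selection, str) and selection == "all"):
            return np.arange(self.n_atoms)
        if isinstance(selection, str):
            if selection == "water-O":
                if self.atom_names is None or self.residue_names is None:
                    raise ValueError("trajectory has no atom metadata for selection")
                idx = np.nonzero((self.atom_names == "O") &
                                 (self.residue_names == "HOH"))[0]
            else:
                raise ValueError(f"unknown selection {selection!r}")
        else:
            idx = np.asarray(selection)
            if idx.dtype == bool:
                idx = np.nonzero(idx)[0]
        if len(idx) == 0:
            raise ValueError("empty selection")
        return idx
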