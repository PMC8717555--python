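"""Random insertion of rigid three-site waters under a minimum-distance constraint.

Waters are placed with uniformly random oxygen positions and uniformly random rigid
orientations, accepted only when every water atom keeps at least ``min_dist`` (default
1.7 A) from every silk atom — and, as a deliberate extension, from every previously
placed water atom — under the orthorhombic minimum-image convention.  The water counts
matching the reference hydrated systems are 67 for the 2x2x2 supercell and 538 for the
4x4x4 supercell (fixed by the printed hydrated atom totals 2377 and 19,022).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import ATOMIC_MASSES, WATER_MOLAR_MASS
from .model import CrystalModel

__all__ = ["HydratedModel", "insert_waters", "water_mass_fraction", "PlacementError",
           "WATER_COUNT_2x2x2", "WATER_COUNT_4x4x4", "water_template"]

#: Water counts reproducing the reference hydrated atom totals.
WATER_COUNT_2x2x2 = 67    # (2377 - 2176) / 3
WATER_COUNT_4x4x4 = 538   # (19022 - 17408) / 3

#: Rigid three-site water geometry: O-H 0.9572 A, H-O-H 104.52 deg.
OH_BOND = 0.9572
HOH_ANGLE_DEG = 104.52


class PlacementError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""

    def __init__(self, placed: int, requested: int, max_attempts: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed}/{requested} waters within "
            f"{max_attempts} attempts per water")


@dataclass
class HydratedModel:
    """A crystal model plus inserted rigid waters.

    ``waters`` has shape (n_waters, 3, 3): per water the O, H1, H2 positions (A,
    wrapped into the cell).
    """

    base: CrystalModel
    waters: np.ndarray
    min_dist: float
    seed: int

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def n_atoms(self) -> int:
        return self.base.n_atoms + 3 * self.n_waters

    def water_positions_flat(self) -> np.ndarray:
        return self.waters.reshape(-1, 3)

    def mass(self) -> float:
        return self.base.mass() + self.n_waters * (
            ATOMIC_MASSES["O"] + 2 * ATOMIC_MASSES["H"])


def water_template() -> np.ndarray:
    """O at the origin, H1 on +x, H2 in the xy-plane at the H-O-H angle."""
    ang = math.radians(HOH_ANGLE_DEG)
    return np.array([
        [0.0, 0.0, 0.0],
        [OH_BOND, 0.0, 0.0],
        [OH_BOND * math.cos(ang), OH_BOND * math.sin(ang), 0.0],
    ])


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed to +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def min_image_distances(points: np.ndarray, others: np.ndarray,
                        cell: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances (n_points, n_others) in an orthorhombic cell."""
    d = points[:, None, :] - others[None, :, :]
    d -= cell * np.round(d / cell)
    return np.linalg.norm(d, axis=-1)


def insert_waters(model: CrystalModel, n_waters: int, min_dist: float = 1.7,
                  seed: int = 0, max_attempts_per_water: int = 10_000) -> HydratedModel:
    """Insert ``n_waters`` rigid three-site waters by rejection sampling.

    Deterministic for a fixed seed.  Raises :class:`PlacementError` (reporting how
    many were placed) if any water exhausts ``max_attempts_per_water``.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    cell = model.cell
    waters = np.empty((n_waters, 3, 3))
    if n_waters == 0:
        return HydratedModel(base=model, waters=waters, min_dist=min_dist, seed=seed)

    rng = np.random.default_rng(seed)
    template = water_template()
    template = template - template[0]
    # silk neighbour lookup: periodic KD-tree on wrapped silk coordinates
    wrapped = model.wrap().positions
    # guard against coordinates landing exactly on the box edge due to rounding
    wrapped = np.mod(wrapped, cell)
    tree = cKDTree(wrapped, boxsize=cell)

    placed_flat: list = []
    for wi in range(n_waters):
        ok = False
        for _ in range(max_attempts_per_water):
            o_pos = rng.uniform(0.0, 1.0, size=3) * cell
            rot = _random_rotation(rng)
            atoms = o_pos + template @ rot.T
            atoms_wrapped = np.mod(atoms, cell)
            if tree.query(atoms_wrapped, k=1)[0].min() < min_dist:
                continue
            if placed_flat:
                prev = np.asarray(placed_flat)
                if min_image_distances(atoms_wrapped, prev, cell).min() < min_dist:
                    continue
            waters[wi] = atoms_wrapped
            placed_flat.extend(atoms_wrapped)
            ok = True
            break
        if not ok:
            raise PlacementError(wi, n_waters, max_attempts_per_water)
    return HydratedModel(base=model, waters=waters, min_dist=min_dist, seed=seed)


def water_mass_fraction(model: HydratedModel) -> float:
    """Mass fraction of water: n * m_H2O / (m_silk + n * m_H2O), standard weights."""
    water_mass = model.n_waters * WATER_MOLAR_MASS
    return water_mass / (model.base.mass() + water_mass)
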