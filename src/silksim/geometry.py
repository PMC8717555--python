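"""Internal-coordinate peptide geometry: the bond/angle table and NeRF atom placement.

The crystal builder grows chains atom-by-atom from internal coordinates (bond length,
bond angle, dihedral to three already-placed reference atoms).  The numerical values of
the backbone and side-chain geometry are standard peptide geometry and are collected in
one overridable table, :data:`DEFAULT_GEOMETRY`; a YAML file with the same keys may be
loaded with :func:`load_geometry` to replace any subset of entries.
"""

from __future__ import annotations

import math

import numpy as np
import yaml

__all__ = ["DEFAULT_GEOMETRY", "load_geometry", "place_atom", "dihedral", "dihedral_batch"]

#: Standard peptide internal geometry.  Bond lengths in Angstrom, angles in degrees.
#: ``branch_offsets`` are dihedral offsets (deg) of CA substituents relative to the
#: backbone carbonyl carbon, i.e. dihedral(C_prev, N, CA, X) = phi + offset.
DEFAULT_GEOMETRY = {
    "bonds": {
        "C-N": 1.329,    # peptide bond
        "N-CA": 1.458,
        "CA-C": 1.525,
        "C=O": 1.231,
        "N-H": 1.010,
        "CA-HA": 1.090,
        "CA-CB": 1.521,
        "CB-HB": 1.090,
    },
    "angles": {
        "CA-C-N": 116.2,   # at the carbonyl carbon, toward the next residue
        "C-N-CA": 121.7,
        "N-CA-C": 111.2,
        "CA-C-O": 120.8,
        "C-N-H": 119.2,
        "N-CA-HA": 109.5,
        "N-CA-CB": 110.4,
        "CA-CB-HB": 110.5,
    },
    # dihedral(C_prev, N, CA, X) = phi + offset for CA substituents
    "branch_offsets": {
        "HA": 119.0,     # Ala alpha hydrogen
        "CB": -121.0,    # Ala side-chain carbon
        "HA1": 119.0,    # Gly alpha hydrogens
        "HA2": -121.0,
    },
    # dihedral(HBk, CB, CA, N): staggered methyl rotamer
    "methyl_dihedrals": [60.0, 180.0, 300.0],
}

#: Per-residue atom dictionaries (PDB atom-name convention, storage order).
RESIDUE_ATOMS = {
    "ALA": ["N", "H", "CA", "HA", "CB", "HB1", "HB2", "HB3", "C", "O"],
    "GLY": ["N", "H", "CA", "HA1", "HA2", "C", "O"],
}

RESIDUE_ELEMENTS = {
    "ALA": ["N", "H", "C", "H", "C", "H", "H", "H", "C", "O"],
    "GLY": ["N", "H", "C", "H", "H", "C", "O"],
}

#: Atoms per Ala-Gly repeat (10 + 7).
ATOMS_PER_AG_REPEAT = len(RESIDUE_ATOMS["ALA"]) + len(RESIDUE_ATOMS["GLY"])


class GeometryError(KeyError):
    """A required internal-geometry entry is missing from the table."""


def load_geometry(path) -> dict:
    """Load a geometry table from YAML, filling unspecified entries from the default."""
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    table = {k: dict(v) if isinstance(v, dict) else list(v) for k, v in DEFAULT_GEOMETRY.items()}
    for section, values in override.items():
        if section not in table:
            raise GeometryError(f"unknown geometry section {section!r}")
        if isinstance(table[section], dict):
            table[section].update(values)
        else:
            table[section] = list(values)
    return table


def _geom(table: dict, section: str, key: str) -> float:
    try:
        return table[section][key]
    except KeyError as exc:
        raise GeometryError(f"missing geometry entry {section}:{key}") from exc


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to *a* with |D-a| = bond, angle(D,a,b) = angle and
    dihedral(D,a,b,c) = dihedral (NeRF construction)."""
    theta = math.radians(angle_deg)
    tau = math.radians(dihedral_deg)
    ab = a - b
    ab /= np.linalg.norm(ab)
    cb = b - c
    n = np.cross(cb, ab)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("degenerate reference frame: a, b, c are colinear")
    n /= norm_n
    m = np.cross(n, ab)
    # local displacement in the (ab, m, n) frame
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        bond * math.sin(theta) * math.sin(tau),
    ])
    return a + d[0] * ab + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    return float(dihedral_batch(np.asarray(p0)[None], np.asarray(p1)[None],
                                np.asarray(p2)[None], np.asarray(p3)[None])[0])


def dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Vectorised signed dihedral (degrees) for stacked quadruples of points.

    Raises :class:`ValueError` when any quadruple is degenerate (three consecutive
    points colinear, so the torsion is undefined).
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    denom = np.linalg.norm(n1, axis=-1) * np.linalg.norm(n2, axis=-1)
    if np.any(denom < 1e-12):
        raise ValueError("undefined dihedral: colinear atoms")
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(b1n, n1) * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def wrap_angle(angle):
    """Wrap angles (deg) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)
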