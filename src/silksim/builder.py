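"""Construction of the four-chain (Ala-Gly)_n silk-I unit cell and supercells.

Chains are grown by sequential internal-coordinate (NeRF) placement from a backbone
torsion template, rotated so the chain propagation axis lies along the crystal c axis,
and periodically closed: the C-terminal carbonyl carbon bonds to the N-terminus of the
chain's own periodic image.  Closure is made exact by distributing the (small) mismatch
between the chain's natural period and the cell length homogeneously along the chain,
so the virtual next N lands exactly on the image of the first N.
"""

from __future__ import annotations

import numpy as np

from .geometry import (DEFAULT_GEOMETRY, RESIDUE_ATOMS, RESIDUE_ELEMENTS,
                       GeometryError, _geom, place_atom)
from .model import Chain, ChainInfo, CrystalModel, TorsionTemplate, UnitCellSpec

__all__ = ["build_chain", "build_unit_cell", "replicate", "ConstructionError",
           "DEFAULT_CHAIN_OFFSETS"]

#: Fractional (a, b) offsets of the four chains in the unit cell.
DEFAULT_CHAIN_OFFSETS = ((0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5))

#: Maximum admissible homogeneous strain per atom step (A) when closing a chain onto
#: its periodic image; larger mismatches indicate the chain does not fit the cell.
MAX_CLOSURE_STRAIN_PER_ATOM = 0.2


class ConstructionError(ValueError):
    """The requested crystal cannot be assembled."""


def _chain_residues(n_repeats: int):
    names = []
    for _ in range(n_repeats):
        names.extend(["ALA", "GLY"])
    return names


def build_chain_from_torsions(phi, psi, residue_names=None, omega: float = 180.0,
                              geometry: dict | None = None) -> Chain:
    """Grow a single chain from per-residue (phi, psi) torsions (degrees).

    ``residue_names`` defaults to the alternating ALA/GLY sequence.  The chain is open;
    the would-be next backbone nitrogen is recorded as ``next_n`` for closure.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1 or len(phi) < 1:
        raise ValueError("phi and psi must be equal-length 1-D sequences")
    n_res = len(phi)
    if residue_names is None:
        if n_res % 2:
            raise ValueError("alternating Ala-Gly chain needs an even residue count")
        residue_names = _chain_residues(n_res // 2)
    if len(residue_names) != n_res:
        raise ValueError("residue_names length does not match torsions")
    g = geometry or DEFAULT_GEOMETRY

    b_cn = _geom(g, "bonds", "C-N")
    b_nca = _geom(g, "bonds", "N-CA")
    b_cac = _geom(g, "bonds", "CA-C")
    b_co = _geom(g, "bonds", "C=O")
    b_nh = _geom(g, "bonds", "N-H")
    b_caha = _geom(g, "bonds", "CA-HA")
    b_cacb = _geom(g, "bonds", "CA-CB")
    b_cbhb = _geom(g, "bonds", "CB-HB")
    a_cacn = _geom(g, "angles", "CA-C-N")
    a_cnca = _geom(g, "angles", "C-N-CA")
    a_ncac = _geom(g, "angles", "N-CA-C")
    a_caco = _geom(g, "angles", "CA-C-O")
    a_cnh = _geom(g, "angles", "C-N-H")
    a_ncaha = _geom(g, "angles", "N-CA-HA")
    a_ncacb = _geom(g, "angles", "N-CA-CB")
    a_cacbhb = _geom(g, "angles", "CA-CB-HB")
    branch = g["branch_offsets"]
    methyl = g["methyl_dihedrals"]

    positions, names, elements, res_names, res_idx = [], [], [], [], []

    # Virtual residue-0 backbone frame bootstraps the first residue so that even
    # residue 1 honours its phi; psi_0 is an arbitrary fixed value (dropped afterwards).
    n_prev = np.array([0.0, 1.0, 0.0])
    ca_prev = np.array([0.0, 0.0, 0.0])
    c_prev = np.array([b_cac, 0.0, 0.0])
    psi_prev = 150.0

    for i, rname in enumerate(residue_names):
        if rname not in RESIDUE_ATOMS:
            raise ValueError(f"unsupported residue {rname!r}")
        # backbone
        n_i = place_atom(c_prev, ca_prev, n_prev, b_cn, a_cacn, psi_prev)
        h_i = place_atom(n_i, c_prev, ca_prev, b_nh, a_cnh, omega + 180.0)
        ca_i = place_atom(n_i, c_prev, ca_prev, b_nca, a_cnca, omega)
        c_i = place_atom(ca_i, n_i, c_prev, b_cac, a_ncac, phi[i])
        o_i = place_atom(c_i, ca_i, n_i, b_co, a_caco, psi[i] + 180.0)
        atoms = {"N": n_i, "H": h_i, "CA": ca_i, "C": c_i, "O": o_i}
        if rname == "ALA":
            atoms["HA"] = place_atom(ca_i, n_i, c_prev, b_caha, a_ncaha,
                                     phi[i] + branch["HA"])
            cb = place_atom(ca_i, n_i, c_prev, b_cacb, a_ncacb, phi[i] + branch["CB"])
            atoms["CB"] = cb
            for k, tau in enumerate(methyl, start=1):
                atoms[f"HB{k}"] = place_atom(cb, ca_i, n_i, b_cbhb, a_cacbhb, tau)
        else:  # GLY
            atoms["HA1"] = place_atom(ca_i, n_i, c_prev, b_caha, a_ncaha,
                                      phi[i] + branch["HA1"])
            atoms["HA2"] = place_atom(ca_i, n_i, c_prev, b_caha, a_ncaha,
                                      phi[i] + branch["HA2"])
        for name, element in zip(RESIDUE_ATOMS[rname], RESIDUE_ELEMENTS[rname]):
            positions.append(atoms[name])
            names.append(name)
            elements.append(element)
            res_names.append(rname)
            res_idx.append(i + 1)
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
        psi_prev = psi[i]

    next_n = place_atom(c_prev, ca_prev, n_prev, b_cn, a_cacn, psi_prev)
    return Chain(positions=np.array(positions), atom_names=names, elements=elements,
                 residue_names=res_names, residue_indices=np.array(res_idx, dtype=int),
                 next_n=next_n)


def build_chain(template: TorsionTemplate, n_repeats: int, omega: float = 180.0,
                geometry: dict | None = None) -> Chain:
    """Build one open (Ala-Gly)_n chain (17 atoms per repeat) from a torsion template."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    residues = _chain_residues(n_repeats)
    phi = [template.phi_psi(r)[0] for r in residues]
    psi = [template.phi_psi(r)[1] for r in residues]
    return build_chain_from_torsions(phi, psi, residues, omega=omega, geometry=geometry)


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit(v) onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # v anti-parallel to z: flip about x
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def close_chain_periodically(chain: Chain, period: float) -> Chain:
    """Orient the chain along +z and strain it so its repeat period equals *period*.

    The chain propagation vector (first N to virtual next N) is rotated onto +z; each
    atom is then displaced along z in proportion to its sequence position so that the
    virtual next N coincides exactly with the first N translated by (0, 0, period).
    """
    first_n = chain.positions[0]
    v = chain.next_n - first_n
    R = _rotation_onto_z(v)
    pos = (chain.positions - first_n) @ R.T
    next_n = (chain.next_n - first_n) @ R.T
    length = next_n[2]
    mismatch = period - length
    n = chain.n_atoms
    if abs(mismatch) / n > MAX_CLOSURE_STRAIN_PER_ATOM:
        raise ConstructionError(
            f"chain of natural period {length:.2f} A does not fit cell length "
            f"{period:.2f} A within the closure tolerance")
    # First N stays put; the virtual next N has t = 1.  The terminal carbonyl C and O
    # (last two atoms) are pinned at t = 1 as well so the closure peptide bond keeps
    # its ideal length instead of absorbing a share of the strain.
    t = np.minimum(np.arange(n) / max(n - 2, 1), 1.0)
    pos = pos + np.outer(t * mismatch, [0.0, 0.0, 1.0])
    next_n = next_n + np.array([0.0, 0.0, mismatch])
    return Chain(positions=pos, atom_names=list(chain.atom_names),
                 elements=list(chain.elements), residue_names=list(chain.residue_names),
                 residue_indices=chain.residue_indices.copy(), next_n=next_n)


_CHAIN_ID_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _chain_id(i: int) -> str:
    if i < len(_CHAIN_ID_ALPHABET):
        return _CHAIN_ID_ALPHABET[i]
    return f"{_CHAIN_ID_ALPHABET[i % len(_CHAIN_ID_ALPHABET)]}{i // len(_CHAIN_ID_ALPHABET)}"


def build_unit_cell(spec: UnitCellSpec | None = None,
                    chain_offsets=None) -> CrystalModel:
    """Assemble the orthorhombic unit cell: n_chains periodically closed chains at
    fractional (a, b) offsets, propagating along c.

    The default spec yields 272 atoms (4 chains x 4 Ala-Gly repeats x 17 atoms).
    """
    spec = spec or UnitCellSpec()
    if chain_offsets is None:
        chain_offsets = DEFAULT_CHAIN_OFFSETS[:spec.n_chains] \
            if spec.n_chains <= 4 else None
    if chain_offsets is None or len(chain_offsets) != spec.n_chains:
        raise ConstructionError(
            f"need exactly {spec.n_chains} chain offsets, got "
            f"{0 if chain_offsets is None else len(chain_offsets)}")
    offs = [tuple(np.round(np.asarray(o, dtype=float) % 1.0, 9)) for o in chain_offsets]
    if len(set(offs)) != len(offs):
        raise ConstructionError("chain offsets must be distinct")

    proto = build_chain(spec.torsion_template, spec.ag_repeats_per_chain,
                        omega=spec.omega, geometry=spec.geometry)
    try:
        proto = close_chain_periodically(proto, spec.c)
    except ConstructionError as exc:
        raise ConstructionError(f"chain A: {exc}") from exc

    positions, elements, names, res_names, res_idx, chain_ids, chains = \
        [], [], [], [], [], [], []
    centroid_xy = proto.positions[:, :2].mean(axis=0)
    for ci, (fx, fy) in enumerate(offs):
        cid = _chain_id(ci)
        shift = np.array([fx * spec.a - centroid_xy[0], fy * spec.b - centroid_xy[1], 0.0])
        pos = proto.positions + shift
        start = sum(len(p) for p in positions)
        positions.append(pos)
        elements.extend(proto.elements)
        names.extend(proto.atom_names)
        res_names.extend(proto.residue_names)
        res_idx.extend(proto.residue_indices.tolist())
        chain_ids.extend([cid] * proto.n_atoms)
        chains.append(ChainInfo(cid, start, start + proto.n_atoms, periodic_closure=True))

    model = CrystalModel(
        positions=np.vstack(positions),
        elements=np.array(elements),
        atom_names=np.array(names),
        residue_names=np.array(res_names),
        residue_indices=np.array(res_idx, dtype=int),
        chain_ids=np.array(chain_ids),
        cell=spec.cell,
        chains=chains,
    )
    return model.wrap()


def chain_model(chain: Chain, cell=(1000.0, 1000.0, 1000.0),
                closed: bool = False, chain_id: str = "A") -> CrystalModel:
    """Wrap a single chain as a :class:`CrystalModel` (open by default, huge cell).

    Useful for running coordinate-level analyses on chains straight from the builder
    without assembling a crystal.
    """
    n = chain.n_atoms
    return CrystalModel(
        positions=chain.positions.copy(),
        elements=np.array(chain.elements),
        atom_names=np.array(chain.atom_names),
        residue_names=np.array(chain.residue_names),
        residue_indices=chain.residue_indices.copy(),
        chain_ids=np.array([chain_id] * n),
        cell=np.asarray(cell, dtype=float),
        chains=[ChainInfo(chain_id, 0, n, periodic_closure=closed)],
    )


def replicate(model: CrystalModel, nx: int, ny: int, nz: int) -> CrystalModel:
    """Replicate a crystal model into an (nx, ny, nz) supercell.

    Images along the chain-propagation axis (z) are concatenated into single longer
    chains so periodic closure is re-established across the enlarged cell; x/y images
    become new chains.  Atom count multiplies by nx*ny*nz.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("replication counts must be >= 1")
    if (nx, ny, nz) == (1, 1, 1):
        return model
    a, b, c = model.cell
    positions, elements, names, res_names, res_idx, chain_ids, chains = \
        [], [], [], [], [], [], []
    new_ci = 0
    cursor = 0
    for ch in model.chains:
        sl = slice(ch.start, ch.stop)
        n_res = int(model.residue_indices[sl][-1]) if ch.stop > ch.start else 0
        n_at = ch.stop - ch.start
        for ix in range(nx):
            for iy in range(ny):
                cid = _chain_id(new_ci)
                new_ci += 1
                for iz in range(nz):
                    shift = np.array([ix * a, iy * b, iz * c])
                    positions.append(model.positions[sl] + shift)
                    elements.extend(model.elements[sl].tolist())
                    names.extend(model.atom_names[sl].tolist())
                    res_names.extend(model.residue_names[sl].tolist())
                    res_idx.extend((model.residue_indices[sl] + iz * n_res).tolist())
                    chain_ids.extend([cid] * n_at)
                chains.append(ChainInfo(cid, cursor, cursor + n_at * nz,
                                        periodic_closure=ch.periodic_closure))
                cursor += n_at * nz
    out = CrystalModel(
        positions=np.vstack(positions),
        elements=np.array(elements),
        atom_names=np.array(names),
        residue_names=np.array(res_names),
        residue_indices=np.array(res_idx, dtype=int),
        chain_ids=np.array(chain_ids),
        cell=np.array([nx * a, ny * b, nz * c]),
        chains=chains,
    )
    return out.wrap()
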