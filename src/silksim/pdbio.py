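"""PDB reading/writing for crystal and hydrated models (via gemmi).

CRYST1 carries the orthorhombic cell (90 degree angles, P 1); silk chains use IDs
A, B, C, ...; inserted waters are appended as HOH residues on their own chain.  TER
records are omitted for periodically closed chains, which is noted in a REMARK.
Round trips preserve atom order, names, chain IDs, the cell and coordinates to the
format's 3-decimal precision.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .geometry import RESIDUE_ATOMS
from .model import ChainInfo, CrystalModel
from .hydration import HydratedModel

__all__ = ["write_pdb", "read_pdb", "PDBFormatError"]

WATER_CHAIN_ID = "W"


class PDBFormatError(ValueError):
    """Input PDB cannot be interpreted as a crystal model."""


def write_pdb(obj: CrystalModel | HydratedModel, path, remarks=None):
    """Write a model (optionally hydrated) as PDB."""
    if isinstance(obj, HydratedModel):
        model, waters = obj.base, obj.waters
    else:
        model, waters = obj, None
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    for ch in model.chains:
        chain = gemmi.Chain(ch.chain_id)
        res = None
        last_idx = None
        for i in range(ch.start, ch.stop):
            ridx = int(model.residue_indices[i])
            if ridx != last_idx:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.residue_names[i])
                res.seqid = gemmi.SeqId(ridx, " ")
                res.het_flag = "A"
                last_idx = ridx
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.positions[i])
            atom.occ = 1.0
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        gm.add_chain(chain)
    if waters is not None and len(waters):
        wchain = gemmi.Chain(WATER_CHAIN_ID)
        for wi, w in enumerate(waters, start=1):
            res = gemmi.Residue()
            res.name = "HOH"
            res.seqid = gemmi.SeqId(wi, " ")
            res.het_flag = "H"
            for name, el, pos in zip(("O", "H1", "H2"), ("O", "H", "H"), w):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                res.add_atom(atom)
            wchain.add_residue(res)
        gm.add_chain(wchain)
    st.add_model(gm)
    closed = [c.chain_id for c in model.chains if c.periodic_closure]
    lines = [f"REMARK 300 PERIODICALLY CLOSED CHAINS (NO TER): {' '.join(closed)}"]
    if remarks:
        lines.extend(f"REMARK 300 {r}" for r in remarks)
    st.raw_remarks = lines
    doc = st.make_pdb_string(gemmi.PdbWriteOptions(cryst1_record=True,
                                                   ter_records=False,
                                                   end_record=True))
    with open(path, "w") as fh:
        fh.write(doc)


def read_pdb(path):
    """Read a PDB into ``(CrystalModel, waters)``.

    ``waters`` has shape (n_waters, 3, 3) (possibly empty).  A file without a CRYST1
    cell is rejected ("missing cell").
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(str(exc)) from exc
    if st.cell.a <= 1.0 and st.cell.b <= 1.0 and st.cell.c <= 1.0:
        raise PDBFormatError(f"{path}: missing cell (no CRYST1 record)")
    cell = np.array([st.cell.a, st.cell.b, st.cell.c])
    positions, elements, names, res_names, res_idx, chain_ids, chains = \
        [], [], [], [], [], [], []
    waters = []
    for chain in st[0]:
        is_water = all(r.name == "HOH" for r in chain)
        if is_water and len(chain) > 0:
            for r in chain:
                try:
                    pos = {a.name: [a.pos.x, a.pos.y, a.pos.z] for a in r}
                    waters.append([pos["O"], pos["H1"], pos["H2"]])
                except KeyError as exc:
                    raise PDBFormatError(
                        f"water {r.seqid.num} missing atom {exc}") from exc
            continue
        start = len(positions)
        for r in chain:
            if r.name not in RESIDUE_ATOMS:
                raise PDBFormatError(
                    f"chain {chain.name}: unsupported residue {r.name!r}")
            for a in r:
                positions.append([a.pos.x, a.pos.y, a.pos.z])
                elements.append(a.element.name)
                names.append(a.name)
                res_names.append(r.name)
                res_idx.append(r.seqid.num)
                chain_ids.append(chain.name)
        chains.append(ChainInfo(chain.name, start, len(positions),
                                periodic_closure=True))
    model = CrystalModel(
        positions=np.array(positions).reshape(-1, 3),
        elements=np.array(elements), atom_names=np.array(names),
        residue_names=np.array(res_names),
        residue_indices=np.array(res_idx, dtype=int),
        chain_ids=np.array(chain_ids), cell=cell, chains=chains)
    return model, np.array(waters).reshape(-1, 3, 3)
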