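"""Multi-frame trajectory I/O (extended XYZ and multi-model PDB) plus JSON sidecars.

The extended-XYZ dialect is one block per frame::

    <n_atoms>
    cell= a b c time_ps= t columns= element x y z [ix iy iz]
    El  x y z [ix iy iz]
    ...

Coordinates are wrapped; integer image counts (when present) make unwrapped
displacements exact, so generator output survives a round trip losslessly at the
stated precision.  Generator ground truth (the :class:`~silksim.dynamics.DynamicsConfig`)
travels in a JSON sidecar next to the trajectory.
"""

from __future__ import annotations

import json

import numpy as np

from .dynamics import DynamicsConfig
from .trajectory import Trajectory

__all__ = ["write_xyz", "read_xyz", "write_multi_pdb", "read_multi_pdb",
           "write_sidecar", "read_sidecar", "TrajectoryFormatError"]

_COORD_FMT = "%.6f"


class TrajectoryFormatError(ValueError):
    pass


def write_xyz(traj: Trajectory, path, extra_comment: str = ""):
    """Write a trajectory as extended multi-frame XYZ."""
    has_images = traj.images is not None
    elements = (traj.atom_names if traj.atom_names is not None
                else np.array(["X"] * traj.n_atoms))
    cols = "element x y z" + (" ix iy iz" if has_images else "")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            cell = traj.cell if traj.cell is not None else (0.0, 0.0, 0.0)
            comment = (f"cell= {cell[0]:.6f} {cell[1]:.6f} {cell[2]:.6f} "
                       f"time_ps= {traj.times_ps[f]:.6f} columns= {cols}")
            if extra_comment:
                comment += f" {extra_comment}"
            fh.write(comment + "\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.positions[f, a]
                line = f"{elements[a]} {x:.6f} {y:.6f} {z:.6f}"
                if has_images:
                    ix, iy, iz = traj.images[f, a]
                    line += f" {ix:d} {iy:d} {iz:d}"
                fh.write(line + "\n")


def _parse_comment(line: str, lineno: int) -> dict:
    tokens = line.split()
    out = {}
    key = None
    for tok in tokens:
        if tok.endswith("="):
            key = tok[:-1]
            out[key] = []
        elif key is not None:
            out[key].append(tok)
    if "cell" not in out or len(out["cell"]) != 3:
        raise TrajectoryFormatError(f"line {lineno}: comment lacks 'cell= a b c'")
    if "time_ps" not in out or len(out["time_ps"]) != 1:
        raise TrajectoryFormatError(f"line {lineno}: comment lacks 'time_ps= t'")
    return out


def read_xyz(path) -> Trajectory:
    """Read an extended multi-frame XYZ trajectory."""
    frames, times, images_all = [], [], []
    names = None
    cell = None
    has_images = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 1 + n > len(lines):
            raise TrajectoryFormatError(f"line {i + 1}: truncated frame")
        meta = _parse_comment(lines[i + 1], i + 2)
        c = np.array([float(v) for v in meta["cell"]])
        frame_cell = None if np.all(c == 0) else c
        if cell is None:
            cell = frame_cell
        times.append(float(meta["time_ps"][0]))
        pos = np.empty((n, 3))
        imgs = np.empty((n, 3), dtype=int)
        frame_names = []
        frame_has_images = None
        for a in range(n):
            parts = lines[i + 2 + a].split()
            if len(parts) not in (4, 7):
                raise TrajectoryFormatError(
                    f"line {i + 3 + a}: expected 4 or 7 columns, got {len(parts)}")
            frame_names.append(parts[0])
            pos[a] = [float(v) for v in parts[1:4]]
            this_has = len(parts) == 7
            if frame_has_images is None:
                frame_has_images = this_has
            elif frame_has_images != this_has:
                raise TrajectoryFormatError(f"line {i + 3 + a}: inconsistent columns")
            if this_has:
                imgs[a] = [int(v) for v in parts[4:7]]
        if has_images is None:
            has_images = frame_has_images
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise TrajectoryFormatError(
                f"line {i + 1}: frame atom count {n} != {len(names)}")
        frames.append(pos)
        if has_images:
            images_all.append(imgs)
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError("no frames found")
    return Trajectory(
        positions=np.array(frames), times_ps=np.array(times), cell=cell,
        images=np.array(images_all) if has_images else None,
        atom_names=np.array(names),
        residue_names=np.array(["HOH" if n == "O" else "UNK" for n in names]))


def write_multi_pdb(traj: Trajectory, path):
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL per frame)."""
    names = (traj.atom_names if traj.atom_names is not None
             else np.array(["X"] * traj.n_atoms))
    res = (traj.residue_names if traj.residue_names is not None
           else np.array(["UNK"] * traj.n_atoms))
    with open(path, "w") as fh:
        if traj.cell is not None:
            a, b, c = traj.cell
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            fh.write(f"REMARK 301 TIME_PS {traj.times_ps[f]:.6f}\n")
            for a_i in range(traj.n_atoms):
                x, y, z = traj.positions[f, a_i]
                name = str(names[a_i])
                pad = f" {name:<3s}" if len(name) < 4 else name
                el = name[0]
                fh.write(f"ATOM  {a_i + 1:5d} {pad}{res[a_i]:>4s} A{(a_i % 9999) + 1:4d}"
                         f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                         f"          {el:>2s}\n")
            fh.write("ENDMDL\n")


def read_multi_pdb(path) -> Trajectory:
    frames, times, names, res = [], [], [], []
    cell = None
    cur = None
    first = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                cell = np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33])])
            elif rec.startswith("MODEL"):
                cur = []
            elif line.startswith("REMARK 301 TIME_PS"):
                times.append(float(line.split()[-1]))
            elif rec in ("ATOM  ", "HETATM"):
                if cur is None:
                    raise TrajectoryFormatError(f"line {lineno}: ATOM outside MODEL")
                try:
                    cur.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                except ValueError as exc:
                    raise TrajectoryFormatError(
                        f"line {lineno}: malformed coordinates") from exc
                if first:
                    names.append(line[12:16].strip())
                    res.append(line[17:20].strip())
            elif rec.startswith("ENDMDL"):
                frames.append(cur)
                cur = None
                first = False
    if not frames:
        raise TrajectoryFormatError("no MODEL frames found")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise TrajectoryFormatError(f"inconsistent atom counts across frames: {counts}")
    if len(times) != len(frames):
        times = list(range(len(frames)))
    return Trajectory(positions=np.array(frames, dtype=float),
                      times_ps=np.array(times, dtype=float), cell=cell,
                      atom_names=np.array(names), residue_names=np.array(res))


def write_sidecar(config: DynamicsConfig, path, extra: dict | None = None):
    """Write generator ground truth (config + any labels/metadata) as JSON."""
    payload = {"dynamics_config": config.to_dict()}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_sidecar(path):
    with open(path) as fh:
        payload = json.load(fh)
    config = DynamicsConfig.from_dict(payload.pop("dynamics_config"))
    return config, payload
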