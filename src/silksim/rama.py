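"""Backbone torsion analysis: phi/psi computation, region classification, fractions.

Backbone dihedrals follow the IUPAC convention, phi_i = C_{i-1}-N_i-CA_i-C_i and
psi_i = N_i-CA_i-C_i-N_{i+1}.  For periodically closed chains the missing neighbours
of the first and last residues are taken from the chain's minimum-image periodic copy,
so every residue has both angles; open chains get NaN at the respective terminus.

Classification uses rectangular regions around the characteristic silk-I centres — the
left-handed alpha-helix near (70, 10), the 3_10-helix near (-40, -30), the beta-sheet
near (-60, 130) — plus the antiparallel beta-sheet near (-143, 142) known from
electronic-structure work on the silk-II form.  Rectangles and priorities are
configurable; anything outside every rectangle is "coil".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import dihedral_batch, wrap_angle
from .model import CrystalModel
from .trajectory import Trajectory

__all__ = ["RamachandranRegion", "DEFAULT_REGIONS", "DihedralSeries",
           "compute_dihedrals", "model_dihedrals", "classify", "classify_batch",
           "region_fractions", "density_histogram", "load_regions", "save_regions"]


@dataclass(frozen=True)
class RamachandranRegion:
    """A rectangular (phi, psi) region: centre, half-widths (deg) and priority rank
    (lower rank wins where rectangles overlap)."""

    name: str
    center: tuple
    half_widths: tuple = (30.0, 30.0)
    priority: int = 0

    def __post_init__(self):
        for v in self.center:
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"region {self.name!r}: centre angle {v} outside (-180, 180]")
        if min(self.half_widths) <= 0:
            raise ValueError(f"region {self.name!r}: half-widths must be positive")

    def contains(self, phi, psi):
        dphi = np.abs(wrap_angle(np.asarray(phi) - self.center[0]))
        dpsi = np.abs(wrap_angle(np.asarray(psi) - self.center[1]))
        return (dphi <= self.half_widths[0]) & (dpsi <= self.half_widths[1])


#: Default region set.  Centres follow the characteristic values quoted for the
#: (Ala-Gly)_n model; half-widths are +-30 degrees.  Priority order: antiparallel
#: beta-sheet > beta-sheet > 3_10-helix > left-handed alpha-helix.
DEFAULT_REGIONS = (
    RamachandranRegion("antiparallel_beta_sheet", (-143.0, 142.0), (30.0, 30.0), 0),
    RamachandranRegion("beta_sheet", (-60.0, 130.0), (30.0, 30.0), 1),
    RamachandranRegion("3_10_helix", (-40.0, -30.0), (30.0, 30.0), 2),
    RamachandranRegion("left_handed_alpha_helix", (70.0, 10.0), (30.0, 30.0), 3),
)


def _region_map(regions) -> dict:
    return {r.name: r for r in regions}


def load_regions(path):
    """Read a region set from YAML (list of {name, center, half_widths, priority})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(RamachandranRegion(r["name"], tuple(r["center"]),
                                    tuple(r.get("half_widths", (30.0, 30.0))),
                                    int(r.get("priority", i)))
                 for i, r in enumerate(raw))


def save_regions(regions, path):
    with open(path, "w") as fh:
        yaml.safe_dump([{"name": r.name, "center": list(r.center),
                         "half_widths": list(r.half_widths), "priority": r.priority}
                        for r in regions], fh)


@dataclass
class DihedralSeries:
    """Per-residue, per-frame (phi, psi) pairs in degrees with residue identity."""

    phi: np.ndarray                # (n_frames, n_residues), deg, NaN where undefined
    psi: np.ndarray
    residue_names: np.ndarray      # (n_residues,)
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    labels: np.ndarray | None = None   # optional ground-truth region labels

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frames, residues = np.meshgrid(np.arange(self.n_frames),
                                       np.arange(self.n_residues), indexing="ij")
        return pd.DataFrame({
            "frame": frames.ravel(),
            "chain": np.tile(self.chain_ids, self.n_frames),
            "residue_index": np.tile(self.residue_indices, self.n_frames),
            "residue_name": np.tile(self.residue_names, self.n_frames),
            "phi": self.phi.ravel(),
            "psi": self.psi.ravel(),
        })


def _unwrap_consecutive(points, cell):
    """Make each point in a backbone quadruple the minimum image of its predecessor."""
    if cell is None:
        return points
    out = [points[0]]
    for p in points[1:]:
        d = p - out[-1]
        d = d - cell * np.round(d / cell)
        out.append(out[-1] + d)
    return out


def compute_dihedrals(traj: Trajectory, model: CrystalModel) -> DihedralSeries:
    """Compute per-residue (phi, psi) series from trajectory coordinates.

    ``model`` supplies the topology (chain ranges, atom names, closure flags); its
    atom order must match the trajectory.  For closed chains the neighbours across
    the periodic boundary come from the minimum-image copy.
    """
    if traj.n_atoms != model.n_atoms:
        raise ValueError("trajectory and model atom counts differ")
    cell = model.cell if traj.cell is not None else None

    phis, psis, rnames, cids, ridx = [], [], [], [], []
    pos = traj.positions  # (F, N, 3)
    for ch in model.chains:
        sl = slice(ch.start, ch.stop)
        names = model.atom_names[sl]
        res = model.residue_indices[sl]
        n_res = int(res[-1])
        bb = {}
        for want in ("N", "CA", "C"):
            mask = names == want
            order = res[mask]
            idx = np.nonzero(mask)[0] + ch.start
            if len(idx) != n_res or not np.array_equal(np.sort(order),
                                                       np.arange(1, n_res + 1)):
                missing = set(range(1, n_res + 1)) - set(order.tolist())
                raise ValueError(
                    f"chain {ch.chain_id}: backbone atom {want} missing for residue(s) "
                    f"{sorted(missing) if missing else '?'}")
            bb[want] = idx[np.argsort(order)]
        rnames.extend(model.residue_names[sl][np.searchsorted(res, np.arange(1, n_res + 1))])
        cids.extend([ch.chain_id] * n_res)
        ridx.extend(range(1, n_res + 1))

        phi = np.full((traj.n_frames, n_res), np.nan)
        psi = np.full((traj.n_frames, n_res), np.nan)
        for i in range(n_res):
            has_prev = i > 0 or ch.periodic_closure
            has_next = i < n_res - 1 or ch.periodic_closure
            c_prev = bb["C"][(i - 1) % n_res] if has_prev else None
            n_next = bb["N"][(i + 1) % n_res] if has_next else None
            n_i, ca_i, c_i = bb["N"][i], bb["CA"][i], bb["C"][i]
            if has_prev:
                quad = _unwrap_consecutive(
                    [pos[:, c_prev], pos[:, n_i], pos[:, ca_i], pos[:, c_i]], cell)
                phi[:, i] = dihedral_batch(*quad)
            if has_next:
                quad = _unwrap_consecutive(
                    [pos[:, n_i], pos[:, ca_i], pos[:, c_i], pos[:, n_next]], cell)
                psi[:, i] = dihedral_batch(*quad)
        phis.append(phi)
        psis.append(psi)

    return DihedralSeries(
        phi=np.concatenate(phis, axis=1), psi=np.concatenate(psis, axis=1),
        residue_names=np.array(rnames), chain_ids=np.array(cids),
        residue_indices=np.array(ridx, dtype=int))


def model_dihedrals(model: CrystalModel) -> DihedralSeries:
    """Single-frame dihedral series of a static crystal model."""
    traj = Trajectory(positions=model.positions[None], times_ps=[0.0],
                      cell=model.cell)
    return compute_dihedrals(traj, model)


def classify(phi: float, psi: float, regions=DEFAULT_REGIONS) -> str:
    """Classify one (phi, psi) pair (degrees) into a named region or "coil"."""
    best = None
    for region in regions:
        if region.contains(phi, psi):
            if best is None or region.priority < best.priority:
                best = region
    return best.name if best is not None else "coil"


def classify_batch(phi, psi, regions=DEFAULT_REGIONS) -> np.ndarray:
    """Vectorised :func:`classify`; NaN angles classify as "unassigned"."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    out = np.full(phi.shape, "coil", dtype=object)
    assigned_priority = np.full(phi.shape, np.inf)
    for region in regions:
        inside = region.contains(phi, psi) & (region.priority < assigned_priority)
        out[inside] = region.name
        assigned_priority[inside] = region.priority
    out[np.isnan(phi) | np.isnan(psi)] = "unassigned"
    return out


def region_fractions(series: DihedralSeries, regions=DEFAULT_REGIONS) -> pd.DataFrame:
    """Per-region fractions of residue-frames, total and split by residue type.

    Fractions within each residue-type group sum to 1 (coil included); residue-frames
    with undefined angles (open-chain termini) are excluded.
    """
    if series.n_frames * series.n_residues == 0:
        raise ValueError("empty dihedral series")
    labels = classify_batch(series.phi, series.psi, regions)
    valid = labels != "unassigned"
    if not valid.any():
        raise ValueError("series has no residue-frames with defined angles")
    res_type = np.broadcast_to(series.residue_names, labels.shape)
    region_names = [r.name for r in sorted(regions, key=lambda r: r.priority)] + ["coil"]
    rows = []
    for group, mask in (("all", valid),
                        ("ALA", valid & (res_type == "ALA")),
                        ("GLY", valid & (res_type == "GLY"))):
        total = int(mask.sum())
        if total == 0:
            continue
        for name in region_names:
            rows.append({"region": name, "residue_type": group,
                         "fraction": float((labels[mask] == name).sum()) / total})
    return pd.DataFrame(rows)


def fractions_dict(series: DihedralSeries, regions=DEFAULT_REGIONS) -> dict:
    """Convenience: {region: fraction} over all residues."""
    df = region_fractions(series, regions)
    sub = df[df.residue_type == "all"]
    return dict(zip(sub.region, sub.fraction))


def density_histogram(series: DihedralSeries, bin_width: float = 10.0):
    """2-D histogram of (phi, psi) over (-180, 180]^2.

    Returns ``(counts, edges)`` where ``counts[i, j]`` covers phi in
    ``edges[i]..edges[i+1]`` and psi likewise.  Total count equals the number of
    residue-frames with defined angles.
    """
    if bin_width <= 0 or not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError("bin_width must be positive and divide 360")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    phi = series.phi.ravel()
    psi = series.psi.ravel()
    ok = ~(np.isnan(phi) | np.isnan(psi))
    # samples at exactly -180 belong to the top bin under the (-180, 180] convention
    phi = wrap_angle(phi[ok])
    psi = wrap_angle(psi[ok])
    phi_idx = np.clip(np.ceil((phi + 180.0) / bin_width).astype(int) - 1, 0, n_bins - 1)
    psi_idx = np.clip(np.ceil((psi + 180.0) / bin_width).astype(int) - 1, 0, n_bins - 1)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (phi_idx, psi_idx), 1)
    return counts, edges
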