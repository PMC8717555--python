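"""Synthetic dynamics with known ground truth, standing in for external MD/AIMD engines.

Two generators are provided:

* :func:`water_trajectory` — non-interacting Brownian water tracers in a periodic
  orthorhombic cell.  The diffusion coefficient either follows the Arrhenius law
  D(T) = D0 * exp(-Ea / (R T)) or is given directly; per-axis anisotropy is imposed
  through axis fractions (f_x, f_y, f_z) with per-axis diffusivity D_axis = 3 f_axis D,
  so the fractions sum the axis diffusivities to 3 D and the isotropic case recovers
  MSD = 6 D t.

* :func:`dihedral_samples` — backbone (phi, psi) ensembles drawn from a stated
  secondary-structure composition over named Ramachandran regions with Gaussian angular
  jitter, with the drawn region labels kept as ground truth.

These emulate only the features the analysis modules measure (Fickian water motion
with a prescribed D(T) and anisotropy; torsion-region populations); they contain no
force-field physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import R_GAS, CM2_S_TO_A2_PS
from .model import UnitCellSpec
from .trajectory import Trajectory

__all__ = [
    "DynamicsConfig", "CompositionSpec", "water_trajectory", "dihedral_samples",
    "trajectory_from_dihedrals", "REFERENCE_ARRHENIUS_CONFIG", "ROOM_T_CONFIG",
    "ARRHENIUS_TEMPERATURES_K", "REFERENCE_COMPOSITION",
]

#: Temperatures (K) of the Arrhenius emulation runs (273-310 K range, two interior points).
ARRHENIUS_TEMPERATURES_K = (273.0, 285.0, 298.0, 310.0)

#: Secondary-structure composition emulating the reported populations:
#: 3_10-helix ~37%, beta-sheet ~26%, remainder coil.
REFERENCE_COMPOSITION = {"3_10_helix": 0.37, "beta_sheet": 0.26, "coil": 0.37}


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the Brownian water-tracer generator.

    In ``arrhenius`` mode the tracer diffusivity at temperature ``temperature_k`` is
    D = d0_cm2_s * exp(-ea_kj_mol * 1000 / (R * T)); in ``direct`` mode it is
    ``d_direct_cm2_s`` verbatim.
    """

    mode: str = "arrhenius"
    d0_cm2_s: float = 1.78e-4
    ea_kj_mol: float = 12.07
    temperature_k: float = 298.0
    d_direct_cm2_s: float | None = None
    axis_fractions: tuple = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    dt_ps: float = 1.0
    n_steps: int = 1000
    sampling_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("arrhenius", "direct"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if self.n_steps < 1 or self.sampling_stride < 1:
            raise ValueError("n_steps and sampling_stride must be >= 1")
        f = np.asarray(self.axis_fractions, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or not math.isclose(f.sum(), 1.0,
                                                                abs_tol=1e-9):
            raise ValueError("axis_fractions must be 3 nonnegative values summing to 1")

    def diffusion_coefficient(self) -> float:
        """Tracer diffusivity D in cm^2 s^-1 at this configuration's temperature."""
        if self.mode == "direct":
            if self.d_direct_cm2_s is None:
                raise ValueError("direct mode requires d_direct_cm2_s")
            d = self.d_direct_cm2_s
        else:
            if self.d0_cm2_s is None or self.ea_kj_mol is None:
                raise ValueError("arrhenius mode requires d0_cm2_s and ea_kj_mol")
            d = self.d0_cm2_s * math.exp(
                -self.ea_kj_mol * 1000.0 / (R_GAS * self.temperature_k))
        if d <= 0:
            raise ValueError("diffusivity must be positive")
        return d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axis_fractions"] = list(self.axis_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicsConfig":
        d = dict(d)
        if "axis_fractions" in d:
            d["axis_fractions"] = tuple(d["axis_fractions"])
        return cls(**d)


#: Reference-emulation Arrhenius generator (use with `ARRHENIUS_TEMPERATURES_K`).
REFERENCE_ARRHENIUS_CONFIG = DynamicsConfig(mode="arrhenius", d0_cm2_s=1.78e-4,
                                        ea_kj_mol=12.07)

#: Room-temperature direct-mode generator.  Kept independent of the Arrhenius config:
#: the two printed values (D0/Ea pair vs the 298 K coefficient) are mutually
#: inconsistent by ~18%, so neither is derived from the other.
ROOM_T_CONFIG = DynamicsConfig(mode="direct", d_direct_cm2_s=1.60e-6,
                               temperature_k=298.0)


def water_trajectory(config: DynamicsConfig, n_waters: int, cell) -> Trajectory:
    """Generate a Brownian water-tracer trajectory in a periodic orthorhombic cell.

    Each tracer represents a water oxygen.  Per-axis displacement increments are
    Gaussian with variance 2 * D_axis * dt; positions are wrapped into the cell with
    image counts recorded, so unwrapped displacements are exact.
    """
    cell = np.asarray(cell, dtype=float)
    if cell.shape != (3,) or np.any(cell <= 0):
        raise ValueError("cell must be three positive lengths")
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    d_cm2_s = config.diffusion_coefficient()
    d_a2_ps = d_cm2_s * CM2_S_TO_A2_PS
    d_axis = 3.0 * np.asarray(config.axis_fractions) * d_a2_ps
    sigma = np.sqrt(2.0 * d_axis * config.dt_ps)   # per-axis step std, A

    rng = np.random.default_rng(config.seed)
    x0 = rng.uniform(0.0, 1.0, size=(n_waters, 3)) * cell
    steps = rng.normal(0.0, 1.0, size=(config.n_steps, n_waters, 3)) * sigma
    unwrapped = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
    frame_idx = np.arange(0, config.n_steps + 1, config.sampling_stride)
    unwrapped = unwrapped[frame_idx]
    images = np.floor(unwrapped / cell).astype(int)
    wrapped = unwrapped - images * cell
    times = frame_idx * config.dt_ps
    return Trajectory(
        positions=wrapped, times_ps=times, cell=cell, images=images,
        atom_names=np.array(["O"] * n_waters),
        residue_names=np.array(["HOH"] * n_waters),
    )


@dataclass(frozen=True)
class CompositionSpec:
    """Secondary-structure composition for the torsion-ensemble generator.

    ``fractions`` maps named Ramachandran regions (plus "coil") to occupation
    probabilities; ``sigma_deg`` is the Gaussian angular jitter applied about each
    region centre.  Coil samples are drawn uniformly over the torus excluding every
    named region rectangle.
    """

    fractions: dict = field(default_factory=lambda: dict(REFERENCE_COMPOSITION))
    sigma_deg: float = 10.0
    n_residues: int = 2048
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self):
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0) or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("composition fractions must be nonnegative and sum to 1")
        if self.sigma_deg < 0:
            raise ValueError("sigma_deg must be >= 0")
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValueError("n_residues and n_frames must be >= 1")


def dihedral_samples(spec: CompositionSpec, regions=None):
    """Draw a synthetic :class:`~silksim.rama.DihedralSeries` from a composition.

    Each residue-frame first draws a region label, then (phi, psi) = region centre +
    independent Gaussian jitter (or a uniform off-region point for "coil"), wrapped to
    (-180, 180].  Drawn labels are stored as ground truth.
    """
    from .rama import DEFAULT_REGIONS, DihedralSeries, _region_map
    from .geometry import wrap_angle

    regions = DEFAULT_REGIONS if regions is None else regions
    rmap = _region_map(regions)
    names = list(spec.fractions.keys())
    for name in names:
        if name != "coil" and name not in rmap:
            raise ValueError(f"unknown region name {name!r}")
    probs = np.array([spec.fractions[n] for n in names])

    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_frames, spec.n_residues)
    n_total = spec.n_frames * spec.n_residues
    label_idx = rng.choice(len(names), size=n_total, p=probs)
    phi = np.empty(n_total)
    psi = np.empty(n_total)
    for li, name in enumerate(names):
        mask = label_idx == li
        count = int(mask.sum())
        if count == 0:
            continue
        if name == "coil":
            phi[mask], psi[mask] = _sample_coil(rng, count, regions)
        else:
            region = rmap[name]
            jitter = rng.normal(0.0, spec.sigma_deg, size=(count, 2))
            phi[mask] = region.center[0] + jitter[:, 0]
            psi[mask] = region.center[1] + jitter[:, 1]
    labels = np.array(names, dtype=object)[label_idx].reshape(shape)

    half = spec.n_residues // 2
    residue_names = np.array((["ALA", "GLY"] * (half + 1))[:spec.n_residues])
    return DihedralSeries(
        phi=wrap_angle(phi.reshape(shape)), psi=wrap_angle(psi.reshape(shape)),
        residue_names=residue_names,
        chain_ids=np.array(["A"] * spec.n_residues),
        residue_indices=np.arange(1, spec.n_residues + 1),
        labels=labels,
    )


def _sample_coil(rng, count, regions):
    """Uniform samples on (-180, 180]^2 excluding every region rectangle."""
    from .geometry import wrap_angle
    phi = np.empty(count)
    psi = np.empty(count)
    filled = 0
    while filled < count:
        batch = max(count - filled, 64)
        cand = rng.uniform(-180.0, 180.0, size=(2 * batch, 2))
        ok = np.ones(len(cand), dtype=bool)
        for region in regions:
            dphi = wrap_angle(cand[:, 0] - region.center[0])
            dpsi = wrap_angle(cand[:, 1] - region.center[1])
            ok &= ~((np.abs(dphi) <= region.half_widths[0]) &
                    (np.abs(dpsi) <= region.half_widths[1]))
        good = cand[ok]
        take = min(len(good), count - filled)
        phi[filled:filled + take] = good[:take, 0]
        psi[filled:filled + take] = good[:take, 1]
        filled += take
    return phi, psi


def trajectory_from_dihedrals(series, spec: UnitCellSpec | None = None) -> Trajectory:
    """Rebuild a chain per frame from a dihedral series (coordinate-level round trip).

    Every frame is an open chain grown by the internal-coordinate builder from that
    frame's torsions, so recomputing dihedrals from the frames returns the series for
    interior residues.  The trajectory carries no cell (coordinates are unwrapped).
    """
    from .builder import build_chain_from_torsions

    spec = spec or UnitCellSpec()
    n_res = len(series.residue_names)
    if n_res != 2 * spec.ag_repeats_per_chain:
        raise ValueError(
            f"series has {n_res} residues but spec expects "
            f"{2 * spec.ag_repeats_per_chain}")
    frames = []
    chain = None
    for f in range(series.n_frames):
        chain = build_chain_from_torsions(
            series.phi[f], series.psi[f], list(series.residue_names),
            omega=spec.omega, geometry=spec.geometry)
        frames.append(chain.positions)
    return Trajectory(
        positions=np.array(frames),
        times_ps=np.arange(series.n_frames, dtype=float),
        cell=None, images=None,
        atom_names=np.array(chain.atom_names),
        residue_names=np.array(chain.residue_names),
    )
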