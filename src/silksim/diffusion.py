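"""Water mobility analysis: MSD, diffusion coefficients, Arrhenius fit, density grids.

The mean square displacement at lag tau is the average over particles and over time
origins (spaced ``origin_stride`` frames) of |x(t0 + tau) - x(t0)|^2 on unwrapped
coordinates.  For Fickian diffusion MSD(tau) = 2 * dim * D * tau, so D is the ordinary
least-squares slope over a fit window divided by 2*dim (with the A^2/ps -> cm^2/s
conversion of 1e-4).  The Arrhenius fit regresses ln D on 1/T: Ea = -slope * R and
D0 = exp(intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_GAS
from .trajectory import Trajectory

__all__ = ["MSDResult", "msd", "fit_diffusion", "ArrheniusFit", "arrhenius_fit",
           "occupancy_grid", "default_fit_window"]


@dataclass
class MSDResult:
    """Lag times with total and per-axis MSD and origin counts.

    Invariant: ``msd_total == msd_x + msd_y + msd_z`` exactly at every lag.
    """

    lag_ps: np.ndarray
    msd_total: np.ndarray
    msd_x: np.ndarray
    msd_y: np.ndarray
    msd_z: np.ndarray
    origins_per_lag: np.ndarray
    selection: str = "all"

    @property
    def max_lag_ps(self) -> float:
        return float(self.lag_ps[-1])

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.msd_x, "y": self.msd_y, "z": self.msd_z,
                "total": self.msd_total}[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag_ps": self.lag_ps, "msd_total": self.msd_total,
            "msd_x": self.msd_x, "msd_y": self.msd_y, "msd_z": self.msd_z,
            "n_origins": self.origins_per_lag,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, selection: str = "all") -> "MSDResult":
        return cls(lag_ps=df["lag_ps"].to_numpy(),
                   msd_total=df["msd_total"].to_numpy(),
                   msd_x=df["msd_x"].to_numpy(), msd_y=df["msd_y"].to_numpy(),
                   msd_z=df["msd_z"].to_numpy(),
                   origins_per_lag=df["n_origins"].to_numpy(), selection=selection)


def msd(traj: Trajectory, selection="water-O", max_lag: int | None = None,
        origin_stride: int = 10) -> MSDResult:
    """Multi-origin MSD (total and per-axis) on unwrapped coordinates.

    ``max_lag`` is in frames (default half the trajectory); time origins are spaced
    ``origin_stride`` frames.  Requires exact unwrap information (see
    :meth:`Trajectory.unwrapped`).
    """
    idx = traj.select(selection)
    u = traj.unwrapped()[:, idx, :]
    n_frames = traj.n_frames
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if max_lag is None:
        max_lag = n_frames // 2
    if not (1 <= max_lag < n_frames):
        raise ValueError(f"max_lag must be in [1, {n_frames - 1}]")
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    dt = traj.times_ps[1] - traj.times_ps[0]

    lags = np.arange(max_lag + 1)
    per_axis = np.zeros((max_lag + 1, 3))
    n_origins = np.zeros(max_lag + 1, dtype=int)
    n_origins[0] = len(np.arange(0, n_frames, origin_stride))
    for lag in lags[1:]:
        t0 = np.arange(0, n_frames - lag, origin_stride)
        d = u[t0 + lag] - u[t0]           # (origins, particles, 3)
        for ax in range(3):
            per_axis[lag, ax] = np.mean(d[..., ax] ** 2)
        n_origins[lag] = len(t0)
    msd_x, msd_y, msd_z = per_axis[:, 0], per_axis[:, 1], per_axis[:, 2]
    sel_desc = selection if isinstance(selection, str) else f"{len(idx)} atoms"
    return MSDResult(lag_ps=lags * dt, msd_total=msd_x + msd_y + msd_z,
                     msd_x=msd_x, msd_y=msd_y, msd_z=msd_z,
                     origins_per_lag=n_origins, selection=sel_desc)


def default_fit_window(result: MSDResult) -> tuple:
    """Default fit window: lags in [10%, 50%] of the maximum lag."""
    return 0.1 * result.max_lag_ps, 0.5 * result.max_lag_ps


def fit_diffusion(result: MSDResult, fit_window: tuple | None = None, dim: int = 3,
                  axis: str | None = None) -> float:
    """Diffusion coefficient (cm^2 s^-1) from the OLS slope of MSD vs lag time.

    ``dim`` is the dimensionality of the displacement measure (3 for the total MSD,
    1 for a single axis, passed via ``axis``).
    """
    if dim not in (1, 3):
        raise ValueError("dim must be 1 or 3")
    if axis is not None and dim != 1:
        raise ValueError("per-axis fits use dim=1")
    y = result.axis(axis) if axis is not None else result.msd_total
    lo, hi = fit_window if fit_window is not None else default_fit_window(result)
    mask = (result.lag_ps >= lo) & (result.lag_ps <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window contains fewer than 2 lags")
    fit = stats.linregress(result.lag_ps[mask], y[mask])
    return fit.slope / (2.0 * dim) * 1e-4


@dataclass
class ArrheniusFit:
    """Arrhenius regression of ln D on 1/T with diagnostics."""

    temperatures_k: np.ndarray
    d_cm2_s: np.ndarray
    ea_kj_mol: float
    d0_cm2_s: float
    r_squared: float
    residuals: np.ndarray        # ln D residuals per point

    def predict(self, temperature_k) -> np.ndarray:
        t = np.asarray(temperature_k, dtype=float)
        return self.d0_cm2_s * np.exp(-self.ea_kj_mol * 1000.0 / (R_GAS * t))

    def to_dict(self) -> dict:
        return {"Ea_kJ_mol": self.ea_kj_mol, "D0_cm2_s": self.d0_cm2_s,
                "r2": self.r_squared,
                "points": [{"T_K": float(t), "D_cm2_s": float(d)}
                           for t, d in zip(self.temperatures_k, self.d_cm2_s)]}


def arrhenius_fit(points) -> ArrheniusFit:
    """Least-squares Arrhenius fit to (T in K, D in cm^2/s) points.

    Ea (kJ/mol) = -slope * R / 1000; D0 = exp(intercept).  Requires at least two
    distinct temperatures and strictly positive D.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (T, D) points")
    T, D = pts[:, 0], pts[:, 1]
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(D <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and diffusivities must be positive")
    x = 1.0 / T
    y = np.log(D)
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    return ArrheniusFit(
        temperatures_k=T, d_cm2_s=D,
        ea_kj_mol=-fit.slope * R_GAS / 1000.0,
        d0_cm2_s=float(np.exp(fit.intercept)),
        r_squared=float(fit.rvalue ** 2),
        residuals=residuals)


def occupancy_grid(traj: Trajectory, selection="water-O", voxel: float = 1.0):
    """Histogram wrapped positions on an orthorhombic voxel grid.

    Returns ``(counts, edges)``; the grid total equals n_frames * n_selected.
    """
    if traj.cell is None:
        raise ValueError("occupancy grid requires a periodic cell")
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    if voxel > float(np.min(traj.cell)):
        raise ValueError("voxel larger than the cell")
    idx = traj.select(selection)
    nbins = np.maximum(np.floor(traj.cell / voxel).astype(int), 1)
    pos = traj.positions[:, idx, :].reshape(-1, 3)
    frac = pos / traj.cell
    frac -= np.floor(frac)
    counts, edges = np.histogramdd(
        frac * traj.cell, bins=nbins.tolist(),
        range=[(0.0, float(c)) for c in traj.cell])
    return counts.astype(int), edges
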