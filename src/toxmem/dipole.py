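"""Molecular dipole magnitude and orientation relative to the membrane normal.

For a set of point charges q_i at positions r_i the molecular dipole about the
mass-weighted center of mass is

    μ = Σ q_i (r_i − r_COM),

reported in Debye (1 e·Å = 4.80320 D). The orientation is the angle between μ
and the +z axis (the membrane normal pointing away from the bilayer through
the toxin-proximal leaflet), in degrees on [0, 180].

For a *net-charged* molecule such as SNX-482 (net −2 e) the dipole depends on
the reference point: shifting the origin by Δ changes μ by −q_net·Δ (in e·nm
before conversion). The mass-weighted COM is used as the conventional
reference, and the origin dependence is exposed rather than hidden — see
:func:`dipole_moment`'s ``origin`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .insertion import fit_leaflet
from .trajectory import Trajectory
from .units import DEBYE_PER_E_NM

ANGLE_TOL_DEBYE = 1e-6


class DipoleError(ValueError):
    pass


@dataclass
class ChargeModel:
    """Point charges with positions (nm), charges (e) and masses (Da)."""

    positions: np.ndarray   # (N, 3)
    charges: np.ndarray     # (N,)
    masses: np.ndarray      # (N,)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.positions)
        if len(self.charges) != n or len(self.masses) != n:
            raise DipoleError("positions, charges and masses must be congruent")
        if n == 0:
            raise DipoleError("empty charge model")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def com(self) -> np.ndarray:
        w = self.masses / self.masses.sum()
        return w @ self.positions


def dipole_moment(
    model: ChargeModel, origin: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Dipole vector (Debye) and magnitude about ``origin`` (default: COM)."""
    ref = model.com() if origin is None else np.asarray(origin, dtype=float)
    mu_e_nm = model.charges @ (model.positions - ref)
    mu = mu_e_nm * DEBYE_PER_E_NM
    return mu, float(np.linalg.norm(mu))


def angle_to_z(mu: np.ndarray) -> float:
    """Angle of a dipole vector to +z, degrees in [0, 180]."""
    norm = np.linalg.norm(mu)
    if norm <= ANGLE_TOL_DEBYE:
        raise DipoleError(f"dipole magnitude {norm:g} D below tolerance; angle undefined")
    return float(np.degrees(np.arccos(np.clip(mu[2] / norm, -1.0, 1.0))))


def dipole_profile(traj: Trajectory) -> pd.DataFrame:
    """Per-frame dipole records: time, |Dip| (D), Dip_z angle (deg), distance (nm).

    Charges and masses are taken from the trajectory's residue annotations;
    membrane distance is the toxin COM height above the fitted upper-leaflet
    surface at the COM's lateral position. The angle is NaN in frames where
    the magnitude falls below tolerance.
    """
    if traj.residue_charges is None:
        raise DipoleError("trajectory has no residue charges attached")
    masses = (
        traj.residue_masses
        if traj.residue_masses is not None
        else np.ones(traj.n_residues)
    )
    records = []
    for f in range(traj.n_frames):
        model = ChargeModel(traj.residue_com[f], traj.residue_charges, masses)
        mu, mag = dipole_moment(model)
        com = model.com()
        fit = fit_leaflet(traj.upper_heads[f])
        dist = float(com[2] - fit.surface_z(com[0], com[1]))
        angle = angle_to_z(mu) if mag > ANGLE_TOL_DEBYE else np.nan
        records.append(
            {
                "time_ns": traj.times[f],
                "magnitude_debye": mag,
                "angle_z_deg": angle,
                "membrane_distance_nm": dist,
            }
        )
    return pd.DataFrame.from_records(records)


def bin_by_distance(
    records: pd.DataFrame, bin_nm: float = 0.25
) -> pd.DataFrame:
    """Mean and spread of |Dip| and Dip_z per membrane-distance bin."""
    r = records.copy()
    r["distance_bin"] = np.floor(r["membrane_distance_nm"] / bin_nm) * bin_nm
    out = (
        r.groupby("distance_bin")
        .agg(
            n=("magnitude_debye", "size"),
            magnitude_mean=("magnitude_debye", "mean"),
            magnitude_std=("magnitude_debye", "std"),
            angle_mean=("angle_z_deg", "mean"),
            angle_std=("angle_z_deg", "std"),
        )
        .reset_index()
    )
    return out


def angle_histogram(
    records: pd.DataFrame | np.ndarray,
    bin_deg: float = 5.0,
    solid_angle_weight: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized probability distribution of the dipole angle on [0, 180].

    Returns (bin_centers_deg, probability) with probabilities summing to 1.
    With ``solid_angle_weight`` each sample is weighted by 1/sin(θ) so an
    isotropic (uniform-on-sphere) dipole population yields a flat weighted
    histogram.
    """
    angles = (
        records["angle_z_deg"].to_numpy()
        if isinstance(records, pd.DataFrame)
        else np.asarray(records, dtype=float)
    )
    angles = angles[np.isfinite(angles)]
    if len(angles) == 0:
        raise DipoleError("no defined angles: all dipole magnitudes below tolerance")
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    weights = None
    if solid_angle_weight:
        s = np.sin(np.radians(angles))
        weights = 1.0 / np.clip(s, 1e-12, None)
    counts, edges = np.histogram(angles, bins=edges, weights=weights)
    prob = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, prob


def lipid_dipole(head_pos: np.ndarray, head_charges: np.ndarray, masses: np.ndarray):
    """Per-lipid head-group dipole helper (illustrative; see docs)."""
    model = ChargeModel(head_pos, head_charges, masses)
    return dipole_moment(model)
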