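"""Canonical in-memory trajectory container and its long-format CSV serialization.

A :class:`Trajectory` holds time-ordered frames of a peptide/bilayer system:
lipid head-group coordinates per leaflet, peptide residue centers of mass
(optionally side-chain centers), optional ions, per-residue charges and
masses, and the periodic box. All coordinates are in nm, times in ns,
charges in e, masses in Da. Coordinates are assumed unwrapped across
periodic boundaries; :func:`unwrap` is provided for wrapped input.

The interchange format is one long table with columns
``frame, time_ns, particle_id, role, species, x, y, z, charge`` where role is
one of ``lipid_head_upper``, ``lipid_head_lower``, ``residue_com``,
``sidechain_com``, ``ion``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("lipid_head_upper", "lipid_head_lower", "residue_com", "sidechain_com", "ion")


class TrajectoryError(ValueError):
    """Raised when a trajectory violates its structural invariants."""


@dataclass
class Trajectory:
    times: np.ndarray                     # (F,) ns, strictly increasing
    box: np.ndarray                       # (F, 3) nm
    upper_heads: np.ndarray               # (F, Nu, 3)
    lower_heads: np.ndarray               # (F, Nl, 3)
    residue_com: np.ndarray               # (F, R, 3)
    sidechain_com: np.ndarray | None = None   # (F, R, 3)
    c1_upper_z: np.ndarray | None = None      # (F, Nu) acyl C1 carbon z per upper lipid
    ions: np.ndarray | None = None            # (F, Ni, 3)
    residue_charges: np.ndarray | None = None  # (R,) e
    residue_masses: np.ndarray | None = None   # (R,) Da
    upper_species: np.ndarray | None = None    # (Nu,) str labels
    lower_species: np.ndarray | None = None    # (Nl,) str labels
    ground_truth_insertion: np.ndarray | None = field(default=None, repr=False)  # (F, R) bool
    ground_truth_onset: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.times.ndim != 1:
            raise TrajectoryError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")
        F = self.n_frames
        for name in ("box", "upper_heads", "lower_heads", "residue_com"):
            arr = getattr(self, name)
            if arr.shape[0] != F:
                raise TrajectoryError(f"{name} has {arr.shape[0]} frames, expected {F}")
        if self.residue_com.ndim != 3:
            raise TrajectoryError("residue_com must be (frames, residues, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_residues(self) -> int:
        return self.residue_com.shape[1]

    def toxin_com(self) -> np.ndarray:
        """Mass-weighted peptide center of mass per frame, (F, 3).

        Falls back to the unweighted mean when residue masses are absent.
        """
        if self.residue_masses is not None:
            w = np.asarray(self.residue_masses, dtype=float)
            w = w / w.sum()
            return np.einsum("frx,r->fx", self.residue_com, w)
        return self.residue_com.mean(axis=1)

    # ------------------------------------------------------------------ IO

    def to_frame_table(self) -> pd.DataFrame:
        """Serialize to the canonical long-format table."""
        rows: list[pd.DataFrame] = []

        def block(coords: np.ndarray, role: str, species, charges) -> None:
            F, N, _ = coords.shape
            frame = np.repeat(np.arange(F), N)
            df = pd.DataFrame(
                {
                    "frame": frame,
                    "time_ns": self.times[frame],
                    "particle_id": np.tile(np.arange(N), F),
                    "role": role,
                    "species": np.tile(np.asarray(species, dtype=object), F)
                    if species is not None
                    else "",
                    "x": coords[:, :, 0].ravel(),
                    "y": coords[:, :, 1].ravel(),
                    "z": coords[:, :, 2].ravel(),
                    "charge": np.tile(np.asarray(charges, dtype=float), F)
                    if charges is not None
                    else 0.0,
                }
            )
            rows.append(df)

        block(self.upper_heads, "lipid_head_upper", self.upper_species, None)
        block(self.lower_heads, "lipid_head_lower", self.lower_species, None)
        block(self.residue_com, "residue_com", None, self.residue_charges)
        if self.sidechain_com is not None:
            block(self.sidechain_com, "sidechain_com", None, None)
        if self.ions is not None:
            block(self.ions, "ion", None, None)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame_table().to_csv(path, index=False)

    @classmethod
    def from_frame_table(
        cls, table: pd.DataFrame, box: np.ndarray | None = None
    ) -> "Trajectory":
        """Rebuild a trajectory from the canonical long-format table.

        The box is not stored in the table; pass it explicitly or a large
        dummy box is assumed (analyses that need it will say so).
        """
        frames = np.sort(table["frame"].unique())
        times = (
            table.drop_duplicates("frame").sort_values("frame")["time_ns"].to_numpy()
        )

        def gather(role: str) -> np.ndarray | None:
            sub = table[table["role"] == role]
            if sub.empty:
                return None
            sub = sub.sort_values(["frame", "particle_id"])
            n = sub["particle_id"].nunique()
            return sub[["x", "y", "z"]].to_numpy().reshape(len(frames), n, 3)

        upper = gather("lipid_head_upper")
        lower = gather("lipid_head_lower")
        res = gather("residue_com")
        if upper is None or lower is None or res is None:
            raise TrajectoryError(
                "table must contain lipid_head_upper, lipid_head_lower and residue_com rows"
            )
        res_rows = table[(table["role"] == "residue_com") & (table["frame"] == frames[0])]
        charges = res_rows.sort_values("particle_id")["charge"].to_numpy()
        upper_rows = table[
            (table["role"] == "lipid_head_upper") & (table["frame"] == frames[0])
        ].sort_values("particle_id")
        species = upper_rows["species"].to_numpy() if "species" in upper_rows else None
        if box is None:
            box = np.full((len(frames), 3), 1e6)
        return cls(
            times=times,
            box=np.asarray(box, dtype=float),
            upper_heads=upper,
            lower_heads=lower,
            residue_com=res,
            sidechain_com=gather("sidechain_com"),
            ions=gather("ion"),
            residue_charges=charges,
            upper_species=species,
        )

    @classmethod
    def from_csv(cls, path, box: np.ndarray | None = None) -> "Trajectory":
        return cls.from_frame_table(pd.read_csv(path), box=box)


def unwrap(positions: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping of a time series of positions.

    ``positions`` is (F, ..., k) and ``box_lengths`` broadcastable to the last
    axis. Jumps larger than half a box length between consecutive frames are
    interpreted as wraps (minimum-image convention).
    """
    positions = np.asarray(positions, dtype=float)
    box_lengths = np.asarray(box_lengths, dtype=float)
    deltas = np.diff(positions, axis=0)
    deltas -= np.round(deltas / box_lengths) * box_lengths
    out = np.concatenate([positions[:1], positions[:1] + np.cumsum(deltas, axis=0)])
    return out
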