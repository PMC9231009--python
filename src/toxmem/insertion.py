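"""Membrane-partitioning metrics: leaflet fitting, insertion scoring, descriptors.

The partitioning analysis classifies, frame by frame, which peptide residues
lie below the lipid head-group surface of the toxin-proximal (upper) leaflet.
The surface is a least-squares plane z = a·x + b·y + c fit to the leaflet's
head positions. A residue's insertion probability Ip is the fraction of
analysed frames in which its reference point (residue COM, side-chain COM, or
— for the stricter variant — any point below the mean acyl C1 carbon plane)
falls below that surface. The insertion score

    IS = Σ_{i=1..NR} Ip_i

sums Ip over all NR residues, so IS ranges from 0 to NR (41 for SNX-482).
Counting is gated: no insertion event is scored before the first frame at
which the toxin COM comes within 0.5 nm of the fitted surface, which excludes
spurious collisional contacts unrelated to binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal
import warnings

import numpy as np

from .trajectory import Trajectory

NO_ONSET = -1
NO_PLATEAU = -1

Criterion = Literal["residue_com", "sidechain_com", "below_c1"]


class InsertionError(ValueError):
    pass


@dataclass
class LeafletFit:
    """Least-squares plane z = a·x + b·y + c through one leaflet's heads."""

    leaflet: str
    a: float
    b: float
    c: float
    rms_residual: float

    def surface_z(self, x, y):
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


@dataclass
class InsertionMatrix:
    inserted: np.ndarray        # (F, R) bool
    criterion: Criterion
    onset_frame: int            # NO_ONSET if gate never satisfied


@dataclass
class InsertionProfile:
    ip: np.ndarray              # (R,) in [0, 1]
    window: tuple[int, int]     # [start, end) frames
    n_residues: int


def fit_leaflet(
    heads: np.ndarray | Trajectory, leaflet: str = "upper", frame: int | None = None
) -> LeafletFit:
    """Fit a plane to one leaflet's head-group positions in a single frame.

    Accepts either an (N, 3) coordinate array or a Trajectory plus frame
    index and leaflet tag.
    """
    if isinstance(heads, Trajectory):
        if frame is None:
            raise InsertionError("frame index required with a Trajectory input")
        coords = (heads.upper_heads if leaflet == "upper" else heads.lower_heads)[frame]
    else:
        coords = np.asarray(heads, dtype=float)
    if coords.shape[0] < 3:
        raise InsertionError("need at least 3 head positions to fit a plane")
    A = np.column_stack([coords[:, 0], coords[:, 1], np.ones(len(coords))])
    # collinearity check via rank of the design matrix
    if np.linalg.matrix_rank(A) < 3:
        raise InsertionError("head positions are collinear; plane fit is degenerate")
    coef, _, _, _ = np.linalg.lstsq(A, coords[:, 2], rcond=None)
    resid = coords[:, 2] - A @ coef
    return LeafletFit(
        leaflet=leaflet,
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _upper_fits(traj: Trajectory) -> list[LeafletFit]:
    return [fit_leaflet(traj.upper_heads[f]) for f in range(traj.n_frames)]


def first_within_gate(distances: np.ndarray, gate_nm: float = 0.5) -> int:
    """Index of the first distance *strictly* below the gate; NO_ONSET if none.

    A distance exactly equal to the gate does not count as contact.
    """
    below = np.asarray(distances) < gate_nm
    idx = np.flatnonzero(below)
    return int(idx[0]) if len(idx) else NO_ONSET


def gate_onset(
    traj: Trajectory, gate_nm: float = 0.5, fits: list[LeafletFit] | None = None
) -> int:
    """First frame where toxin COM sits strictly closer than gate_nm above the
    fitted upper surface (evaluated at the COM's x, y). Returns NO_ONSET when
    the gate is never satisfied."""
    fits = fits if fits is not None else _upper_fits(traj)
    com = traj.toxin_com()
    dist = np.array(
        [com[f, 2] - fits[f].surface_z(com[f, 0], com[f, 1]) for f in range(traj.n_frames)]
    )
    return first_within_gate(dist, gate_nm)


def classify_insertions(
    traj: Trajectory,
    criterion: Criterion = "residue_com",
    gate_nm: float = 0.5,
) -> InsertionMatrix:
    """Per-frame, per-residue insertion classification under one criterion.

    residue_com     — residue COM z below the fitted upper-leaflet surface.
    sidechain_com   — side-chain COM z below the same surface.
    below_c1        — residue COM z below the mean acyl C1 carbon z of the
                      upper leaflet (a horizontal plane; stricter since the
                      C1 plane lies below the heads).

    All entries before the onset frame (see :func:`gate_onset`) are False.
    """
    if criterion == "sidechain_com":
        if traj.sidechain_com is None:
            raise InsertionError(
                "criterion 'sidechain_com' requires side-chain COM coordinates "
                "(missing: sidechain_com)"
            )
        ref = traj.sidechain_com
    elif criterion in ("residue_com", "below_c1"):
        ref = traj.residue_com
    else:
        raise InsertionError(f"unknown criterion {criterion!r}")
    if criterion == "below_c1" and traj.c1_upper_z is None:
        raise InsertionError(
            "criterion 'below_c1' requires per-lipid C1 carbon z (missing: c1_upper_z)"
        )

    fits = _upper_fits(traj)
    onset = gate_onset(traj, gate_nm=gate_nm, fits=fits)
    F, R = traj.n_frames, traj.n_residues
    mat = np.zeros((F, R), dtype=bool)
    if onset == NO_ONSET:
        warnings.warn(
            "toxin COM never came within the contact gate; insertion matrix is all-False",
            stacklevel=2,
        )
        return InsertionMatrix(mat, criterion, NO_ONSET)

    for f in range(onset, F):
        if criterion == "below_c1":
            plane_z = float(np.mean(traj.c1_upper_z[f]))
            mat[f] = ref[f, :, 2] < plane_z
        else:
            surf = fits[f].surface_z(ref[f, :, 0], ref[f, :, 1])
            mat[f] = ref[f, :, 2] < surf
    return InsertionMatrix(mat, criterion, onset)


def insertion_probability(
    matrix: InsertionMatrix, window: tuple[int, int] | None = None
) -> InsertionProfile:
    """Per-residue fraction of window frames classified inserted.

    ``window`` is a [start, end) frame range; it defaults to onset→end. The
    start may not precede the onset frame — pre-contact frames are excluded
    from both numerator and denominator.
    """
    F, R = matrix.inserted.shape
    onset = matrix.onset_frame if matrix.onset_frame != NO_ONSET else F
    start, end = window if window is not None else (onset, F)
    if not (0 <= start < end <= F):
        raise InsertionError(f"empty or out-of-range window {(start, end)} for {F} frames")
    if start < onset:
        raise InsertionError(
            f"window start {start} precedes onset frame {onset}; "
            "pre-contact frames are excluded from Ip"
        )
    ip = matrix.inserted[start:end].mean(axis=0)
    return InsertionProfile(ip=ip, window=(start, end), n_residues=R)


def insertion_score(profile: InsertionProfile) -> float:
    """IS = Σ_i Ip_i, in [0, n_residues]."""
    return float(np.sum(profile.ip))


def is_time_derivative(
    traj: Trajectory,
    window_ns: float = 500.0,
    criterion: Criterion = "residue_com",
    gate_nm: float = 0.5,
) -> tuple[float, np.ndarray, np.ndarray]:
    """IS per non-overlapping time window and its OLS slope in IS units / μs.

    Windows of ``window_ns`` are laid out from the onset frame; incomplete
    trailing windows are dropped. Returns (slope_per_us, window_mid_times_ns,
    window_is_values).
    """
    matrix = classify_insertions(traj, criterion=criterion, gate_nm=gate_nm)
    if matrix.onset_frame == NO_ONSET:
        raise InsertionError("no onset; IS time series undefined")
    t = traj.times
    t0 = t[matrix.onset_frame]
    edges = np.arange(t0, t[-1] + 1e-9, window_ns)
    if len(edges) < 3:
        raise InsertionError("need at least 2 complete windows for a slope")
    mids, values = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = np.where((t >= lo) & (t < hi))[0]
        if len(sel) == 0:
            continue
        prof = insertion_probability(
            matrix, window=(int(sel[0]), int(sel[-1]) + 1)
        )
        mids.append((lo + hi) / 2.0)
        values.append(insertion_score(prof))
    if len(values) < 2:
        raise InsertionError("need at least 2 complete windows for a slope")
    mids_a = np.asarray(mids)
    vals_a = np.asarray(values)
    slope_per_ns = np.polyfit(mids_a, vals_a, 1)[0]
    return float(slope_per_ns * 1e3), mids_a, vals_a


def com_distance_and_plateau(
    traj: Trajectory,
    slope_tol: float = 1e-3,     # nm/ns
    window: int = 10,            # frames per moving OLS window
) -> tuple[np.ndarray, int]:
    """Toxin-COM to membrane-COM z-distance per frame, and plateau start.

    The membrane COM is the mean z of all head groups. The plateau start is
    the first frame from which every subsequent moving-window OLS slope of
    the distance stays below ``slope_tol`` in magnitude; NO_PLATEAU with a
    warning when no such frame exists.
    """
    if traj.n_frames < window:
        raise InsertionError(f"need at least {window} frames")
    mem_z = np.concatenate(
        [traj.upper_heads[..., 2], traj.lower_heads[..., 2]], axis=1
    ).mean(axis=1)
    dist = traj.toxin_com()[:, 2] - mem_z
    t = traj.times
    n_win = traj.n_frames - window + 1
    slopes = np.empty(n_win)
    for i in range(n_win):
        slopes[i] = np.polyfit(t[i : i + window], dist[i : i + window], 1)[0]
    flat = np.abs(slopes) < slope_tol
    # first index after which flatness persists to the end
    plateau = NO_PLATEAU
    for i in range(n_win - 1, -1, -1):
        if flat[i]:
            plateau = i
        else:
            break
    if plateau == NO_PLATEAU:
        warnings.warn("no plateau found in COM distance series", stacklevel=2)
    return dist, plateau


def membrane_descriptors(
    traj: Trajectory, frame: int
) -> dict[str, float]:
    """Area per lipid (nm², per leaflet and averaged) and thickness (nm)."""
    n_up = traj.upper_heads.shape[1]
    n_lo = traj.lower_heads.shape[1]
    if n_up == 0 or n_lo == 0:
        raise InsertionError("both leaflets must be populated")
    area = float(traj.box[frame, 0] * traj.box[frame, 1])
    apl_up = area / n_up
    apl_lo = area / n_lo
    thickness = float(
        traj.upper_heads[frame, :, 2].mean() - traj.lower_heads[frame, :, 2].mean()
    )
    return {
        "area_per_lipid_upper": apl_up,
        "area_per_lipid_lower": apl_lo,
        "area_per_lipid": (apl_up + apl_lo) / 2.0,
        "thickness": thickness,
    }


def axial_density(
    traj: Trajectory, species: str = "ion", bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Number-density profile along z, averaged over frames.

    Returns (bin_centers_nm, density_nm^-3). The histogram of z positions is
    normalized per frame and per bin volume (lateral box area × bin width),
    so integrating density over z and multiplying by the lateral area
    recovers the mean particle count per frame.
    """
    if species == "ion":
        if traj.ions is None:
            raise InsertionError("trajectory has no ion coordinates")
        coords = traj.ions
    elif species == "lipid_head":
        coords = np.concatenate([traj.upper_heads, traj.lower_heads], axis=1)
    elif species == "residue_com":
        coords = traj.residue_com
    else:
        raise InsertionError(f"unknown species {species!r}")
    z = coords[..., 2].ravel()
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    area = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    density = counts / (traj.n_frames * area * bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, density
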