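"""Synthetic trajectory and time-series generators with known ground truth.

The analyses in this package (insertion scoring, dipole orientation, lateral
diffusion, block-average errors) normally consume MD output. The generators
here emulate the *statistical* structure of such output — a planar two-leaflet
bilayer with thermal head-group roughness, a peptide approaching and inserting
a prescribed residue patch, Brownian motion at a prescribed diffusion
coefficient, AR(1)-correlated scalar series — so every estimator can be tested
against a closed-form ground truth. No force-field physics is involved.

Every generator is a pure function of its spec: a fixed seed yields bitwise
identical output, and each generator draws from its own independently seeded
stream so adding one call cannot shift another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .trajectory import Trajectory
from .units import CM2_PER_S_TO_NM2_PER_NS

GATE_NM = 0.5  # toxin-COM-to-surface contact gate used throughout


class FixtureError(RuntimeError):
    """Packaged fixture file missing or failing its integrity checks."""


class SpecError(ValueError):
    """A generator spec violates its invariants."""


# --------------------------------------------------------------------------
# Peptide fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideFixture:
    """The SNX-482 peptide: sequence, formal charges and residue masses.

    ``residue_charges`` are integer formal charges at neutral pH with His
    neutral; they sum to the toxin's net charge of −2. ``hydrophobic_patch``
    lists the 1-based residue numbers of the membrane-inserting patch
    (residues 9–12 and 29–35).
    """

    sequence: str
    residue_charges: np.ndarray
    residue_masses: np.ndarray
    hydrophobic_patch: tuple[int, ...]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def net_charge(self) -> int:
        return int(self.residue_charges.sum())

    def residue(self, number: int) -> tuple[str, int, float]:
        """(one-letter code, formal charge, mass) for a 1-based residue number."""
        i = number - 1
        if not 0 <= i < self.n_residues:
            raise IndexError(f"residue number {number} out of range 1..{self.n_residues}")
        return self.sequence[i], int(self.residue_charges[i]), float(self.residue_masses[i])


def load_snx482_fixture() -> PeptideFixture:
    """Load the packaged SNX-482 fixture (FASTA sequence + JSON sidecar).

    Validates the invariants the toxin is known to satisfy: 41 residues,
    6 cysteines (ICK motif), net formal charge −2.
    """
    try:
        data = resources.files("toxmem.data")
        fasta = (data / "snx482.fasta").read_text()
        sidecar = json.loads((data / "snx482.json").read_text())
    except (FileNotFoundError, json.JSONDecodeError) as exc:
        raise FixtureError(f"SNX-482 fixture missing or corrupt: {exc}") from exc

    seq_lines = [ln.strip() for ln in fasta.splitlines() if ln and not ln.startswith(">")]
    sequence = "".join(seq_lines)
    residues = sidecar["residues"]
    if "".join(r["aa"] for r in residues) != sequence:
        raise FixtureError("FASTA sequence and JSON sidecar disagree")
    charges = np.array([r["charge"] for r in residues], dtype=int)
    masses = np.array([r["mass_da"] for r in residues], dtype=float)

    if len(sequence) != 41:
        raise FixtureError(f"expected 41 residues, got {len(sequence)}")
    if sequence.count("C") != 6:
        raise FixtureError("expected 6 cysteines")
    if int(charges.sum()) != -2:
        raise FixtureError("expected net formal charge -2")
    return PeptideFixture(
        sequence=sequence,
        residue_charges=charges,
        residue_masses=masses,
        hydrophobic_patch=tuple(sidecar["hydrophobic_patch"]),
    )


# --------------------------------------------------------------------------
# Bilayer
# --------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Planar two-leaflet bilayer with thermal head-group roughness.

    Defaults follow the all-atom construction used as the reference system:
    an ~11.5 × 11.5 nm patch of 308 lipids at a 3:1 POPC:POPG ratio.
    """

    box_xy: tuple[float, float] = (11.5, 11.5)
    n_lipids: int = 308
    popg_fraction: float = 0.25
    leaflet_half_thickness: float = 2.0
    head_roughness_sigma: float = 0.05
    lateral_jitter_sigma: float = 0.1
    n_frames: int = 100
    frame_dt: float = 1.0   # ns
    box_z: float = 8.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids % 2 != 0:
            raise SpecError("n_lipids must be even (two equal leaflets)")
        if not 0.0 <= self.popg_fraction <= 1.0:
            raise SpecError("popg_fraction must lie in [0, 1]")
        if self.head_roughness_sigma < 0 or self.lateral_jitter_sigma < 0:
            raise SpecError("jitter sigmas must be non-negative")


@dataclass
class Bilayer:
    times: np.ndarray          # (F,)
    box: np.ndarray            # (F, 3)
    upper_heads: np.ndarray    # (F, N/2, 3)
    lower_heads: np.ndarray    # (F, N/2, 3)
    upper_species: np.ndarray  # (N/2,) 'POPC' | 'POPG'
    lower_species: np.ndarray
    spec: BilayerSpec

    @property
    def species_counts(self) -> dict[str, int]:
        labels, counts = np.unique(
            np.concatenate([self.upper_species, self.lower_species]), return_counts=True
        )
        return dict(zip(labels.tolist(), counts.tolist()))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _leaflet_grid(n: int, box_xy: tuple[float, float]) -> np.ndarray:
    """Regular (near-square) lattice of n lateral positions inside the box."""
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    gx = (np.arange(nx) + 0.5) * box_xy[0] / nx
    gy = (np.arange(ny) + 0.5) * box_xy[1] / ny
    xy = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    return xy[:n]


def make_bilayer(spec: BilayerSpec) -> Bilayer:
    """Build per-frame leaflet head coordinates and lipid species labels.

    Heads sit on a regular lateral grid with Gaussian lateral jitter; leaflet
    planes are at ±leaflet_half_thickness with Gaussian z-jitter of width
    head_roughness_sigma. The POPG count is round-half-away-from-zero of
    popg_fraction × n_lipids, split evenly across leaflets with an odd
    remainder assigned to the upper leaflet.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x_B17A]))
    per_leaflet = spec.n_lipids // 2
    n_popg = _round_half_away(spec.popg_fraction * spec.n_lipids)
    popg_upper = n_popg // 2 + n_popg % 2
    popg_lower = n_popg // 2

    def species(n_popg_leaflet: int) -> np.ndarray:
        s = np.array(["POPC"] * per_leaflet, dtype=object)
        s[:n_popg_leaflet] = "POPG"
        return s

    base_xy = _leaflet_grid(per_leaflet, spec.box_xy)
    F = spec.n_frames
    times = np.arange(F) * spec.frame_dt
    box = np.tile(np.array([*spec.box_xy, spec.box_z]), (F, 1))

    def leaflet(sign: float) -> np.ndarray:
        xy = base_xy[None] + rng.normal(0.0, spec.lateral_jitter_sigma, (F, per_leaflet, 2))
        z = sign * spec.leaflet_half_thickness + rng.normal(
            0.0, spec.head_roughness_sigma, (F, per_leaflet)
        )
        return np.concatenate([xy, z[..., None]], axis=-1)

    return Bilayer(
        times=times,
        box=box,
        upper_heads=leaflet(+1.0),
        lower_heads=leaflet(-1.0),
        upper_species=species(popg_upper),
        lower_species=species(popg_lower),
        spec=spec,
    )


# --------------------------------------------------------------------------
# Brownian motion
# --------------------------------------------------------------------------

@dataclass
class BrownianSpec:
    """Free Brownian motion at diffusion coefficient D (cm^2/s)."""

    D: float
    n_dims: int = 3
    dt: float = 10.0       # ps
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise SpecError("D must be non-negative")
        if self.n_dims not in (2, 3):
            raise SpecError("n_dims must be 2 or 3")
        if self.dt <= 0 or self.n_steps < 1:
            raise SpecError("dt must be positive and n_steps >= 1")


def make_brownian(spec: BrownianSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (times_ns, positions_nm) of shape (n_steps+1,), (n_steps+1, n_dims).

    Per-dimension increments are i.i.d. Gaussian with variance 2·D·dt after
    converting D from cm^2/s to nm^2/ns and dt from ps to ns; the walk starts
    at the origin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x_B20]))
    dt_ns = spec.dt * 1e-3
    d_nm = spec.D * CM2_PER_S_TO_NM2_PER_NS
    sigma = np.sqrt(2.0 * d_nm * dt_ns)
    steps = rng.normal(0.0, 1.0, (spec.n_steps, spec.n_dims)) * sigma
    pos = np.vstack([np.zeros((1, spec.n_dims)), np.cumsum(steps, axis=0)])
    times = np.arange(spec.n_steps + 1) * dt_ns
    return times, pos


# --------------------------------------------------------------------------
# Binding trajectory
# --------------------------------------------------------------------------

@dataclass
class BindingScenario:
    """A peptide approaching the upper leaflet and inserting a residue patch.

    ``target_depths`` gives each residue's equilibrium z-offset relative to
    the upper-leaflet plane once bound (negative = inserted below the heads).
    Before ``onset_frame`` the peptide descends rigidly from ``start_distance``
    above the surface; from ``onset_frame`` on, per-residue z fluctuates about
    its target depth with ``depth_noise_sigma``. If ``onset_frame`` is None it
    is derived from ``approach_speed``.
    """

    target_depths: np.ndarray
    start_distance: float = 2.5
    approach_speed: float = 0.05   # nm/ns
    onset_frame: int | None = None
    depth_noise_sigma: float = 0.0
    lateral_spread: float = 1.0
    seed: int = 0


def make_binding_trajectory(
    bilayer: Bilayer, scenario: BindingScenario, fixture: PeptideFixture
) -> Trajectory:
    """Assemble a full synthetic binding trajectory with ground-truth labels.

    The toxin COM-to-surface distance decreases to < 0.5 nm at the onset frame
    and plateaus; after onset each residue's z follows its target depth plus
    Gaussian noise. The ground-truth insertion matrix (frame × residue, True
    where the residue's z lies strictly below the *true* leaflet plane, gated
    at onset) is attached for oracle tests, as are the fixture's per-residue
    charges so dipole analysis is runnable.
    """
    depths = np.asarray(scenario.target_depths, dtype=float)
    if len(depths) != fixture.n_residues:
        raise SpecError(
            f"target_depths has {len(depths)} entries, expected {fixture.n_residues}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0x_B1AD]))
    F = bilayer.spec.n_frames
    R = fixture.n_residues
    plane = bilayer.spec.leaflet_half_thickness
    masses = fixture.residue_masses
    w = masses / masses.sum()

    onset = scenario.onset_frame
    if onset is None:
        travel = scenario.start_distance - GATE_NM
        onset = int(np.ceil(travel / (scenario.approach_speed * bilayer.spec.frame_dt)))
    if not 0 < onset < F:
        raise SpecError(f"onset_frame {onset} outside (0, {F})")

    # lateral layout: residues clustered around the box center
    center = np.array(bilayer.spec.box_xy) / 2.0
    lateral = center + rng.normal(0.0, scenario.lateral_spread / 3.0, (R, 2))

    # bound-state COM offset of each residue relative to the peptide COM
    com_depth = float(w @ depths)
    rel = depths - com_depth

    z = np.empty((F, R))
    noise = rng.normal(0.0, scenario.depth_noise_sigma, (F, R))
    frames = np.arange(F)
    # pre-onset: rigid descent, COM-to-plane distance from start_distance to
    # just-above-gate; crosses below the gate exactly at the onset frame
    pre = frames < onset
    d_pre = GATE_NM + (scenario.start_distance - GATE_NM) * (onset - frames[pre]) / onset
    z[pre] = plane + d_pre[:, None] + rel[None, :]
    z[~pre] = plane + depths[None, :] + noise[~pre]

    xyz = np.empty((F, R, 3))
    xyz[:, :, :2] = lateral[None]
    xyz[:, :, 2] = z

    truth = np.zeros((F, R), dtype=bool)
    truth[~pre] = z[~pre] < plane

    return Trajectory(
        times=bilayer.times,
        box=bilayer.box,
        upper_heads=bilayer.upper_heads,
        lower_heads=bilayer.lower_heads,
        residue_com=xyz,
        residue_charges=fixture.residue_charges.astype(float),
        residue_masses=masses,
        upper_species=bilayer.upper_species,
        lower_species=bilayer.lower_species,
        ground_truth_insertion=truth,
        ground_truth_onset=onset,
    )


# --------------------------------------------------------------------------
# AR(1) series
# --------------------------------------------------------------------------

@dataclass
class CorrelatedSeriesSpec:
    """Stationary AR(1) series: mean, stationary sigma, lag-1 autocorrelation phi."""

    mean: float = 0.0
    sigma: float = 1.0
    phi: float = 0.0
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise SpecError("|phi| must be < 1 for stationarity")
        if self.sigma < 0:
            raise SpecError("sigma must be non-negative")


def make_correlated_series(spec: CorrelatedSeriesSpec) -> np.ndarray:
    """Stationary AR(1): x_t − μ = φ(x_{t−1} − μ) + ε_t, Var(x) = σ²."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x_A21]))
    innov_sd = spec.sigma * np.sqrt(1.0 - spec.phi**2)
    x = np.empty(spec.n_samples)
    x[0] = rng.normal(0.0, spec.sigma)
    eps = rng.normal(0.0, innov_sd, spec.n_samples)
    for t in range(1, spec.n_samples):
        x[t] = spec.phi * x[t - 1] + eps[t]
    return spec.mean + x


def make_pair_energy_table(
    pair_means: dict[str, tuple[float, float]],
    totals_bonded_mean: float = 100.0,
    sigma: float = 5.0,
    phi: float = 0.5,
    n_frames: int = 2048,
    frame_dt: float = 0.001,
    seed: int = 0,
):
    """Emulate a per-frame pair-interaction energy log with AR(1) noise.

    ``pair_means`` maps each pair label to its (vdw, ele) mean in kcal/mol.
    Per-frame totals are built as the exact sums of the pair columns (plus an
    independent bonded term), so the decomposition partition identity holds
    by construction. Returns an :class:`~toxmem.energetics.PairEnergyTable`.
    """
    import pandas as pd

    from .energetics import PAIR_VOCABULARY, PairEnergyTable

    bad = set(pair_means) - set(PAIR_VOCABULARY)
    if bad:
        raise SpecError(f"unknown pair labels: {sorted(bad)}")
    times = np.arange(n_frames) * frame_dt
    rows = []
    vdw_sum = np.zeros(n_frames)
    ele_sum = np.zeros(n_frames)
    for k, (label, (vdw_mu, ele_mu)) in enumerate(sorted(pair_means.items())):
        vdw = make_correlated_series(
            CorrelatedSeriesSpec(vdw_mu, sigma, phi, n_frames, seed=seed * 1000 + 2 * k)
        )
        ele = make_correlated_series(
            CorrelatedSeriesSpec(ele_mu, sigma, phi, n_frames, seed=seed * 1000 + 2 * k + 1)
        )
        vdw_sum += vdw
        ele_sum += ele
        rows.append(
            pd.DataFrame({"time": times, "pair": label, "vdw": vdw, "ele": ele})
        )
    bond = make_correlated_series(
        CorrelatedSeriesSpec(totals_bonded_mean, sigma, phi, n_frames, seed=seed * 1000 + 999)
    )
    pairs = pd.concat(rows, ignore_index=True)
    totals = pd.DataFrame(
        {
            "time": times,
            "tot_pot": vdw_sum + ele_sum + bond,
            "tot_vdw": vdw_sum,
            "tot_ele": ele_sum,
            "tot_bond": bond,
        }
    )
    return PairEnergyTable(pairs=pairs, totals=totals)
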