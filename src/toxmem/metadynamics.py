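"""One-dimensional well-tempered metadynamics on analytic model potentials.

The engine runs overdamped Langevin dynamics on a 1D collective variable x
under U(x) plus an adaptive history-dependent bias. Every ``deposit_stride``
steps a repulsive Gaussian hill

    G(x; c, d) = exp(−(x − c)² / (2 d²))

is deposited at the current position with the well-tempered height

    h = W0 · exp(−V(x) / (kB ΔT)),

where V is the bias accumulated so far and ΔT the bias temperature, so hills
shrink as a region fills. Soft harmonic walls confine sampling to a window.
For long runs the converged bias estimates the potential of mean force via

    PMF(x) ≅ −(T + ΔT)/ΔT · V(x) + C,

with C fixed so the PMF minimum is zero. As ΔT → ∞ the scheme reduces to
standard (untempered) metadynamics with constant hill height W0.

Hills are evaluated exactly (direct Gaussian summation, no grid splines);
the inner loop is JIT-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import KB_KCAL_MOL_K


class MetadError(ValueError):
    pass


@dataclass
class WTParams:
    """Well-tempered bias parameters.

    W0              initial hill height, kcal/mol
    hill_width      Gaussian width d in CV units
    delta_T         bias temperature ΔT, K
    temperature     system temperature T, K
    deposit_stride  steps between hill depositions
    """

    W0: float = 1.0
    hill_width: float = 0.05
    delta_T: float = 1500.0
    temperature: float = 298.0
    deposit_stride: int = 200
    kB: float = KB_KCAL_MOL_K

    def __post_init__(self) -> None:
        if self.W0 <= 0 or self.hill_width <= 0 or self.delta_T <= 0:
            raise MetadError("W0, hill_width and delta_T must be positive")
        if self.deposit_stride < 1:
            raise MetadError("deposit_stride must be >= 1")

    @property
    def pmf_scale(self) -> float:
        """(T + ΔT)/ΔT, the bias-to-PMF conversion factor."""
        return (self.temperature + self.delta_T) / self.delta_T


@dataclass
class HillHistory:
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    width: float = 0.05

    @property
    def n_hills(self) -> int:
        return len(self.centers)

    def bias(self, x) -> np.ndarray | float:
        """Exact bias V(x) = Σ h_i exp(−(x−c_i)²/(2d²)); x scalar or array."""
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        v = np.zeros_like(xa)
        if self.n_hills:
            diff = xa[:, None] - self.centers[None, :]
            v = (self.heights[None, :] * np.exp(-(diff**2) / (2 * self.width**2))).sum(
                axis=1
            )
        return v if np.ndim(x) else float(v[0])

    def to_table(self) -> np.ndarray:
        """(n_hills, 4) array: hill index, center, height, width."""
        return np.column_stack(
            [
                np.arange(self.n_hills, dtype=float),
                self.centers,
                self.heights,
                np.full(self.n_hills, self.width),
            ]
        )


@dataclass
class WallSpec:
    """Soft harmonic walls at the CV window edges."""

    lower: float
    upper: float
    force_constant: float = 10.0  # kcal/mol per CV-unit²

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise MetadError("wall lower bound must be below upper bound")

    def energy(self, x: float) -> float:
        if x < self.lower:
            return 0.5 * self.force_constant * (x - self.lower) ** 2
        if x > self.upper:
            return 0.5 * self.force_constant * (x - self.upper) ** 2
        return 0.0


@dataclass
class ModelPotential:
    """Analytic potential with a closed-form reference PMF (itself, shifted)."""

    name: str
    params: tuple

    def energy(self, x):
        return _potential_energy_vec(self.name, self.params, np.asarray(x, dtype=float))

    def reference_pmf(self, grid: np.ndarray) -> np.ndarray:
        u = self.energy(grid)
        return u - u.min()


def double_well(barrier: float = 3.0, half_separation: float = 1.0) -> ModelPotential:
    """Symmetric double well U = barrier·((x/a)² − 1)², minima at ±a, barrier at 0."""
    return ModelPotential("double_well", (barrier, half_separation))


def harmonic(k: float = 1.0, x0: float = 0.0) -> ModelPotential:
    return ModelPotential("harmonic", (k, x0))


def flat() -> ModelPotential:
    return ModelPotential("flat", ())


def _potential_energy_vec(name: str, params: tuple, x: np.ndarray) -> np.ndarray:
    if name == "double_well":
        b, a = params
        return b * ((x / a) ** 2 - 1.0) ** 2
    if name == "harmonic":
        k, x0 = params
        return 0.5 * k * (x - x0) ** 2
    if name == "flat":
        return np.zeros_like(x)
    raise MetadError(f"unknown model potential {name!r}")


_POT_IDS = {"flat": 0, "harmonic": 1, "double_well": 2}


def bias_and_deposit(
    x: float, hills: HillHistory, params: WTParams
) -> tuple[HillHistory, float]:
    """Evaluate the bias at x and deposit one tempered hill there.

    Returns the updated history and the bias value *before* the deposit. The
    new hill's height is W0·exp(−V(x)/(kB ΔT)).
    """
    v = float(hills.bias(x))
    h = params.W0 * np.exp(-v / (params.kB * params.delta_T))
    new = HillHistory(
        centers=np.append(hills.centers, x),
        heights=np.append(hills.heights, h),
        width=params.hill_width,
    )
    return new, v


@njit(cache=True)
def _run_core(
    x0, n_steps, dt, friction, kT, pot_id, p0, p1,
    wall_lo, wall_hi, wall_k,
    w0, d, kb_dT, stride, noise, sample_stride,
):  # pragma: no cover - exercised through run_sampler
    n_hills_max = n_steps // stride + 1
    centers = np.empty(n_hills_max)
    heights = np.empty(n_hills_max)
    n_hills = 0
    n_samples = n_steps // sample_stride + 1
    xs = np.empty(n_samples)
    xs[0] = x0
    isamp = 1
    x = x0
    inv2d2 = 1.0 / (2.0 * d * d)
    cutoff2 = (8.0 * d) ** 2
    mob = dt / friction
    noise_pref = np.sqrt(2.0 * kT * dt / friction)
    for step in range(n_steps):
        # physical force −dU/dx
        if pot_id == 2:
            s = x / p1
            force = -4.0 * p0 * (s * s - 1.0) * s / p1
        elif pot_id == 1:
            force = -p0 * (x - p1)
        else:
            force = 0.0
        # wall force
        if x < wall_lo:
            force -= wall_k * (x - wall_lo)
        elif x > wall_hi:
            force -= wall_k * (x - wall_hi)
        # bias force (exact Gaussian sum, truncated at 8 widths)
        for j in range(n_hills):
            dx = x - centers[j]
            dx2 = dx * dx
            if dx2 < cutoff2:
                g = heights[j] * np.exp(-dx2 * inv2d2)
                force += g * dx * 2.0 * inv2d2
        x = x + mob * force + noise_pref * noise[step]
        if not np.isfinite(x):
            return xs[:isamp], centers[:n_hills], heights[:n_hills], step
        if (step + 1) % stride == 0:
            v = 0.0
            for j in range(n_hills):
                dx = x - centers[j]
                dx2 = dx * dx
                if dx2 < cutoff2:
                    v += heights[j] * np.exp(-dx2 * inv2d2)
            centers[n_hills] = x
            heights[n_hills] = w0 * np.exp(-v / kb_dT)
            n_hills += 1
        if (step + 1) % sample_stride == 0 and isamp < n_samples:
            xs[isamp] = x
            isamp += 1
    return xs[:isamp], centers[:n_hills], heights[:n_hills], -1


@dataclass
class LangevinSpec:
    friction: float = 1.0
    dt: float = 5e-3
    n_steps: int = 100_000
    temperature: float | None = None  # defaults to WTParams.temperature
    x0: float = 0.0
    seed: int = 0
    sample_stride: int = 10


def run_sampler(
    potential: ModelPotential,
    params: WTParams,
    walls: WallSpec,
    langevin: LangevinSpec,
) -> tuple[np.ndarray, HillHistory]:
    """Overdamped Langevin dynamics on U + bias + walls with hill deposition.

    Returns (sampled positions, hill history). Deterministic under a fixed
    seed. Raises on a diverging integration (dt/friction too aggressive).
    """
    temp = langevin.temperature if langevin.temperature is not None else params.temperature
    kT = params.kB * temp
    rng = np.random.default_rng(np.random.SeedSequence([langevin.seed, 0x_3E7A]))
    noise = rng.standard_normal(langevin.n_steps)
    xs, centers, heights, bad_step = _run_core(
        float(langevin.x0),
        int(langevin.n_steps),
        float(langevin.dt),
        float(langevin.friction),
        float(kT),
        _POT_IDS[potential.name],
        float(potential.params[0]) if potential.params else 0.0,
        float(potential.params[1]) if len(potential.params) > 1 else 0.0,
        float(walls.lower),
        float(walls.upper),
        float(walls.force_constant),
        float(params.W0),
        float(params.hill_width),
        float(params.kB * params.delta_T),
        int(params.deposit_stride),
        noise,
        int(langevin.sample_stride),
    )
    if bad_step >= 0:
        raise MetadError(
            f"integration diverged at step {bad_step}: reduce dt or increase friction"
        )
    hills = HillHistory(centers=centers, heights=heights, width=params.hill_width)
    return xs, hills


def pmf_from_bias(
    hills: HillHistory, params: WTParams, grid: np.ndarray
) -> np.ndarray:
    """PMF(x) = −(T+ΔT)/ΔT · V(x) + C on a grid, with min PMF = 0."""
    if hills.n_hills == 0:
        raise MetadError("no hills deposited; PMF undefined")
    pmf = -params.pmf_scale * hills.bias(np.asarray(grid, dtype=float))
    return pmf - pmf.min()


def pmf_time_averaged(
    hills: HillHistory, params: WTParams, grid: np.ndarray, last_fraction: float = 0.5
) -> np.ndarray:
    """PMF from the bias averaged over the final hills (reduced fill noise).

    The estimator averages the instantaneous well-tempered PMF over the
    deposition history restricted to the last ``last_fraction`` of hills,
    which suppresses the oscillation of the still-growing bias around its
    converged shape.
    """
    if hills.n_hills == 0:
        raise MetadError("no hills deposited; PMF undefined")
    n0 = int((1.0 - last_fraction) * hills.n_hills)
    grid = np.asarray(grid, dtype=float)
    diff2 = (grid[:, None] - hills.centers[None, :]) ** 2
    g = np.exp(-diff2 / (2.0 * hills.width**2)) * hills.heights[None, :]
    cum = np.cumsum(g, axis=1)          # bias on grid after each hill
    v_avg = cum[:, n0:].mean(axis=1)
    pmf = -params.pmf_scale * v_avg
    return pmf - pmf.min()
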