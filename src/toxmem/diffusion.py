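"""Diffusion coefficients from mean squared displacements (Einstein relation).

The MSD at lag τ is averaged over multiple time origins t0,

    MSD(τ) = ⟨ |r(t0 + τ) − r(t0)|² ⟩_{t0},

and the diffusion coefficient follows from the long-time Einstein relation
D = MSD(τ) / (2·d·τ) with d the dimensionality (3 in bulk, 2 for lateral
diffusion in the membrane plane). With unit origin stride the full
all-origins average is computed with the standard FFT autocorrelation
identity, which is algebraically identical to the brute-force double loop.

Lateral diffusion coefficients from periodic simulation boxes underestimate
the infinite-system value; :func:`psd_extrapolate` applies a periodic
Saffman–Delbrück finite-size correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .units import KB_J_K, NM2_PER_NS_TO_CM2_PER_S


class DiffusionError(ValueError):
    pass


@dataclass
class MSDCurve:
    lag_times_ns: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray      # origin count per lag
    n_dims: int


@dataclass
class DiffusionEstimate:
    D_cm2_s: float
    stderr_cm2_s: float
    fit_window_ns: tuple[float, float]
    n_dims: int


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """All-origins MSD of one coordinate via the FFT autocorrelation identity."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    sq = x**2
    # S1(m) = sum_{k=0}^{n-m-1} (x_k^2 + x_{k+m}^2), computed by recursion
    s1 = np.empty(n)
    css = 2.0 * sq.sum()
    s1[0] = css
    for m in range(1, n):
        css -= sq[m - 1] + sq[n - m]
        s1[m] = css
    counts = n - np.arange(n)
    return (s1 - 2.0 * acf) / counts


def msd(
    positions: np.ndarray,
    times_ns: np.ndarray,
    origin_stride: int = 1,
    max_lag_fraction: float = 0.5,
    box_lengths: np.ndarray | None = None,
) -> MSDCurve:
    """Multi-origin MSD of an unwrapped (N, d) position series.

    ``origin_stride`` thins the time origins (1 = every frame, the maximal
    averaging); lags are truncated at ``max_lag_fraction`` of the series
    length. If ``box_lengths`` is given, a jump larger than half a box length
    between consecutive frames trips a wrapped-coordinate error.
    """
    positions = np.asarray(positions, dtype=float)
    times_ns = np.asarray(times_ns, dtype=float)
    if positions.ndim != 2:
        raise DiffusionError("positions must be (n_frames, n_dims)")
    n, d = positions.shape
    if n < 2:
        raise DiffusionError("need at least 2 frames")
    if d not in (2, 3):
        raise DiffusionError("n_dims must be 2 or 3")
    if box_lengths is not None:
        jumps = np.abs(np.diff(positions, axis=0))
        if np.any(jumps > np.asarray(box_lengths) / 2.0):
            raise DiffusionError(
                "jump larger than half a box length detected: coordinates look "
                "wrapped; unwrap them first (toxmem.trajectory.unwrap)"
            )
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    lags = np.arange(max_lag + 1)

    if origin_stride == 1:
        curve = np.zeros(n)
        for k in range(d):
            curve += _msd_fft_1d(positions[:, k])
        msd_vals = curve[: max_lag + 1]
        counts = (n - lags).astype(int)
    else:
        msd_vals = np.zeros(max_lag + 1)
        counts = np.zeros(max_lag + 1, dtype=int)
        for m in lags:
            origins = np.arange(0, n - m, origin_stride)
            disp = positions[origins + m] - positions[origins]
            msd_vals[m] = np.mean(np.sum(disp**2, axis=1)) if len(origins) else np.nan
            counts[m] = len(origins)
    dt = float(np.mean(np.diff(times_ns)))
    return MSDCurve(
        lag_times_ns=lags * dt,
        msd_nm2=msd_vals,
        n_pairs=counts,
        n_dims=d,
    )


def einstein_fit(
    curve: MSDCurve, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionEstimate:
    """Fit D from the linear regime of an MSD curve.

    ``fit_window`` gives the (lo, hi) fractions of the maximum lag time to
    include; the default 10%–50% excludes the zero-lag registration region
    and the noisy long-lag tail. D = slope / (2·d), reported in cm²/s with
    the OLS standard error.
    """
    lo_f, hi_f = fit_window
    if not 0 <= lo_f < hi_f <= 1:
        raise DiffusionError("fit_window fractions must satisfy 0 <= lo < hi <= 1")
    tmax = curve.lag_times_ns[-1]
    lo, hi = lo_f * tmax, hi_f * tmax
    sel = (curve.lag_times_ns >= lo) & (curve.lag_times_ns <= hi)
    if sel.sum() < 2:
        raise DiffusionError("fewer than 2 lag points in fit window")
    res = stats.linregress(curve.lag_times_ns[sel], curve.msd_nm2[sel])
    scale = NM2_PER_NS_TO_CM2_PER_S / (2.0 * curve.n_dims)
    return DiffusionEstimate(
        D_cm2_s=float(res.slope) * scale,
        stderr_cm2_s=float(res.stderr) * scale,
        fit_window_ns=(float(lo), float(hi)),
        n_dims=curve.n_dims,
    )


@dataclass
class PSDInputs:
    """Physical inputs of the periodic Saffman–Delbrück finite-size correction.

    box_L_nm              lateral box edge of the (square) membrane patch
    membrane_viscosity    membrane *surface* viscosity η_m·h in Pa·s·m
    water_viscosity       bulk solvent viscosity in Pa·s
    inclusion_radius_nm   in-plane radius of the diffusing inclusion
    temperature_K         absolute temperature
    """

    box_L_nm: float = 16.0
    membrane_viscosity: float = 5.0e-10
    water_viscosity: float = 1.0e-3
    inclusion_radius_nm: float = 1.5
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        vals = (
            self.box_L_nm,
            self.membrane_viscosity,
            self.water_viscosity,
            self.inclusion_radius_nm,
            self.temperature_K,
        )
        if any(v <= 0 for v in vals):
            raise DiffusionError("all PSD inputs must be strictly positive")
        if self.inclusion_radius_nm >= self.box_L_nm:
            raise DiffusionError("inclusion radius must be smaller than the box")

    @property
    def sd_length_nm(self) -> float:
        """Saffman–Delbrück length L_SD = η_m·h / (2 η_w), in nm."""
        return self.membrane_viscosity / (2.0 * self.water_viscosity) * 1e9


def psd_correction(inputs: PSDInputs) -> float:
    """Finite-size correction Δ = D∞ − D_sim in cm²/s.

    Uses the interpolating form

        Δ(L) = kBT / (4π η_m) · ln(1 + L_SD / L),

    which reproduces the logarithmic small-box behaviour of the periodic
    Saffman–Delbrück model (Δ ~ ln(L_SD/L) for L ≪ L_SD) and vanishes as
    L → ∞. Δ is non-negative and strictly decreasing in L.
    """
    pref_m2_s = KB_J_K * inputs.temperature_K / (4.0 * np.pi * inputs.membrane_viscosity)
    delta_m2_s = pref_m2_s * np.log1p(inputs.sd_length_nm / inputs.box_L_nm)
    return float(delta_m2_s * 1e4)  # m²/s → cm²/s


def psd_extrapolate(D_sim_cm2_s: float, inputs: PSDInputs) -> tuple[float, float]:
    """Extrapolate a periodic-box lateral D to infinite box size.

    Returns (D_infinity, correction), both cm²/s; D∞ = D_sim + Δ ≥ D_sim.
    """
    if D_sim_cm2_s <= 0:
        raise DiffusionError("D_sim must be strictly positive")
    delta = psd_correction(inputs)
    return D_sim_cm2_s + delta, delta
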