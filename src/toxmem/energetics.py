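"""Block-average error estimation and pair-energy decomposition bookkeeping.

MD energy time series are strongly autocorrelated, so the naive standard
error of the mean underestimates the true uncertainty. Block averaging
computes the SEM of block means for doubling block sizes; as blocks grow
past the correlation time the SEM saturates, and the plateau — estimated
here by fitting a saturating exponential — is the honest SEM. The squared
ratio of plateau to naive SEM is the statistical inefficiency g (for an
AR(1) series with lag-1 autocorrelation φ, g = (1+φ)/(1−φ) in closed form).

The decomposition reduces per-frame pair-interaction energy tables into the
bound-minus-unbound ΔE report: pairs involving the toxin are summed into
ToxVdW/ToxEle, the remainder into RestVdW/RestEle, alongside the per-frame
totals (TotPot, TotVdW, TotEle, TotBond). Restraint energies are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class EnergeticsError(ValueError):
    pass


# ------------------------------------------------------------------ block error

@dataclass
class BlockErrorResult:
    block_sizes: np.ndarray
    sems: np.ndarray
    sem_infinity: float
    naive_sem: float
    statistical_inefficiency: float


def block_error(series: np.ndarray, min_blocks: int = 8) -> BlockErrorResult:
    """Block-averaged SEM with extrapolation to infinite block size.

    SEM is computed for doubling block sizes (1, 2, 4, …) while at least
    ``min_blocks`` blocks remain, then fitted with the saturating exponential
    s(b) = s∞·(1 − exp(−b/b0)) + s1·exp(−b/b0); s∞ is reported as the
    extrapolated SEM.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 16:
        raise EnergeticsError("need at least 16 samples for block averaging")
    sizes = []
    sems = []
    counts = []
    b = 1
    while n // b >= min_blocks:
        nb = n // b
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        sems.append(float(np.std(means, ddof=1) / np.sqrt(nb)))
        sizes.append(b)
        counts.append(nb)
        b *= 2
    sizes_a = np.array(sizes, dtype=float)
    sems_a = np.array(sems)
    counts_a = np.array(counts, dtype=float)
    naive = sems_a[0]

    if np.allclose(sems_a, 0.0):
        sem_inf = 0.0
    else:
        def model(bs, s_inf, b0):
            return s_inf * (1.0 - np.exp(-bs / b0)) + naive * np.exp(-bs / b0)

        # each SEM estimate carries sampling error ~ sem/sqrt(2(nb-1));
        # weighting by it keeps the well-sampled small-block points in charge
        sigma = np.clip(sems_a, 1e-300, None) / np.sqrt(2.0 * (counts_a - 1.0))
        bmax = sizes_a.max()
        try:
            popt, _ = curve_fit(
                model,
                sizes_a,
                sems_a,
                p0=(max(sems_a.max(), 1e-12), max(bmax / 16.0, 1.0)),
                sigma=sigma,
                absolute_sigma=True,
                bounds=([0.0, 0.25], [5.0 * sems_a.max(), 4.0 * bmax]),
                maxfev=20_000,
            )
            sem_inf = float(popt[0])
        except RuntimeError:
            sem_inf = float(sems_a[-3:].mean())  # fall back to the tail average

    g = (sem_inf / naive) ** 2 if naive > 0 else 1.0
    return BlockErrorResult(
        block_sizes=sizes_a.astype(int),
        sems=sems_a,
        sem_infinity=sem_inf,
        naive_sem=naive,
        statistical_inefficiency=g,
    )


# ------------------------------------------------------------------ decomposition

TOXIN_PAIRS = ("toxin-water", "toxin-membrane", "toxin-ions", "toxin-toxin")
REST_PAIRS = (
    "water-water", "water-membrane", "water-ions",
    "membrane-membrane", "membrane-ions", "ions-ions",
)
PAIR_VOCABULARY = TOXIN_PAIRS + REST_PAIRS


@dataclass
class PairEnergyTable:
    """Per-frame pair-interaction energies plus per-frame totals.

    ``pairs``  — columns time, pair, vdw, ele (kcal/mol), pair drawn from the
                 closed vocabulary of toxin-involving and rest pairs.
    ``totals`` — columns time, tot_pot, tot_vdw, tot_ele, tot_bond.
    """

    pairs: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.pairs["pair"].unique()) - set(PAIR_VOCABULARY)
        if bad:
            raise EnergeticsError(f"unknown pair labels: {sorted(bad)}")
        if not self.pairs["time"].is_monotonic_increasing:
            # long format repeats times across pairs; check per-pair ordering
            for label, sub in self.pairs.groupby("pair"):
                if not sub["time"].is_monotonic_increasing:
                    raise EnergeticsError(f"frames for pair {label!r} are not time-ordered")

    def category_series(self) -> dict[str, np.ndarray]:
        """Per-frame sums: ToxVdW, ToxEle, RestVdW, RestEle (+ totals)."""
        out: dict[str, np.ndarray] = {}
        p = self.pairs
        for name, labels, col in (
            ("ToxVdW", TOXIN_PAIRS, "vdw"),
            ("ToxEle", TOXIN_PAIRS, "ele"),
            ("RestVdW", REST_PAIRS, "vdw"),
            ("RestEle", REST_PAIRS, "ele"),
        ):
            sub = p[p["pair"].isin(labels)]
            out[name] = sub.groupby("time")[col].sum().to_numpy()
        out["TotPot"] = self.totals["tot_pot"].to_numpy()
        out["TotVdW"] = self.totals["tot_vdw"].to_numpy()
        out["TotEle"] = self.totals["tot_ele"].to_numpy()
        out["TotBond"] = self.totals["tot_bond"].to_numpy()
        return out


def read_energy_log(pairs_csv, totals_csv) -> PairEnergyTable:
    """Read the generic per-frame energy CSVs (see PairEnergyTable columns)."""
    return PairEnergyTable(pd.read_csv(pairs_csv), pd.read_csv(totals_csv))


def energy_decomposition(
    bound: PairEnergyTable, unbound: PairEnergyTable
) -> pd.DataFrame:
    """Bound-minus-unbound ΔE per category, each with a block-average error.

    Returns a table with columns component, delta_kcal_mol, error_kcal_mol:
    Δ = mean(bound) − mean(unbound); the error combines the two extrapolated
    SEMs in quadrature. Restraint terms are not part of the bookkeeping.
    """
    sb = bound.category_series()
    su = unbound.category_series()
    if set(sb) != set(su):
        raise EnergeticsError(
            f"category mismatch: {sorted(set(sb) ^ set(su))}"
        )
    order = ["TotPot", "TotVdW", "TotEle", "TotBond",
             "ToxVdW", "ToxEle", "RestVdW", "RestEle"]
    rows = []
    for name in order:
        b_series, u_series = sb[name], su[name]
        delta = float(np.mean(b_series) - np.mean(u_series))
        err = float(
            np.hypot(
                block_error(b_series).sem_infinity,
                block_error(u_series).sem_infinity,
            )
        )
        rows.append({"component": name, "delta_kcal_mol": delta, "error_kcal_mol": err})
    return pd.DataFrame(rows)
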