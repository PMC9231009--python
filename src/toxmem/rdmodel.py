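"""Reduction-of-dimensionality binding fractions (Axelrod–Wang model).

A membrane-permeant ligand can reach a receptor embedded in the membrane
either directly from the bulk (3D) or by first adsorbing to the membrane and
diffusing laterally to the site (2D, "reduction of dimensionality"). For a
reaction-limited, reversibly adsorbing ligand at equilibrium the fraction of
the total binding rate contributed by the surface pathway is

    F2 = [ (3π/16) · (σ2/σ3) · (χ3/χ2) · (D3/D2) · (Ra · SA:V / Kp) + 1 ]⁻¹,

where σ is the Brownian persistence distance and χ the binding probability
per collision in each phase (both default to equal in 2D and 3D), D2 and D3
the membrane-bound and bulk diffusion coefficients, Ra the capture radius,
SA:V the surface-to-volume ratio of the compartment, and Kp the
membrane–water partition coefficient. Kp relates to the adsorption constant
K_ads (surface/bulk concentration quotient, units cm) by Kp = (SA:V)·K_ads.

F2 increases monotonically with Kp and with D2; slower lateral diffusion
shifts the F2(Kp) curve to larger Kp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class RDModelError(ValueError):
    pass


@dataclass
class RDParams:
    """Inputs of the two-pathway binding-fraction model (see module docs).

    Defaults: unit σ and χ ratios, the measured bulk and membrane diffusion
    coefficients of the toxin (1.0e-6 and 4.1e-8 cm²/s), capture radius
    0.5 nm, SA:V = 1e6 cm⁻¹ (microscale spherical compartment), Kp = 1.
    """

    sigma_ratio: float = 1.0     # σ2/σ3
    chi_ratio: float = 1.0       # χ3/χ2
    D2: float = 4.1e-8           # cm²/s
    D3: float = 1.0e-6           # cm²/s
    Ra_nm: float = 0.5
    SAV: float = 1.0e6           # cm⁻¹
    Kp: float = 1.0

    def __post_init__(self) -> None:
        vals = (
            self.sigma_ratio, self.chi_ratio, self.D2, self.D3,
            self.Ra_nm, self.SAV, self.Kp,
        )
        if any(v <= 0 for v in vals):
            raise RDModelError("all RD parameters must be strictly positive")

    @property
    def Ra_cm(self) -> float:
        return self.Ra_nm * 1e-7


def f2(params: RDParams) -> float:
    """Surface-pathway fraction of the total binding rate, in (0, 1)."""
    bulk_term = (
        (3.0 * np.pi / 16.0)
        * params.sigma_ratio
        * params.chi_ratio
        * (params.D3 / params.D2)
        * (params.Ra_cm * params.SAV / params.Kp)
    )
    return 1.0 / (bulk_term + 1.0)


def f3(params: RDParams) -> float:
    """Complementary bulk-pathway fraction, 1 − F2."""
    return 1.0 - f2(params)


def kp_from_kads(kads_cm: float, sav_per_cm: float) -> float:
    """Dimensionless partition coefficient Kp = (SA:V) · K_ads."""
    if kads_cm <= 0 or sav_per_cm <= 0:
        raise RDModelError("K_ads and SA:V must be strictly positive")
    return sav_per_cm * kads_cm


def f2_sweep(
    kp_grid: np.ndarray,
    d2_list: np.ndarray,
    base: RDParams | None = None,
) -> pd.DataFrame:
    """F2 over the Cartesian grid of Kp × D2, other parameters fixed.

    Returns a long table with columns Kp, D2, F2, F3. Along each row/column
    F2 is monotone non-decreasing in Kp and in D2.
    """
    base = base if base is not None else RDParams()
    kp_grid = np.asarray(kp_grid, dtype=float)
    d2_list = np.asarray(d2_list, dtype=float)
    if kp_grid.size == 0 or d2_list.size == 0:
        raise RDModelError("kp_grid and d2_list must be nonempty")
    rows = []
    for d2 in d2_list:
        for kp in kp_grid:
            p = RDParams(
                sigma_ratio=base.sigma_ratio,
                chi_ratio=base.chi_ratio,
                D2=float(d2),
                D3=base.D3,
                Ra_nm=base.Ra_nm,
                SAV=base.SAV,
                Kp=float(kp),
            )
            val = f2(p)
            rows.append({"Kp": kp, "D2": d2, "F2": val, "F3": 1.0 - val})
    return pd.DataFrame(rows)
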