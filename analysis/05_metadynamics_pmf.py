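#!/usr/bin/env python
"""Well-tempered metadynamics on an analytic double well.

Runs the 1D engine (hill height 0.5 kcal/mol, width 0.1 CV units, bias
temperature 1500 K, deposition every 200 steps, harmonic walls) on a
symmetric double well with a 3 kcal/mol barrier for 1e6 Langevin steps and
compares the recovered PMF with the closed form.

Writes results/05_pmf.csv and results/05_hills.txt.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from toxmem import metadynamics as mtd

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 42

params = mtd.WTParams(W0=0.5, hill_width=0.1, delta_T=1500.0, deposit_stride=200)
potential = mtd.double_well(barrier=3.0)
walls = mtd.WallSpec(-1.6, 1.6, 10.0)
lang = mtd.LangevinSpec(dt=5e-3, n_steps=1_000_000, x0=-1.0, seed=SEED)

xs, hills = mtd.run_sampler(potential, params, walls, lang)
grid = np.linspace(-1.6, 1.6, 161)
pmf = mtd.pmf_time_averaged(hills, params, grid)
ref = potential.reference_pmf(grid)

pd.DataFrame({"cv": grid, "pmf_kcal_mol": pmf, "reference_kcal_mol": ref}).to_csv(
    OUT / "05_pmf.csv", index=False
)
np.savetxt(OUT / "05_hills.txt", hills.to_table(),
           header="index center height width", comments="# ")

barrier = pmf[np.abs(grid) < 0.05].max() - pmf[np.abs(grid) <= 1.3].min()
print(f"{hills.n_hills} hills deposited; bias-to-PMF scale {params.pmf_scale:.5f}")
print(f"recovered barrier {barrier:.3f} kcal/mol (analytic 3.000)")
print(f"max |PMF - reference| inside walls: "
      f"{np.abs(pmf - ref)[np.abs(grid) <= 1.3].max():.3f} kcal/mol")
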