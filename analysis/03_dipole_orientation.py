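#!/usr/bin/env python
"""Dipole magnitude and orientation of the bound peptide vs membrane distance.

Runs the dipole analysis on the same synthetic binding trajectory as the
insertion scoring: per-frame molecular dipole about the mass-weighted COM,
its angle to the membrane normal (+z), distance binning, and the bound-state
angle distribution.

Writes results/03_dipole_records.csv, 03_dipole_by_distance.csv and
03_angle_histogram.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from toxmem import dipole as dip
from toxmem import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 42

fixture = syn.load_snx482_fixture()
bilayer = syn.make_bilayer(
    syn.BilayerSpec(popg_fraction=0.25, head_roughness_sigma=0.05,
                    n_frames=400, frame_dt=2.0, seed=SEED)
)
depths = np.full(fixture.n_residues, 0.5)
for r in fixture.hydrophobic_patch:
    depths[r - 1] = -0.3
traj = syn.make_binding_trajectory(
    bilayer,
    syn.BindingScenario(target_depths=depths, onset_frame=80,
                        depth_noise_sigma=0.15, seed=SEED),
    fixture,
)

records = dip.dipole_profile(traj)
records.to_csv(OUT / "03_dipole_records.csv", index=False)
binned = dip.bin_by_distance(records, bin_nm=0.25)
binned.to_csv(OUT / "03_dipole_by_distance.csv", index=False)

bound = records[records["membrane_distance_nm"] < 0.5]
centers, prob = dip.angle_histogram(bound, bin_deg=5.0)
pd.DataFrame({"angle_deg": centers, "probability": prob}).to_csv(
    OUT / "03_angle_histogram.csv", index=False
)

print(f"{len(records)} frames, {len(bound)} bound (distance < 0.5 nm)")
print(f"bound-state |Dip| = {bound['magnitude_debye'].mean():.1f} D")
print(f"bound-state Dip_z angle = {bound['angle_z_deg'].mean():.1f} deg")
print(f"modal angle bin: {centers[int(np.argmax(prob))]:.0f} deg")
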