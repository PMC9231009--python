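#!/usr/bin/env python
"""Build the peptide fixture and synthetic bilayer and report their makeup.

Writes results/01_system.csv with the lipid composition of each membrane
variant and prints the peptide's basic chemistry (length, net charge,
cysteine count, hydrophobic patch).
"""

from pathlib import Path

import pandas as pd

from toxmem import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

fixture = syn.load_snx482_fixture()
print(
    f"peptide: {fixture.n_residues} residues, net charge {fixture.net_charge:+d}, "
    f"{fixture.sequence.count('C')} cysteines"
)
print(f"hydrophobic patch (1-based): {fixture.hydrophobic_patch}")

rows = []
for label, frac in [("1:0", 0.0), ("3:1", 0.25), ("1:1", 0.5), ("1:3", 0.75), ("0:1", 1.0)]:
    bilayer = syn.make_bilayer(
        syn.BilayerSpec(n_lipids=308, popg_fraction=frac, n_frames=1, seed=1)
    )
    counts = bilayer.species_counts
    rows.append(
        {
            "popc_popg_ratio": label,
            "popg_fraction": frac,
            "POPC": counts.get("POPC", 0),
            "POPG": counts.get("POPG", 0),
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "01_system.csv", index=False)
print(table.to_string(index=False))
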