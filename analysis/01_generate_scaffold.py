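"""Generate the default synthetic scaffold block and audit its properties.

Produces the 10 x 10 x 20 mm, 69%-porous surrogate volume used by all
downstream studies, verifies porosity control and axial percolation over
an ensemble of seeds, and writes the audit table to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from perfuseed.scaffold import generate_scaffold, percolates, save_volume

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for seed in range(10):
        vol = generate_scaffold(seed=seed)
        rows.append(dict(seed=seed, porosity=vol.porosity,
                         percolates=percolates(vol.fluid_mask()),
                         shape=str(vol.shape)))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "scaffold_audit.csv", index=False)

    vol = generate_scaffold(seed=42)
    save_volume(vol, OUT / "scaffold_seed42.npz")

    print(df.to_string(index=False))
    print(f"\nmean porosity over {len(df)} seeds: {df.porosity.mean():.4f} "
          f"(target 0.69), all percolating: {df.percolates.all()}")
    print(f"reference volume written to {OUT / 'scaffold_seed42.npz'}")


if __name__ == "__main__":
    main()
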