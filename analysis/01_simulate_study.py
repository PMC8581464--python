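#!/usr/bin/env python
"""Generate the synthetic datasets every later analysis step consumes.

Writes, under scratch/ (large raw tables, regenerated on demand):

  scratch/validation_study/   7-batch validation dataset, default persona
  scratch/carryover_study/    2-batch dataset, carryover persona, noise off
  scratch/commercial_panel/   200 synthetic e-liquids in bracketed batches

and a small inventory table under results/.
"""

from pathlib import Path

import pandas as pd

from flavorquant import (
    generate_commercial_panel,
    generate_validation_study,
    load_panel,
    sticky,
    well_behaved,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    panel = load_panel()
    inventory = []

    study = generate_validation_study(well_behaved(panel), panel, seed=SEED, n_batches=7)
    study.write(ROOT / "scratch/validation_study")
    inventory.append(("validation_study", "well_behaved", len(study.manifest), len(study.peaks)))

    carry = generate_validation_study(
        sticky(panel), panel, seed=SEED + 1, n_batches=2,
        include_dilution_checks=False, include_stability=False,
    )
    carry.write(ROOT / "scratch/carryover_study")
    inventory.append(("carryover_study", "sticky", len(carry.manifest), len(carry.peaks)))

    liquids = generate_commercial_panel(well_behaved(panel), panel, n_liquids=200, seed=SEED)
    liquids.write(ROOT / "scratch/commercial_panel")
    inventory.append(("commercial_panel", "well_behaved", len(liquids.manifest), len(liquids.peaks)))

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table = pd.DataFrame(
        inventory, columns=["dataset", "persona", "n_injections", "n_peak_rows"]
    )
    table.to_csv(out / "simulated_inventory.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nraw datasets under {ROOT / 'scratch'}; inventory in results/simulated_inventory.csv")


if __name__ == "__main__":
    main()
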