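#!/usr/bin/env python
"""Steady and pulsatile flow solves over the simulated cohort.

Loads the cohort written by 01_simulate_cohort.py, applies the protocol
(1 mm extensions on the posterior cerebral efferents), runs both solver
modes and writes tidy 73-parameter metric tables.

Output: results/metrics_steady.csv, results/metrics_transient.csv
"""

from pathlib import Path

import pandas as pd

from cowhemo import VascularNetwork
from cowhemo.cohort import VirtualAnimal
from cowhemo.pipeline import cohort_metrics

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_cohort(cohort_dir: Path) -> list[VirtualAnimal]:
    man = pd.read_csv(cohort_dir / "manifest.csv")
    animals = []
    for row in man.itertuples():
        net = VascularNetwork.from_json(cohort_dir / row.network_file)
        vel = {c[2:]: getattr(row, c) for c in man.columns if c.startswith("v_")}
        animals.append(VirtualAnimal(row.animal_id, row.group, net, vel))
    return animals


def main() -> None:
    animals = load_cohort(ROOT / "cohort")
    for mode in ("steady", "transient"):
        tidy = cohort_metrics(animals, mode=mode)
        out = ROOT / f"metrics_{mode}.csv"
        tidy.to_csv(out, index=False)
        print(f"{mode}: {tidy['animal_id'].nunique()} animals, "
              f"{tidy['feature'].nunique()} features -> {out}")

        # headline hemodynamic quantities per arm
        sub = tidy[tidy.feature.isin(["R_5_6", "vmax_S1"])]
        print(sub.pivot_table(index="group", columns="feature", values="value")
              .round(2).to_string(), "\n")


if __name__ == "__main__":
    main()
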