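"""Simulate the default pen-structured gilt population and describe it.

Generates the reduced-scale default world (5 farms x 200 pens of ~10.7
F1 gilts, binary skin-damage scores at ~4.3% incidence, genotyped
purebred ancestors) and writes the four input files every later stage
consumes, plus the truth tables recovery experiments compare against.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from igeblup.interface import (write_dosages, write_pedigree,
                               write_phenotypes, write_plink)
from igeblup.syndata import SimConfig, gilt_cohort, simulate_world

OUT = Path("results/simulated_population")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed)
    world = simulate_world(config, with_genotypes=True)

    write_pedigree(world.pedigree, OUT / "pedigree.csv")
    write_phenotypes(world.phenotypes, OUT / "phenotypes.csv")
    write_plink(world.genotypes, OUT / "genotypes")
    write_dosages(world.genotypes, OUT / "dosages.csv")
    world.pens.to_csv(OUT / "pens.csv", index=False)
    world.effects.frame().to_csv(OUT / "true_breeding_values.csv",
                                 index=False)

    phen = world.phenotypes
    pen_sizes = phen.groupby("pen")["animal"].size()
    by_farm = phen.groupby("farm").apply(
        lambda g: pd.Series({
            "n_gilts": len(g),
            "mean_pen_size": g.groupby("pen")["animal"].size().mean(),
            "incidence_pct": 100 * (g["score"] == 1).mean(),
        }), include_groups=False)
    summary = pd.DataFrame({
        "quantity": ["gilts", "pedigree records", "genotyped ancestors",
                     "pens", "mean pen size", "sd pen size",
                     "incidence %"],
        "value": [len(phen), len(world.pedigree),
                  int(world.pedigree.table["genotyped"].sum()),
                  len(pen_sizes), round(pen_sizes.mean(), 2),
                  round(pen_sizes.std(), 2),
                  round(100 * (phen["score"] == 1).mean(), 2)],
    })
    summary.to_csv(OUT / "population_summary.csv", index=False)
    by_farm.to_csv(OUT / "farm_summary.csv")

    print(summary.to_string(index=False))
    print("\nper farm:")
    print(by_farm.round(2).to_string())
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
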