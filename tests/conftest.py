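import numpy as np
import pandas as pd
import pytest

from igeblup.pedigree import Pedigree, sort_and_validate
from igeblup.syndata import SimConfig, simulate_world


def make_pedigree(rows) -> Pedigree:
    """Pedigree from (animal, sire, dam) or (animal, sire, dam, genotyped)."""
    recs = []
    for r in rows:
        animal, sire, dam = r[:3]
        geno = r[3] if len(r) > 3 else False
        recs.append((animal, sire, dam, "L1", "2019-01-01", geno))
    return sort_and_validate(pd.DataFrame(
        recs, columns=["animal", "sire", "dam", "line", "birth_date",
                       "genotyped"]))


def random_pedigree(rng: np.random.Generator, n: int,
                    p_parent: float = 0.7) -> Pedigree:
    """Random acyclic pedigree; parents drawn among earlier animals."""
    rows = []
    for i in range(1, n + 1):
        sire = dam = 0
        if i > 2 and rng.random() < p_parent:
            sire, dam = rng.choice(np.arange(1, i), size=2, replace=False)
        rows.append((i, int(sire), int(dam)))
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """~300-gilt binary-scored world with genotyped purebred ancestors."""
    return SimConfig(
        n_farms=3, pens_per_farm=12, pen_size_mean=8.0, pen_size_sd=0.8,
        n_sires=12, n_dams=40, gilts_per_litter=8.0,
        n_founder_generations=2, founders_per_line=8,
        n_snps=120, n_chromosomes=4, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return simulate_world(tiny_config, with_genotypes=True)


@pytest.fixture(scope="session")
def liability_config() -> SimConfig:
    """Small continuous-record world for estimation tests."""
    return SimConfig(
        n_farms=3, pens_per_farm=8, pen_size_mean=6.0, pen_size_sd=0.6,
        n_sires=10, n_dams=30, gilts_per_litter=5.0,
        n_founder_generations=1, founders_per_line=8,
        record_liability=True, seed=7,
    )


@pytest.fixture(scope="session")
def liability_world(liability_config):
    world = simulate_world(liability_config)
    world.phenotypes["y"] = world.phenotypes["score"]
    return world
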