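"""LR-method forward validation: pedigree BLUP vs single-step GBLUP.

Breeding values of young sires (>= 10 phenotyped progeny only after
the cutoff) are estimated with the partial data (records up to the end
of October 2019) and the complete data; accuracy, bias and dispersion
follow from the covariance of the two sets.  Both relationship sources
are compared for direct, social and total breeding values.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from igeblup.genpar import sigma_tbv, total_breeding_values
from igeblup.mme import ModelSpec, estimate_breeding_values
from igeblup.pedigree import (a22, a_inverse, inbreeding,
                              pen_mate_relationship_from_pedigree)
from igeblup.genomics import (QCThresholds, build_genomic_matrices,
                              h_inverse, impute_missing, qc_genotypes)
from igeblup.syndata import MODEL2_TRUE, SimConfig, simulate_world
from igeblup.validation import (bootstrap_se, lr_statistics,
                                select_validation_sires, split_partial)

OUT = Path("results/validation")
CUTOFF = "2019-10-31"


def validation_world(seed: int):
    """~1,000 liability-recorded gilts with genotyped purebred ancestors."""
    config = SimConfig(
        pens_per_farm=19, n_sires=48, n_dams=160, gilts_per_litter=7.0,
        n_founder_generations=2, founders_per_line=10,
        n_snps=400, n_chromosomes=5, record_liability=True, seed=seed)
    return simulate_world(config, with_genotypes=True)


def relationship_inverses(world):
    ped = world.pedigree
    Ainv = a_inverse(ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc, _ = qc_genotypes(world.genotypes, QCThresholds())
        geno = impute_missing(qc, ped.table.set_index("animal")["line"])
    A22, A22_inv = a22(ped, geno.ids)
    gm = build_genomic_matrices(geno, A22, A22_inv)
    Hinv = h_inverse(Ainv, gm.hinv_correction, ped.positions_of(geno.ids))
    return Ainv, Hinv, geno, gm


def main(seed: int = 1, n_boot: int = 500) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    world = validation_world(seed)
    data = world.phenotypes.copy()
    data["y"] = data["score"]
    ped = world.pedigree
    Ainv, Hinv, geno, _ = relationship_inverses(world)
    vc = MODEL2_TRUE
    partial = split_partial(data, CUTOFF)
    sires = select_validation_sires(ped.table, data, CUTOFF, min_progeny=10)
    print(f"{len(data)} records, {len(partial)} before cutoff, "
          f"{len(sires)} validation sires")
    summary = pen_mate_relationship_from_pedigree(ped, data[["animal", "pen"]])
    F = inbreeding(ped)
    f_bar = float(F[ped.positions_of(sires)].mean())

    rows = []
    for source, relinv in (("blup", Ainv), ("ssgblup", Hinv)):
        spec = ModelSpec(model="social",
                         relationship="pedigree" if source == "blup"
                         else "ssgblup")
        ebv_c = estimate_breeding_values(data, spec, vc, relinv, ped)
        ebv_p = estimate_breeding_values(partial, spec, vc, relinv, ped)
        ebv_c = total_breeding_values(ebv_c, summary.n_bar)
        ebv_p = total_breeding_values(ebv_p, summary.n_bar)
        kinds = [("dbv", vc.sigma2_ud), ("sbv", vc.sigma2_us),
                 ("tbv", sigma_tbv(vc, summary.n_bar))]
        for kind, s2 in kinds:
            p = ebv_p.set_index("animal")[kind]
            c = ebv_c.set_index("animal")[kind]
            stat = lr_statistics(p, c, sires, f_bar, s2, kind=kind)
            se = bootstrap_se(
                lambda ids: lr_statistics(p, c, ids, f_bar, s2).accuracy,
                sires, n_boot=n_boot, seed=seed)
            rows.append({
                "source": source, "ebv": kind, "accuracy": stat.accuracy,
                "accuracy_se": se, "bias": stat.bias,
                "dispersion": stat.dispersion, "n_sires": stat.n,
                "f_bar": f_bar,
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "sire_validation.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
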