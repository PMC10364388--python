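"""Single-step GWAS of the direct and social components by backsolving.

Uses the validation world's complete-data ssGBLUP solution: genotyped
ancestors' GEBVs are mapped to SNP effects through the genomic
relationship matrix, standard errors propagate the prediction-error
variances from the mixed-model equations, and 20-SNP sliding windows
summarise the share of genetic variance along the genome.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

from igeblup.gwas import gebv_covariance, manhattan_plot, run_gwas
from igeblup.genomics import center_dosages
from igeblup.mme import ModelSpec, assemble_mme, build_design, solve_mme
from igeblup.syndata import MODEL2_TRUE

OUT = Path("results/gwas")


def main(seed: int = 1) -> None:
    sys.path.insert(0, str(Path(__file__).parent))
    val = importlib.import_module("04_validation")
    OUT.mkdir(parents=True, exist_ok=True)
    world = val.validation_world(seed)
    data = world.phenotypes.copy()
    data["y"] = data["score"]
    ped = world.pedigree
    _, Hinv, geno, gm = val.relationship_inverses(world)
    vc = MODEL2_TRUE

    spec = ModelSpec(model="social", relationship="ssgblup")
    design = build_design(data, spec, ped)
    solution = solve_mme(assemble_mme(design, vc, Hinv),
                         compute_inverse=True)
    M, _, scale = center_dosages(geno)
    gpos = ped.positions_of(geno.ids)

    results = {}
    for comp, name, s2 in (("direct", "direct", vc.sigma2_ud),
                           ("social", "social", vc.sigma2_us)):
        sl = solution.slices[name]
        u_hat = solution.sol[sl][gpos]
        pev = solution.c_inv[sl, sl.start:sl.stop][gpos][:, gpos]
        var_u = gebv_covariance(pev, gm.G_blend, s2)
        res = run_gwas(u_hat, gm.G_blend, M, geno.snp_map, s2, var_u,
                       vanraden_scale=scale, component=comp, model="social")
        res.snps.to_csv(OUT / f"snp_effects_{comp}.csv", index=False)
        res.windows.to_csv(OUT / f"windows_{comp}.csv", index=False)
        manhattan_plot(res, OUT / f"manhattan_{comp}.png")
        results[comp] = res
        top = res.windows.sort_values("pct_var").iloc[-1]
        n_sig = int((res.snps["pvalue"] < res.threshold).sum())
        print(f"{comp}: {len(res.snps)} SNPs, Bonferroni threshold "
              f"{res.threshold:.2e}, significant SNPs: {n_sig}")
        print(f"  top window chr{top['chrom']} "
              f"{top['start_pos']}-{top['end_pos']}: "
              f"{top['pct_var']:.2f}% of genetic variance")
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
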