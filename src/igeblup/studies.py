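"""Replicate simulation studies: parameter recovery at study conditions.

These drivers tie the generator to the estimation stack at the scale
used throughout the package's own experiments: ~2,000 gilts per
replicate (5 farms x 38 pens x 10.7 animals) from 60 sires and 250
dam litters, phenotypes recorded on the liability scale so the linear
mixed models are exactly correctly specified and the generating
components live on the observed scale.

Starting values for the replicate fits encode what is known about the
trait class before seeing any estimate - a low-heritability score with
a sizeable pen-group component - and the social model is warm-started
from the classical fit; starting values do not move the REML optimum
(the fits are likelihood-guarded), they only cut the iteration count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .components import CLASSICAL, SOCIAL, VarianceComponents
from .genpar import heritability, t_squared
from .mme import ModelSpec
from .pedigree import a_inverse, pen_mate_relationship_from_pedigree
from .reml import REMLOptions, em_reml, pedigree_logdet
from .syndata import MODEL1_TRUE, MODEL2_TRUE, SimConfig, simulate_world

#: study-scale replicate: ~2,033 gilts in pens of 10.7 on 5 farms
RECOVERY_KWARGS = dict(
    pens_per_farm=38,
    n_sires=60,
    n_dams=250,
    gilts_per_litter=8.0,
    n_founder_generations=1,
    founders_per_line=40,  # a diverse purebred base, as in the emulated program
    record_liability=True,
)

#: numerical settings of the replicate fits (documented in the methods note)
FIT_OPTIONS = REMLOptions(tol=1e-7, maxiter=30, n_em_warmup=1)


def recovery_config(model: str, seed: int) -> SimConfig:
    """Replicate configuration generating from the fitted-model truth."""
    true = MODEL2_TRUE if model == SOCIAL else MODEL1_TRUE
    return SimConfig(true_varcomp=true, seed=seed, **RECOVERY_KWARGS)


def _informed_start(vy: float, model: str) -> VarianceComponents:
    """Low-heritability start: small genetic share, pen group largest."""
    if model == SOCIAL:
        return VarianceComponents(
            0.05 * vy, 0.005 * vy, 0.0, 0.15 * vy, 0.05 * vy, 0.05 * vy,
            0.70 * vy, model=SOCIAL)
    return VarianceComponents(
        0.05 * vy, None, None, 0.15 * vy, 0.05 * vy, 0.05 * vy, 0.70 * vy,
        model=CLASSICAL)


def run_recovery_replicate(model: str, seed: int) -> dict:
    """Simulate one replicate and fit the matching model by REML.

    For the social model a classical prefit supplies warm starts.
    Returns the fitted components plus the derived parameter the
    replicate contributes (h2 for the classical model; T2 with its
    pen summaries for the social model).
    """
    config = recovery_config(model, seed)
    world = simulate_world(config)
    data = world.phenotypes.copy()
    data["y"] = data["score"]  # liability recorded: already on the 100-scale
    ped = world.pedigree
    relinv = a_inverse(ped)
    rel_logdet = pedigree_logdet(ped)
    vy = float(np.var(data["y"], ddof=1))

    vc1 = em_reml(data, ModelSpec(model=CLASSICAL), relinv, ped,
                  init=_informed_start(vy, CLASSICAL),
                  rel_logdet=rel_logdet, options=FIT_OPTIONS)
    out = {"seed": seed, "model": model, "n_records": len(data)}
    if model == CLASSICAL:
        h2, sigma2_p = heritability(vc1)
        out.update(vc=vc1, h2=h2, sigma2_p=sigma2_p,
                   iterations=vc1.meta["iterations"])
        return out

    warm = VarianceComponents(
        vc1.sigma2_ud, 0.01 * vc1.sigma2_ud, 0.0, vc1.sigma2_gr,
        vc1.sigma2_cl, vc1.sigma2_cg, vc1.sigma2_e, model=SOCIAL)
    vc2 = em_reml(data, ModelSpec(model=SOCIAL), relinv, ped, init=warm,
                  rel_logdet=rel_logdet, options=FIT_OPTIONS)
    pens = data[["animal", "pen"]]
    summary = pen_mate_relationship_from_pedigree(ped, pens)
    out.update(vc=vc2, t2=t_squared(vc2, summary.n_bar, summary.r),
               n_bar=summary.n_bar, r=summary.r,
               iterations=vc2.meta["iterations"])
    return out


def recovery_study(model: str, n_replicates: int = 10,
                   base_seed: int = 1) -> pd.DataFrame:
    """Replicate table of fitted components and derived parameters.

    Per-replicate seeds are ``base_seed * 1000 + replicate``, keeping
    every stream reproducible from one integer.
    """
    rows = []
    for rep in range(n_replicates):
        res = run_recovery_replicate(model, seed=base_seed * 1000 + rep)
        vc: VarianceComponents = res.pop("vc")
        row = {**res,
               "sigma2_ud": vc.sigma2_ud, "sigma2_gr": vc.sigma2_gr,
               "sigma2_cl": vc.sigma2_cl, "sigma2_cg": vc.sigma2_cg,
               "sigma2_e": vc.sigma2_e,
               "minus2logl": vc.meta["minus2logl"], "aic": vc.meta["aic"],
               "converged": vc.meta["converged"]}
        if vc.is_social:
            row.update(sigma2_us=vc.sigma2_us, sigma_uds=vc.sigma_uds)
        rows.append(row)
    return pd.DataFrame(rows)


def gwas_null_replicate(seed: int, n_animals: int = 100,
                        n_snps: int = 300) -> dict:
    """One no-QTL world: GBLUP on a polygenic trait, then backsolving.

    Phenotypes are polygenic through the blended genomic relationship
    with no causal variant, so backsolved SNP-effect p-values should be
    uniform and Bonferroni exceedances rare.  Returns the p-values and
    the count passing the corrected threshold.
    """
    from .genomics import blend
    from .gwas import (backsolve_snp_effects, gebv_covariance,
                       significance_threshold, snp_pvalues,
                       snp_standard_errors)

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.15, 0.85, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n_animals, n_snps)).astype(float)
    p = dosages.mean(axis=0) / 2.0
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    M = dosages - 2.0 * p
    G = (M @ M.T) / scale
    Gb = blend(G, np.eye(n_animals), weight=0.05)
    sigma2_u, sigma2_e = 1.0, 2.0
    L = np.linalg.cholesky(Gb + 1e-10 * np.eye(n_animals))
    u = np.sqrt(sigma2_u) * (L @ rng.standard_normal(n_animals))
    y = u + rng.normal(0.0, np.sqrt(sigma2_e), size=n_animals)

    # mean + animal GBLUP mixed-model equations
    n = n_animals
    C = np.zeros((n + 1, n + 1))
    C[0, 0] = n / sigma2_e
    C[0, 1:] = C[1:, 0] = 1.0 / sigma2_e
    C[1:, 1:] = np.eye(n) / sigma2_e + np.linalg.inv(Gb) / sigma2_u
    rhs = np.concatenate([[y.sum()], y]) / sigma2_e
    c_inv = np.linalg.inv(C)
    sol = c_inv @ rhs
    u_hat = sol[1:]
    pev = c_inv[1:, 1:]
    var_u = gebv_covariance(pev, Gb, sigma2_u)
    a_hat = backsolve_snp_effects(u_hat, Gb, M, sigma2_u,
                                  vanraden_scale=scale)
    sd = snp_standard_errors(var_u, Gb, M, sigma2_u, vanraden_scale=scale)
    pvals = snp_pvalues(a_hat, sd)
    threshold = significance_threshold(n_snps, alpha=0.05)
    return {"pvalues": pvals, "n_significant": int(np.sum(pvals < threshold))}


def gwas_null_study(n_replicates: int = 100, base_seed: int = 1) -> dict:
    """Family-wise calibration of the backsolving GWAS under the null."""
    pvals = []
    counts = []
    for rep in range(n_replicates):
        out = gwas_null_replicate(base_seed * 1000 + rep)
        pvals.append(out["pvalues"])
        counts.append(out["n_significant"])
    return {"pvalues": np.concatenate(pvals),
            "mean_exceedance": float(np.mean(counts)),
            "n_replicates": n_replicates}


def study_summary(table: pd.DataFrame, column: str) -> dict:
    """Mean, Monte-Carlo SE and replicate count of a study column."""
    vals = table[column].to_numpy(dtype=float)
    return {
        "mean": float(np.mean(vals)),
        "mc_se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
        "n": int(len(vals)),
    }
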