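"""File formats, configuration and the end-to-end pipeline.

CSV dialects are fixed: comma-delimited, header row, "." decimal,
ISO-8601 dates, one-based animal ids with ``0`` for unknown parents.
Genotypes travel as PLINK .ped/.map text or a plain dosage table
(animals x SNPs, header row of SNP ids).  The binary score is stored as
1 (damaged) / 2 (sold undamaged) on disk and multiplied by 100 for
analysis, a coding that keeps the mixed-model solver well scaled.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genpar, gwas as gwas_mod, validation as val_mod
from .components import CLASSICAL, SOCIAL
from .genomics import (GenotypeMatrix, QCThresholds, build_genomic_matrices,
                       h_inverse, impute_missing, qc_genotypes, center_dosages)
from .mme import ModelSpec, estimate_breeding_values, PEDIGREE_REL, SSGBLUP
from .pedigree import (Pedigree, a22, a_inverse, inbreeding,
                       pen_mate_relationship_from_pedigree, sort_and_validate)
from .reml import em_reml, pedigree_logdet, REMLOptions

log = logging.getLogger("igeblup")

PHENOTYPE_COLUMNS = ["animal", "score", "pen", "litter", "cg", "farm",
                     "scorer", "line", "age_days", "date"]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# readers / writers


def write_pedigree(ped: Pedigree, path) -> None:
    cols = ["animal", "sire", "dam", "line", "birth_date", "genotyped"]
    ped.table[cols].to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    tab = pd.read_csv(path)
    return sort_and_validate(tab)


def scale_scores(data: pd.DataFrame, scaling: bool = True) -> pd.DataFrame:
    """Attach the analysis phenotype ``y`` (= score x 100 when scaling)."""
    out = data.copy()
    out["y"] = out["score"] * (100.0 if scaling else 1.0)
    return out


def write_phenotypes(data: pd.DataFrame, path) -> None:
    data[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path, scaling: bool = True) -> pd.DataFrame:
    """Validated phenotype table with the analysis column ``y``.

    Scores must be 1 or 2 (continuous liabilities are written/read via
    plain CSV instead); duplicated animals and missing pens are errors.
    """
    data = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(data.columns)
    if missing:
        raise FormatError(f"phenotype file lacks columns {sorted(missing)}")
    bad = ~data["score"].isin([1, 2])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"score outside {{1,2}} at row {row + 2} (animal "
            f"{data['animal'].iloc[row]})")
    if data["animal"].duplicated().any():
        dup = data.loc[data["animal"].duplicated(), "animal"].iloc[0]
        raise FormatError(f"duplicated phenotype record for animal {dup}")
    if data["pen"].isna().any():
        row = int(np.flatnonzero(data["pen"].isna())[0])
        raise FormatError(f"missing pen at row {row + 2}")
    return scale_scores(data, scaling)


def write_dosages(geno: GenotypeMatrix, path) -> None:
    """Plain dosage table: animal column then one column per SNP id."""
    tab = pd.DataFrame(geno.dosages, columns=geno.snp_map["snp"])
    tab.insert(0, "animal", geno.ids)
    tab.to_csv(path, index=False)


def read_dosages(path, snp_map: pd.DataFrame) -> GenotypeMatrix:
    tab = pd.read_csv(path)
    ids = tab["animal"].to_numpy()
    dos = tab[snp_map["snp"]].to_numpy(dtype=float)
    return GenotypeMatrix(ids=ids, dosages=dos, snp_map=snp_map.copy())


def write_map(snp_map: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chrom": snp_map["chrom"], "snp": snp_map["snp"],
        "cm": 0, "pos": snp_map["pos"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_map(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos"])
    return tab[["snp", "chrom", "pos"]]


_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """PLINK text .ped/.map; missing dosages become '0 0'."""
    prefix = Path(prefix)
    write_map(geno.snp_map, prefix.with_suffix(".map"))
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(geno.ids):
            fields = [str(animal), str(animal), "0", "0", "0", "-9"]
            for d in geno.dosages[i]:
                if np.isnan(d):
                    fields.extend(("0", "0"))
                else:
                    fields.extend(_ALLELES[int(round(d))])
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = read_map(prefix.with_suffix(".map"))
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_map):
                raise FormatError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(snp_map)}")
            ids.append(int(parts[1]))
            alleles = parts[6:]
            a = np.array(alleles[0::2])
            b = np.array(alleles[1::2])
            miss = (a == "0") | (b == "0")
            dose = (a == "B").astype(float) + (b == "B")
            dose[miss] = np.nan
            rows.append(dose)
    return GenotypeMatrix(ids=np.array(ids), dosages=np.array(rows),
                          snp_map=snp_map)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Declared inputs, model choices and seeds of one pipeline run."""

    pedigree_path: str = ""
    phenotype_path: str = ""
    genotype_prefix: str = ""          # PLINK prefix or '' for no genomics
    out_dir: str = "results/run"
    model: int = 2                     # 1 classical, 2 social
    relationship: str = PEDIGREE_REL   # or 'ssgblup'
    scaling: bool = True
    blend_weight: float = 0.05
    cutoff_date: str = "2019-10-31"
    min_progeny: int = 10
    n_boot: int = 200
    window: int = 20
    alpha: float = 0.05
    qc_maf: float = 0.05
    qc_call_rate: float = 0.95
    qc_hwe_p: float = 1e-7
    reml_tol: float = 1e-9
    reml_maxiter: int = 500
    seed: int = 0

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            model=SOCIAL if self.model == 2 else CLASSICAL,
            relationship=self.relationship,
            blend_weight=self.blend_weight,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    out_dir: Path
    varcomp: object
    ebv: pd.DataFrame
    derived: object
    validation: pd.DataFrame | None = None
    gwas: object | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute QC -> relationships -> REML -> BLUP -> parameters ->
    validation (-> GWAS under ssGBLUP) and write every artifact.

    Stage failures abort with the stage name; partial outputs are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    spec = config.model_spec()
    if spec.relationship == SSGBLUP and not config.genotype_prefix:
        raise FormatError("relationship=ssgblup requires a genotype path")

    def stage(name):
        t0 = time.time()
        log.info("stage %s", name)

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3), **info}
        return done

    try:
        fin = stage("load")
        ped = read_pedigree(config.pedigree_path)
        data = read_phenotypes(config.phenotype_path, scaling=config.scaling)
        fin(n_pedigree=len(ped), n_records=len(data))

        fin = stage("relationships")
        Ainv = a_inverse(ped)
        rel_logdet = pedigree_logdet(ped)
        relinv = Ainv
        genomic = None
        if config.genotype_prefix:
            raw = read_plink(config.genotype_prefix)
            qc, report = qc_genotypes(raw, QCThresholds(
                maf=config.qc_maf, call_rate=config.qc_call_rate,
                hwe_p=config.qc_hwe_p))
            report.to_csv(out / "qc_report.csv", index=False)
            lines = ped.table.set_index("animal")["line"]
            geno = impute_missing(qc, lines)
            A22, A22_inv = a22(ped, geno.ids)
            genomic = build_genomic_matrices(geno, A22, A22_inv,
                                             weight=config.blend_weight)
            if spec.relationship == SSGBLUP:
                relinv = h_inverse(Ainv, genomic.hinv_correction,
                                   ped.positions_of(geno.ids))
        fin(nnz_relinv=int(relinv.nnz))

        fin = stage("reml")
        # variance components estimated without genomic information
        vc = em_reml(data, spec, Ainv, ped, rel_logdet=rel_logdet,
                     options=REMLOptions(tol=config.reml_tol,
                                         maxiter=config.reml_maxiter))
        pd.DataFrame([{**dict(zip(
            ["sigma2_ud", "sigma_uds", "sigma2_us"] if spec.is_social
            else ["sigma2_ud"],
            vc.as_vector()[:3] if spec.is_social else vc.as_vector()[:1])),
            "sigma2_gr": vc.sigma2_gr, "sigma2_cl": vc.sigma2_cl,
            "sigma2_cg": vc.sigma2_cg, "sigma2_e": vc.sigma2_e,
            "minus2logl": vc.meta["minus2logl"], "aic": vc.meta["aic"],
        }]).to_csv(out / "varcomp.csv", index=False)
        fin(iterations=vc.meta["iterations"], converged=vc.meta["converged"])

        fin = stage("blup")
        ebv = estimate_breeding_values(data, spec, vc, relinv, ped)
        fin(n_ebv=len(ebv))

        fin = stage("parameters")
        pens = data[["animal", "pen"]]
        summary = pen_mate_relationship_from_pedigree(ped, pens)
        if spec.is_social:
            derived = genpar.derived_params(vc, summary.n_bar, summary.r)
            ebv = genpar.total_breeding_values(ebv, n_bar=summary.n_bar)
        else:
            derived = genpar.derived_params(vc)
        ebv.to_csv(out / "ebv.csv", index=False)
        pd.DataFrame([vars(derived)]).to_csv(out / "derived_params.csv",
                                             index=False)
        fin(n_bar=summary.n_bar, r=summary.r)

        fin = stage("validation")
        partial = val_mod.split_partial(data, config.cutoff_date)
        vrep = None
        if len(partial) and len(partial) < len(data):
            ebv_p = estimate_breeding_values(partial, spec, vc, relinv, ped)
            sires = val_mod.select_validation_sires(
                ped.table, data, config.cutoff_date, config.min_progeny)
            F = inbreeding(ped)
            rows = []
            kinds = [("dbv", vc.sigma2_ud)]
            if spec.is_social:
                ebv_p = genpar.total_breeding_values(ebv_p, summary.n_bar)
                kinds += [("sbv", vc.sigma2_us),
                          ("tbv", genpar.sigma_tbv(vc, summary.n_bar))]
            for ids, group in ((sires, "sires"),):
                if not ids:
                    continue
                fbar = float(F[ped.positions_of(ids)].mean())
                for kind, s2 in kinds:
                    stat = val_mod.lr_statistics(
                        ebv_p.set_index("animal")[kind],
                        ebv.set_index("animal")[kind],
                        ids, fbar, s2, kind=kind)
                    rows.append({"group": group, **vars(stat)})
            vrep = pd.DataFrame(rows)
            vrep.to_csv(out / "validation.csv", index=False)
        fin(n_partial=len(partial))

        gw = None
        if genomic is not None and spec.relationship == SSGBLUP:
            fin = stage("gwas")
            from .mme import assemble_mme, build_design, solve_mme

            M, _, scale = center_dosages(geno)
            design = build_design(data, spec, ped)
            # PEV route for sd(a) needs the MME inverse; feasible at
            # desk scale, otherwise fall back to Var(u) = G_blend*s2u
            use_pev = design.n_equations <= 8000
            solution = solve_mme(assemble_mme(design, vc, relinv),
                                 compute_inverse=use_pev)
            gpos = ped.positions_of(geno.ids)
            comps = [("direct", vc.sigma2_ud)]
            if spec.is_social:
                comps.append(("social", vc.sigma2_us))
            tables = {}
            for comp, s2 in comps:
                sl = solution.slices[comp]
                u_hat = solution.sol[sl][gpos]
                if use_pev:
                    pev = solution.c_inv[sl, sl][np.ix_(gpos, gpos)]
                    var_u = gwas_mod.gebv_covariance(pev, genomic.G_blend, s2)
                else:
                    log.warning("system too large for the PEV route; "
                                "using Var(u) = G_blend * sigma2_u")
                    var_u = gwas_mod.gebv_covariance(
                        None, genomic.G_blend, s2, ignore_pev=True)
                res = gwas_mod.run_gwas(
                    u_hat, genomic.G_blend, M, geno.snp_map, s2, var_u,
                    vanraden_scale=scale, component=comp, model=spec.model,
                    window=config.window, alpha=config.alpha)
                res.snps.to_csv(out / f"gwas_{comp}.csv", index=False)
                res.windows.to_csv(out / f"gwas_{comp}_windows.csv",
                                   index=False)
                tables[comp] = res
            gw = tables
            fin(n_snps=geno.n_snps, pev_route=use_pev)
    except Exception as err:
        manifest["failed"] = repr(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(out_dir=out, varcomp=vc, ebv=ebv, derived=derived,
                          validation=vrep, gwas=gw, manifest=manifest)
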