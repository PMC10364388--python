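"""Synthetic pen-structured population generator.

Emulates a multiplier-farm population of F1 gilts scored once for a
binary skin-damage trait at the end of the finishing phase: purebred
sires and dams produce crossbred litters on several farms, litters are
split into finishing pens of ~10.7 animals, and each gilt's liability
is the sum of fixed effects, her own direct genetic effect, the social
genetic effects of her pen mates, and pen / litter / contemporary-group
/ residual environmental effects.  Thresholding the liability at a
configured incidence yields the binary score (1 = damaged, 2 = sold
undamaged).

Default generating (co)variances are the social-model estimates the
package is benchmarked against (direct 14.21, social 0.29, correlation
-0.05, pen 68.84, litter 8.60, contemporary group 15.79, residual
284.3 on the 100-point score scale); the default incidence is 4.3% and
pens average 10.7 +/- 0.7 animals.

Recovery experiments can record the continuous liability itself
(``record_liability=True``): the linear mixed models fitted downstream
are then exactly correctly specified and the generating components live
on the observed scale, which is how all parameter-recovery tests in
this package are calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .components import SOCIAL, VarianceComponents, social_components
from .pedigree import Pedigree, mendelian_variances, sort_and_validate

# Social-model generating values (100-point score scale).
MODEL2_TRUE = social_components(
    sigma2_ud=14.21, sigma2_us=0.29, sigma2_gr=68.84, sigma2_cl=8.60,
    sigma2_cg=15.79, sigma2_e=284.3, r_uds=-0.05,
)
# Classical-model generating values; the residual completes a phenotypic
# variance of 469.28 so that the generating heritability is 0.030.
MODEL1_TRUE = VarianceComponents(
    sigma2_ud=14.08, sigma2_us=None, sigma_uds=None, sigma2_gr=72.28,
    sigma2_cl=8.91, sigma2_cg=16.60, sigma2_e=357.41, model="classical",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design knobs of the generator.

    The defaults describe the emulated population at a reduced scale:
    5 farms of 200 pens averaging 10.7 gilts (~10,700 gilts), 64
    purebred sires (a fraction with progeny on several farms), litters
    of ~5 scored gilts, and 2,000 SNPs on 10 autosomes genotyped only on
    purebred ancestors.
    """

    n_farms: int = 5
    pens_per_farm: int = 200
    pen_size_mean: float = 10.7
    pen_size_sd: float = 0.7
    n_sires: int = 64
    n_dams: int = 1100
    gilts_per_litter: float = 5.0
    n_founder_generations: int = 3
    founders_per_line: int = 24
    sire_lines: tuple[str, ...] = ("D1", "D2")
    dam_lines: tuple[str, ...] = ("D1", "D2", "D3")
    multi_farm_sire_fraction: float = 0.43
    # sires enter service in a staggered fashion so that "young sires"
    # with progeny only late in the recording window exist
    sire_entry_spread: bool = True
    n_scorers: int = 8
    scorers_per_farm: int = 3
    n_birth_months: int = 12
    first_birth_month: str = "2019-01"
    age_mean_days: float = 146.0
    age_sd_days: float = 13.0
    # fixed-effect magnitudes (100-point score scale)
    line_effect_sd: float = 2.0
    scorer_effect_sd: float = 4.0
    age_slope: float = 0.10
    # genetics
    true_varcomp: VarianceComponents = field(default_factory=lambda: MODEL2_TRUE)
    r_uds_true: float | None = None  # overrides true_varcomp's covariance
    target_incidence: float = 0.043
    record_liability: bool = False
    # genotypes
    n_snps: int = 2000
    n_chromosomes: int = 10
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    line_freq_jitter_sd: float = 0.02
    missing_rate: float = 0.005
    genotype_dam_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pen_size_mean <= 1:
            raise ConfigurationError("pen_size_mean must exceed 1")
        if not 0 < self.target_incidence < 1:
            raise ConfigurationError("target_incidence must be in (0, 1)")
        if min(self.n_farms, self.pens_per_farm, self.n_sires, self.n_dams) < 1:
            raise ConfigurationError("all design counts must be positive")
        if self.r_uds_true is not None:
            if abs(self.r_uds_true) > 1:
                raise ConfigurationError("|r_uds_true| must not exceed 1")
            vc = self.true_varcomp
            if vc.is_social:
                self.true_varcomp = social_components(
                    vc.sigma2_ud, vc.sigma2_us, vc.sigma2_gr, vc.sigma2_cl,
                    vc.sigma2_cg, vc.sigma2_e, r_uds=self.r_uds_true,
                )
        # the implied 2x2 genetic matrix must be PSD
        g = self.true_varcomp.genetic_matrix()
        if np.linalg.eigvalsh(g).min() < -1e-10:
            raise ConfigurationError("direct-social genetic matrix is not PSD")

    @property
    def n_gilts(self) -> int:
        return int(round(self.n_farms * self.pens_per_farm * self.pen_size_mean))

    def with_(self, **changes) -> "SimConfig":
        return replace(self, **changes)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    return np.random.default_rng([int(config.seed) % (2**31), stage])


@dataclass
class TrueEffects:
    """True random effects on the liability scale.

    Genetic effects cover every pedigree animal; the environmental
    effects (pen, litter, contemporary group, residual) are drawn when
    phenotypes are simulated and keyed by their factor levels.
    """

    ids: np.ndarray
    u_d: np.ndarray
    u_s: np.ndarray
    gr: pd.Series | None = None
    cl: pd.Series | None = None
    cg: pd.Series | None = None
    e: pd.Series | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.ids, "u_d": self.u_d, "u_s": self.u_s})


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate purebred ancestor generations and F1 gilt litters.

    Returns a sorted :class:`Pedigree` whose table carries two extra
    columns for the phenotyped cohort: ``farm`` (missing for ancestors)
    and ``sex``.  Litter identity is implicit in (sire, dam, birth_date).
    Only purebred ancestors are flagged as genotyped.
    """
    rng = _rng(config, stage=1)
    rows: list[tuple] = []
    next_id = 1

    def new_animals(k, sire, dam, line, date, genotyped, sex, farm=None):
        nonlocal next_id
        out = []
        for _ in range(k):
            rows.append((next_id, sire, dam, line, date, genotyped, sex, farm))
            out.append(next_id)
            next_id += 1
        return out

    lines = sorted(set(config.sire_lines) | set(config.dam_lines))
    depth = max(config.n_founder_generations - 1, 1)
    # purebred layers: founders, then `depth - 1` within-line generations
    males: dict[str, list[int]] = {}
    females: dict[str, list[int]] = {}
    for ln in lines:
        males[ln] = new_animals(
            config.founders_per_line // 2, 0, 0, ln, "2014-01-01", True, "M")
        females[ln] = new_animals(
            (config.founders_per_line + 1) // 2, 0, 0, ln, "2014-01-01", True, "F")
    for g in range(1, depth):
        date = f"{2014 + g}-01-01"
        for ln in lines:
            sires = rng.choice(males[ln], size=config.founders_per_line)
            dams = rng.choice(females[ln], size=config.founders_per_line)
            new_m, new_f = [], []
            for k, (s, d) in enumerate(zip(sires, dams)):
                sex = "M" if k % 2 == 0 else "F"
                (a,) = new_animals(1, int(s), int(d), ln, date, True, sex)
                (new_m if sex == "M" else new_f).append(a)
            males[ln] = new_m or males[ln]
            females[ln] = new_f or females[ln]
    # breeding sires (purebred, genotyped) and dams (purebred, mostly ungenotyped)
    sire_ids, sire_line = [], {}
    for k in range(config.n_sires):
        ln = config.sire_lines[k % len(config.sire_lines)]
        s = int(rng.choice(males[ln]))
        d = int(rng.choice(females[ln]))
        (a,) = new_animals(1, s, d, ln, "2017-06-01", True, "M")
        sire_ids.append(a)
        sire_line[a] = ln
    dam_ids, dam_line = [], {}
    geno_dams = rng.random(config.n_dams) < config.genotype_dam_fraction
    for k in range(config.n_dams):
        ln = config.dam_lines[k % len(config.dam_lines)]
        s = int(rng.choice(males[ln]))
        d = int(rng.choice(females[ln]))
        (a,) = new_animals(1, s, d, ln, "2017-06-01", bool(geno_dams[k]), "F")
        dam_ids.append(a)
        dam_line[a] = ln

    # farm service: every sire has a home farm; a configured fraction serves more
    sire_farms: dict[int, list[int]] = {}
    farms_of_sires = rng.integers(0, config.n_farms, size=config.n_sires)
    multi = rng.random(config.n_sires) < config.multi_farm_sire_fraction
    for k, a in enumerate(sire_ids):
        fs = {int(farms_of_sires[k])}
        if multi[k] and config.n_farms > 1:
            extra = 1 + rng.integers(0, min(4, config.n_farms - 1))
            fs |= set(
                int(f) for f in rng.choice(
                    [f for f in range(config.n_farms) if f not in fs],
                    size=min(extra, config.n_farms - 1), replace=False)
            )
        sire_farms[a] = sorted(fs)
    farm_sires: dict[int, list[int]] = {f: [] for f in range(config.n_farms)}
    for a, fs in sire_farms.items():
        for f in fs:
            farm_sires[f].append(a)
    for f in range(config.n_farms):
        if not farm_sires[f]:
            farm_sires[f].append(sire_ids[f % len(sire_ids)])

    # litters of F1 gilts; dams are split across farms
    n_gilts = config.n_gilts
    n_litters = max(1, int(math.ceil(n_gilts / config.gilts_per_litter)))
    if n_litters > 4 * config.n_dams:
        raise ConfigurationError(
            f"{n_litters} litters requested but only {config.n_dams} dams "
            "(at most 4 litters each); increase n_dams or gilts_per_litter")
    dam_farm = {a: int(f) for a, f in zip(
        dam_ids, rng.integers(0, config.n_farms, size=config.n_dams))}
    months = [
        (pd.Period(config.first_birth_month, "M") + m).strftime("%Y-%m")
        for m in range(config.n_birth_months)
    ]
    if config.sire_entry_spread:
        entry = {a: int(m) for a, m in zip(
            sire_ids, rng.integers(0, config.n_birth_months,
                                   size=config.n_sires))}
    else:
        entry = {a: 0 for a in sire_ids}
    made = 0
    k = 0
    while made < n_gilts:
        dam = dam_ids[k % config.n_dams]
        k += 1
        farm = dam_farm[dam]
        month_idx = int(rng.integers(0, len(months)))
        in_service = [s for s in farm_sires[farm] if entry[s] <= month_idx]
        sire = int(rng.choice(in_service or farm_sires[farm]))
        month = months[month_idx]
        day = int(rng.integers(1, 29))
        date = f"{month}-{day:02d}"
        size = max(1, int(rng.poisson(config.gilts_per_litter)))
        size = min(size, n_gilts - made)
        ln = f"{sire_line[sire]}x{dam_line[dam]}"
        new_animals(size, sire, dam, ln, date, False, "F", farm=farm)
        made += size

    table = pd.DataFrame(
        rows,
        columns=["animal", "sire", "dam", "line", "birth_date", "genotyped",
                 "sex", "farm"],
    )
    ped = sort_and_validate(table)
    return ped


def gilt_cohort(ped: Pedigree) -> pd.DataFrame:
    """Phenotyped cohort: crossbred females carrying a farm assignment."""
    tab = ped.table
    return tab[tab["farm"].notna()].copy()


# ---------------------------------------------------------------------------
# breeding values


def simulate_true_breeding_values(
    ped: Pedigree, varcomp: VarianceComponents, seed: int = 0
) -> TrueEffects:
    """Gene-flow simulation of correlated direct/social breeding values.

    Founders draw (u_D, u_S) from the 2x2 genetic covariance; offspring
    are the parent average plus a Mendelian-sampling deviation with
    covariance ``(0.5 - 0.25*(F_s + F_d)) * G2x2`` (one form for unknown
    parents), so E[var] reproduces ``A (x) G2x2``.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 2])
    g = varcomp.genetic_matrix()
    if varcomp.is_social:
        g2 = g
    else:
        g2 = np.array([[varcomp.sigma2_ud, 0.0], [0.0, 0.0]])
    w, v = np.linalg.eigh(g2)
    if w.min() < -1e-10:
        raise ValueError("genetic covariance matrix is not PSD")
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    d = mendelian_variances(ped)
    n = len(ped)
    z = rng.standard_normal((n, 2)) @ L.T
    u = np.zeros((n, 2))
    s, dm = ped.sire_pos, ped.dam_pos
    for i in range(n):
        pa = 0.0
        if s[i] >= 0:
            pa = pa + 0.5 * u[s[i]]
        if dm[i] >= 0:
            pa = pa + 0.5 * u[dm[i]]
        u[i] = pa + math.sqrt(d[i]) * z[i]
    return TrueEffects(ids=ped.ids.copy(), u_d=u[:, 0], u_s=u[:, 1])


# ---------------------------------------------------------------------------
# pens


def draw_pen_sizes(n_pens: int, mean: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Integer pen sizes around ``mean`` +/- ``sd``, truncated to >= 2."""
    if mean < 2:
        raise ConfigurationError("pen_size_mean below 2 cannot form pens")
    sizes = np.rint(rng.normal(mean, sd, size=n_pens)).astype(int)
    return np.maximum(sizes, 2)


def assign_pens(ped: Pedigree, config: SimConfig) -> pd.DataFrame:
    """Assign each gilt to exactly one pen; derive litter and cg labels.

    Pens are filled within farm with randomly ordered gilts (grouping in
    the emulated population aimed at uniform body weight, which is not
    modelled, so random filling is the neutral stand-in).  Contemporary
    group is farm x year-month of birth; litter is the (sire, dam,
    birth_date) triple.
    """
    rng = _rng(config, stage=3)
    gilts = gilt_cohort(ped)
    if gilts.empty:
        raise ConfigurationError("no phenotyped cohort in pedigree")
    parts = []
    pen_no = 0
    for farm, sub in gilts.groupby("farm"):
        order = sub.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        n = len(order)
        sizes = []
        while sum(sizes) < n:
            sizes.extend(draw_pen_sizes(
                8, config.pen_size_mean, config.pen_size_sd, rng).tolist())
        # trim to exactly n animals; merge a too-small tail into the last pen
        cum, kept = 0, []
        for s in sizes:
            if cum + s >= n:
                kept.append(n - cum)
                break
            kept.append(s)
            cum += s
        if kept[-1] < 2 and len(kept) > 1:
            kept[-2] += kept[-1]
            kept.pop()
        pen_ids = np.repeat(
            [f"F{int(farm)}P{pen_no + k}" for k in range(len(kept))], kept)
        pen_no += len(kept)
        part = pd.DataFrame({
            "animal": order["animal"].to_numpy(),
            "farm": int(farm),
            "pen": pen_ids,
        })
        parts.append(part)
    pens = pd.concat(parts, ignore_index=True)
    meta = gilts.set_index("animal")
    pens["litter"] = [
        f"L{meta.at[a, 'sire']}-{meta.at[a, 'dam']}-{meta.at[a, 'birth_date']}"
        for a in pens["animal"]
    ]
    pens["cg"] = [
        f"F{meta.at[a, 'farm']:.0f}-{str(meta.at[a, 'birth_date'])[:7]}"
        for a in pens["animal"]
    ]
    return pens.sort_values("animal", ignore_index=True)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    effects: TrueEffects, pens: pd.DataFrame, config: SimConfig,
    ped: Pedigree,
) -> pd.DataFrame:
    """Liability-threshold phenotypes for the penned cohort.

    liability_i = line_i + scorer_i + b*(age_i - mean age) + u_D,i
                  + sum_{j in pen(i), j != i} u_S,j + gr + cl + cg + e_i

    The binary score is 1 (damaged) above a threshold placed at the
    ``1 - target_incidence`` quantile of the liability distribution,
    calibrated on the realised mean and standard deviation; else 2.
    With ``record_liability=True`` the liability itself is recorded.

    Environmental effect draws are stored back on ``effects`` so that
    recovery tests can compare estimates against the truth.
    """
    if pens.empty:
        raise ConfigurationError("empty pen assignment")
    if (pens.groupby("pen")["animal"].size() < 1).any():
        raise ConfigurationError("empty pens in assignment")
    rng = _rng(config, stage=4)
    vc = config.true_varcomp
    pos = ped.positions_of(pens["animal"].to_numpy())
    line = ped.table["line"].to_numpy()[pos]

    # pen-mate social sum: per pen, total u_s minus own
    u_s = effects.u_s[pos]
    u_d = effects.u_d[pos]
    pen_codes, pen_levels = pd.factorize(pens["pen"])
    pen_sum = np.bincount(pen_codes, weights=u_s, minlength=len(pen_levels))
    social = pen_sum[pen_codes] - u_s

    lines = pd.unique(line)
    line_eff = pd.Series(
        rng.normal(0.0, config.line_effect_sd, size=len(lines)), index=lines)
    scorer_eff = rng.normal(0.0, config.scorer_effect_sd, size=config.n_scorers)
    # scorers work within farm: each farm draws a panel, gilts of a pen share one
    farm_panels = {
        int(f): rng.choice(config.n_scorers,
                           size=min(config.scorers_per_farm, config.n_scorers),
                           replace=False)
        for f in pens["farm"].unique()
    }
    pen_scorer = {}
    pen_age = {}
    for p, sub in pens.groupby("pen"):
        farm = int(sub["farm"].iloc[0])
        pen_scorer[p] = int(rng.choice(farm_panels[farm]))
        pen_age[p] = rng.normal(config.age_mean_days, config.age_sd_days)
    scorer = np.array([pen_scorer[p] for p in pens["pen"]])
    age = np.array([pen_age[p] for p in pens["pen"]])

    gr_levels = pen_levels
    cl_codes, cl_levels = pd.factorize(pens["litter"])
    cg_codes, cg_levels = pd.factorize(pens["cg"])
    gr = rng.normal(0.0, math.sqrt(vc.sigma2_gr), size=len(gr_levels))
    cl = rng.normal(0.0, math.sqrt(vc.sigma2_cl), size=len(cl_levels))
    cg = rng.normal(0.0, math.sqrt(vc.sigma2_cg), size=len(cg_levels))
    e = rng.normal(0.0, math.sqrt(vc.sigma2_e), size=len(pens))

    liability = (
        line_eff[line].to_numpy()
        + scorer_eff[scorer]
        + config.age_slope * (age - config.age_mean_days)
        + u_d + social
        + gr[pen_codes] + cl[cl_codes] + cg[cg_codes] + e
    )

    effects.gr = pd.Series(gr, index=gr_levels)
    effects.cl = pd.Series(cl, index=cl_levels)
    effects.cg = pd.Series(cg, index=cg_levels)
    effects.e = pd.Series(e, index=pens["animal"].to_numpy())

    if config.record_liability:
        score = liability
    else:
        z = norm.ppf(1.0 - config.target_incidence)
        threshold = liability.mean() + z * liability.std(ddof=1)
        score = np.where(liability > threshold, 1, 2)

    birth = ped.table["birth_date"].to_numpy()[pos]
    date = (
        pd.to_datetime(birth) + pd.to_timedelta(np.round(age), unit="D")
    ).strftime("%Y-%m-%d")
    return pd.DataFrame({
        "animal": pens["animal"].to_numpy(),
        "score": score,
        "pen": pens["pen"].to_numpy(),
        "litter": pens["litter"].to_numpy(),
        "cg": pens["cg"].to_numpy(),
        "farm": pens["farm"].to_numpy(),
        "scorer": scorer,
        "line": line,
        "age_days": age,
        "date": date,
    })


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(ped: Pedigree, config: SimConfig):
    """Gene-drop SNP genotypes through the pedigree.

    Founder allele frequencies are drawn per line around a shared base
    frequency (uniform on ``founder_freq_range``); two alleles per locus
    are transmitted by Mendelian sampling.  Only animals flagged as
    genotyped are exported, with missingness at ``missing_rate``.
    """
    from .genomics import GenotypeMatrix  # local import avoids a cycle

    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be positive")
    rng = _rng(config, stage=5)
    m = config.n_snps
    base = rng.uniform(*config.founder_freq_range, size=m)
    lines = sorted(ped.table["line"].unique())
    line_freq = {
        ln: np.clip(base + rng.normal(0.0, config.line_freq_jitter_sd, size=m),
                    0.01, 0.99)
        for ln in lines
    }
    n = len(ped)
    s, d = ped.sire_pos, ped.dam_pos
    line_arr = ped.table["line"].to_numpy()
    alleles = np.zeros((2, n, m), dtype=np.int8)
    for i in range(n):
        for k, p in enumerate((s[i], d[i])):
            if p < 0:
                freq = line_freq.get(line_arr[i], base)
                alleles[k, i] = rng.random(m) < freq
            else:
                pick = rng.random(m) < 0.5
                alleles[k, i] = np.where(pick, alleles[0, p], alleles[1, p])
    genotyped = ped.table["genotyped"].astype(bool).to_numpy()
    ids = ped.ids[genotyped]
    dosage = (alleles[0, genotyped].astype(np.float64)
              + alleles[1, genotyped])
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos_bp = np.concatenate([
        50_000 * (np.arange(c) + 1) for c in per_chrom
    ])
    snp_map = pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(m)],
        "chrom": chrom,
        "pos": pos_bp,
    })
    return GenotypeMatrix(ids=ids, dosages=dosage, snp_map=snp_map)


# ---------------------------------------------------------------------------
# one-call world


@dataclass
class SimulatedWorld:
    """Everything one replicate of the study design produces."""

    config: SimConfig
    pedigree: Pedigree
    effects: TrueEffects
    pens: pd.DataFrame
    phenotypes: pd.DataFrame
    genotypes: object | None = None


def simulate_world(config: SimConfig, with_genotypes: bool = False) -> SimulatedWorld:
    ped = simulate_pedigree(config)
    effects = simulate_true_breeding_values(
        ped, config.true_varcomp, seed=config.seed)
    pens = assign_pens(ped, config)
    phen = simulate_phenotypes(effects, pens, config, ped)
    geno = simulate_genotypes(ped, config) if with_genotypes else None
    return SimulatedWorld(config, ped, effects, pens, phen, geno)
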