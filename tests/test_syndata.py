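import numpy as np
import pandas as pd
import pytest

from igeblup.components import VarianceComponents, social_components
from igeblup.interface import scale_scores
from igeblup.pedigree import sort_and_validate
from igeblup.syndata import (
    MODEL2_TRUE, ConfigurationError, SimConfig, assign_pens, draw_pen_sizes,
    gilt_cohort, simulate_genotypes, simulate_pedigree, simulate_phenotypes,
    simulate_true_breeding_values, simulate_world,
)
from .conftest import make_pedigree


def founder_pedigree(n):
    return make_pedigree([(i, 0, 0) for i in range(1, n + 1)])


class TestSimulatePedigree:
    def test_small_family_structure(self):
        cfg = SimConfig(n_farms=1, pens_per_farm=1, pen_size_mean=3.0,
                        pen_size_sd=0.0, n_sires=1, n_dams=1,
                        gilts_per_litter=3.0, founders_per_line=4,
                        n_founder_generations=1, seed=1)
        ped = simulate_pedigree(cfg)
        gilts = gilt_cohort(ped)
        assert len(gilts) == 3
        # all three gilts are full sibs from the single sire x dam pair
        assert gilts["sire"].nunique() == 1
        assert gilts["dam"].nunique() == 1

    def test_same_seed_identical(self, tiny_config):
        p1 = simulate_pedigree(tiny_config)
        p2 = simulate_pedigree(tiny_config)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_multi_farm_sire_fraction(self):
        cfg = SimConfig(pens_per_farm=30, n_sires=80, n_dams=300,
                        multi_farm_sire_fraction=0.43, seed=3,
                        n_founder_generations=1, founders_per_line=8)
        ped = simulate_pedigree(cfg)
        gilts = gilt_cohort(ped)
        farms_per_sire = gilts.groupby("sire")["farm"].nunique()
        frac = (farms_per_sire >= 2).mean()
        assert abs(frac - 0.43) < 0.12

    def test_genotyped_only_purebred_ancestors(self, tiny_world):
        tab = tiny_world.pedigree.table
        genotyped = tab[tab["genotyped"].astype(bool)]
        assert (genotyped["farm"].isna()).all()  # never a phenotyped gilt
        assert (~genotyped["line"].str.contains("x")).all()

    def test_infeasible_litter_demand_raises(self):
        with pytest.raises(ConfigurationError, match="litters"):
            simulate_pedigree(SimConfig(pens_per_farm=100, n_dams=10,
                                        gilts_per_litter=2.0))


class TestTrueBreedingValues:
    def test_no_social_variance_means_zero_us(self):
        ped = founder_pedigree(50)
        vc = social_components(5.0, 0.0, 1, 1, 1, 1, r_uds=0.0)
        eff = simulate_true_breeding_values(ped, vc, seed=1)
        assert np.all(eff.u_s == 0.0)

    def test_founder_covariance_recovers_target(self):
        ped = founder_pedigree(10_000)
        eff = simulate_true_breeding_values(ped, MODEL2_TRUE, seed=2)
        r = np.corrcoef(eff.u_d, eff.u_s)[0, 1]
        se = 1.0 / np.sqrt(len(ped) - 3)  # Fisher-z standard error
        assert abs(np.arctanh(r) - np.arctanh(-0.05)) < 3 * se
        assert np.var(eff.u_d) == pytest.approx(14.21, rel=0.1)
        assert np.var(eff.u_s) == pytest.approx(0.29, rel=0.1)

    def test_selfed_clone_mendelian_variance_scales(self):
        # parent from a full-sib mating (F = 0.25); 4,000 selfed
        # offspring: deviation variance 0.5 * (1 - 0.25) * sigma2
        rows = [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)]
        rows += [(6 + k, 5, 5) for k in range(4000)]
        ped = make_pedigree(rows)
        vc = social_components(8.0, 0.5, 1, 1, 1, 1, r_uds=0.0)
        eff = simulate_true_breeding_values(ped, vc, seed=3)
        dev = eff.u_d[5:] - eff.u_d[4]
        assert np.var(dev) == pytest.approx(0.5 * 0.75 * 8.0, rel=0.1)

    def test_offspring_on_midparent_regression(self):
        # 5,000 independent trios
        rows = [(i, 0, 0) for i in range(1, 10_001)]
        rows += [(10_000 + k, 2 * k - 1, 2 * k) for k in range(1, 5_001)]
        ped = make_pedigree(rows)
        vc = social_components(10.0, 1.0, 1, 1, 1, 1, r_uds=0.3)
        eff = simulate_true_breeding_values(ped, vc, seed=4)
        mid = 0.5 * (eff.u_d[0:10_000:2] + eff.u_d[1:10_000:2])
        off = eff.u_d[10_000:]
        slope, intercept = np.polyfit(mid, off, 1)
        resid = off - slope * mid - intercept
        se = np.sqrt(np.var(resid) / (len(mid) * np.var(mid)))
        assert abs(slope - 1.0) < 3 * se

    def test_unsorted_pedigree_rejected(self):
        tab = pd.DataFrame(
            [(2, 1, 0, "L", "2019", False), (1, 0, 0, "L", "2018", False)],
            columns=["animal", "sire", "dam", "line", "birth_date",
                     "genotyped"])
        ped = sort_and_validate(tab)  # sorting is the supported path
        assert list(ped.ids) == [1, 2]


class TestAssignPens:
    def test_mean_pen_size_near_default(self):
        rng = np.random.default_rng(0)
        sizes = draw_pen_sizes(2000, 10.7, 0.7, rng)
        assert abs(sizes.mean() - 10.7) < 0.2

    def test_zero_sd_gives_exact_sizes(self):
        rng = np.random.default_rng(1)
        assert np.all(draw_pen_sizes(50, 10.0, 0.0, rng) == 10)

    def test_membership_disjoint_and_complete(self, tiny_world):
        pens = tiny_world.pens
        assert pens["animal"].is_unique
        gilts = gilt_cohort(tiny_world.pedigree)
        assert set(pens["animal"]) == set(gilts["animal"])

    def test_pen_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            draw_pen_sizes(10, 1.0, 0.0, np.random.default_rng(0))

    def test_litters_follow_sire_dam_birth(self, tiny_world):
        pens = tiny_world.pens
        meta = gilt_cohort(tiny_world.pedigree).set_index("animal")
        key = pens["animal"].map(
            lambda a: (meta.at[a, "sire"], meta.at[a, "dam"],
                       meta.at[a, "birth_date"]))
        assert (pens.groupby("litter")["animal"].transform("size")
                == key.map(key.value_counts()).to_numpy()).all()


class TestSimulatePhenotypes:
    def test_incidence_under_pure_noise(self):
        vc = social_components(1e-8, 1e-8, 1e-8, 1e-8, 1e-8, 300.0, 0.0)
        cfg = SimConfig(pens_per_farm=40, n_sires=30, n_dams=260,
                        n_founder_generations=1, founders_per_line=8,
                        true_varcomp=vc, line_effect_sd=0.0,
                        scorer_effect_sd=0.0, age_slope=0.0, seed=5)
        w = simulate_world(cfg)
        p = (w.phenotypes["score"] == 1).mean()
        n = len(w.phenotypes)
        se = np.sqrt(0.043 * 0.957 / n)
        assert abs(p - 0.043) < 3 * se + 1e-9

    def test_scores_scale_to_100_200(self, tiny_world):
        scaled = scale_scores(tiny_world.phenotypes)
        assert set(scaled["y"].unique()) <= {100.0, 200.0}

    def test_doubling_social_effects_raises_pen_liability(self,
                                                          liability_world):
        w = liability_world
        pens = w.pens
        target_pen = None
        for pen, grp in pens.groupby("pen"):
            pos = w.pedigree.positions_of(grp["animal"].to_numpy())
            if w.effects.u_s[pos].sum() > 0:
                target_pen = pen
                break
        assert target_pen is not None
        eff2 = simulate_true_breeding_values(
            w.pedigree, w.config.true_varcomp, seed=w.config.seed)
        members = pens.loc[pens["pen"] == target_pen, "animal"].to_numpy()
        pos = w.pedigree.positions_of(members)
        eff2.u_s[pos] *= 2.0
        phen2 = simulate_phenotypes(eff2, pens, w.config, w.pedigree)
        before = w.phenotypes.set_index("animal").loc[members, "score"]
        after = phen2.set_index("animal").loc[members, "score"]
        # same residual streams, so liabilities move by the added social
        # sums; each member with positive pen-mate sum gains liability
        assert (after - before).sum() > 0

    def test_empty_pens_rejected(self, liability_world):
        with pytest.raises(ConfigurationError):
            simulate_phenotypes(liability_world.effects,
                                liability_world.pens.iloc[:0],
                                liability_world.config,
                                liability_world.pedigree)


class TestSimulateGenotypes:
    def test_homozygous_parents_transmit(self, tiny_world):
        geno = tiny_world.genotypes
        ped = tiny_world.pedigree
        ids = set(geno.ids)
        tab = ped.table.set_index("animal")
        lookup = {a: i for i, a in enumerate(geno.ids)}
        checked = 0
        for a in geno.ids:
            s, d = tab.at[a, "sire"], tab.at[a, "dam"]
            if s in ids and d in ids:
                both2 = ((geno.dosages[lookup[s]] == 2)
                         & (geno.dosages[lookup[d]] == 2)
                         & ~np.isnan(geno.dosages[lookup[a]]))
                assert np.all(geno.dosages[lookup[a]][both2] == 2)
                checked += both2.sum()
        assert checked > 0

    def test_mean_dosage_at_half_frequency(self):
        ped = founder_pedigree(400)
        ped.table["genotyped"] = True
        cfg = SimConfig(n_snps=200, founder_freq_range=(0.5, 0.5),
                        line_freq_jitter_sd=0.0, missing_rate=0.0, seed=6)
        geno = simulate_genotypes(ped, cfg)
        se = np.sqrt(0.5 / (2 * 400 * 200))
        assert abs(geno.dosages.mean() - 1.0) < 3 * se * 2

    def test_same_seed_identical_matrix(self, tiny_config, tiny_world):
        again = simulate_genotypes(tiny_world.pedigree, tiny_config)
        assert np.array_equal(again.dosages, tiny_world.genotypes.dosages,
                              equal_nan=True)

    def test_map_sorted_and_partitioned(self, tiny_world):
        m = tiny_world.genotypes.snp_map
        assert m["chrom"].nunique() == tiny_world.config.n_chromosomes
        assert (m.groupby("chrom")["pos"].diff().dropna() > 0).all()


def test_pen_sum_of_social_effects_variance():
    """Var of the pen-mate social sum for unrelated animals is
    (n - 1) * sigma2_us (checked against the direct simulation)."""
    ped = founder_pedigree(60_000)
    vc = social_components(1.0, 2.0, 1, 1, 1, 1, r_uds=0.0)
    eff = simulate_true_breeding_values(ped, vc, seed=8)
    size = 6
    pens = np.repeat(np.arange(len(ped) // size), size)
    sums = np.bincount(pens, weights=eff.u_s)[pens] - eff.u_s
    assert np.var(sums) == pytest.approx((size - 1) * 2.0, rel=0.05)
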