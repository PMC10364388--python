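import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from igeblup.components import VarianceComponents, social_components
from igeblup.mme import (
    MMEError, ModelSpec, assemble_mme, build_design, estimate_breeding_values,
    solve_mme,
)
from igeblup.genomics import h_inverse
from igeblup.pedigree import a_inverse, a_matrix, a22
from .conftest import make_pedigree

VC = social_components(4.0, 1.0, 40.0, 6.0, 5.0, 60.0, r_uds=-0.2)
VC1 = VarianceComponents(4.0, None, None, 40.0, 6.0, 5.0, 60.0,
                         model="classical")


def small_dataset():
    """9 phenotyped full/half-sib gilts in 3 pens."""
    ped = make_pedigree(
        [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)]
        + [(5 + k, 1 + (k % 2), 3 + (k // 5), 0) for k in range(9)])
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "animal": range(5, 14),
        "y": rng.normal(150, 12, size=9).round(1),
        "pen": np.repeat(["p1", "p2", "p3"], 3),
        "litter": np.repeat(["l1", "l2", "l3"], 3),
        "cg": ["c1"] * 5 + ["c2"] * 4,
        "scorer": [1, 1, 1, 2, 2, 2, 1, 1, 1],
        "line": ["A", "A", "B", "B", "A", "B", "A", "B", "A"],
        "age_days": rng.normal(146, 10, size=9).round(0),
    })
    return ped, data


class TestBuildDesign:
    def test_zs_rows_link_pen_mates_only(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model="social"), ped)
        Z_S = design.genetic[1].Z.toarray()
        pos = ped.id_to_pos
        row0 = Z_S[0]  # animal 5 in pen p1 with animals 6, 7
        assert row0[pos[6]] == 1 and row0[pos[7]] == 1
        assert row0[pos[5]] == 0
        assert row0.sum() == 2

    def test_zs_row_sums_equal_pen_size_minus_one(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model="social"), ped)
        sums = np.asarray(design.genetic[1].Z.sum(axis=1)).ravel()
        expected = data.groupby("pen")["animal"].transform("size") - 1
        assert np.array_equal(sums, expected.to_numpy())

    def test_classical_design_drops_social_only(self):
        ped, data = small_dataset()
        social = build_design(data, ModelSpec(model="social"), ped)
        classical = build_design(data, ModelSpec(model="classical"), ped)
        assert len(classical.genetic) == 1
        assert np.allclose(classical.X, social.X)
        assert (classical.genetic[0].Z != social.genetic[0].Z).nnz == 0

    def test_missing_pedigree_link_raises(self):
        ped, data = small_dataset()
        data = data.copy()
        data.loc[0, "animal"] = 999
        with pytest.raises(MMEError, match="missing from pedigree"):
            build_design(data, ModelSpec(), ped)

    def test_age_centred(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(), ped)
        age_col = design.X[:, -1]
        assert age_col.mean() == pytest.approx(0.0, abs=1e-12)


class TestAssembleSolve:
    def test_system_symmetric(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model="social"), ped)
        system = assemble_mme(design, VC, a_inverse(ped))
        assert np.abs(system.C - system.C.T).max() < 1e-12

    def test_matches_dense_solve(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model="social"), ped)
        system = assemble_mme(design, VC, a_inverse(ped))
        sol = solve_mme(system)
        dense = np.linalg.solve(system.C, system.rhs)
        assert np.abs(sol.sol - dense).max() < 1e-10

    def test_inverse_blocks_returned(self):
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model="classical"), ped)
        system = assemble_mme(design, VC1, a_inverse(ped))
        sol = solve_mme(system, compute_inverse=True)
        assert np.abs(sol.c_inv - np.linalg.inv(system.C)).max() < 1e-9

    def test_record_permutation_invariance(self):
        ped, data = small_dataset()
        perm = data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        spec = ModelSpec(model="social")
        ebv1 = estimate_breeding_values(data, spec, VC, a_inverse(ped), ped)
        ebv2 = estimate_breeding_values(perm, spec, VC, a_inverse(ped), ped)
        assert np.allclose(ebv1["dbv"], ebv2["dbv"], atol=1e-10)
        assert np.allclose(ebv1["sbv"], ebv2["sbv"], atol=1e-10)

    def test_singular_fixed_effects_reported(self):
        ped, data = small_dataset()
        data = data.copy()
        data["line"] = data["scorer"].map({1: "A", 2: "B"})  # aliased
        design = build_design(data, ModelSpec(model="classical"), ped)
        with pytest.raises(MMEError, match="aliased"):
            solve_mme(assemble_mme(design, VC1, a_inverse(ped)))


def marginal_covariance(design, vc, A):
    """Dense V = Z G Z' + R for the GLS oracle."""
    Zg = [t.Z.toarray() for t in design.genetic]
    Zi = [t.Z.toarray() for t in design.iid]
    G = np.kron(vc.genetic_matrix(), A) if vc.is_social \
        else vc.sigma2_ud * A
    Z = np.hstack(Zg + Zi)
    Gbig = sla.block_diag(
        G, vc.sigma2_gr * np.eye(Zi[0].shape[1]),
        vc.sigma2_cl * np.eye(Zi[1].shape[1]),
        vc.sigma2_cg * np.eye(Zi[2].shape[1]))
    return Z @ Gbig @ Z.T + vc.sigma2_e * np.eye(design.n_records), Gbig, Z


class TestGLSEquivalence:
    @pytest.mark.parametrize("model, vc", [("classical", VC1), ("social", VC)])
    def test_blup_equals_gls(self, model, vc):
        """Henderson solutions reproduce GLS fixed effects and
        G Z' V^-1 (y - Xb) random effects on the marginal covariance."""
        ped, data = small_dataset()
        design = build_design(data, ModelSpec(model=model), ped)
        sol = solve_mme(assemble_mme(design, vc, a_inverse(ped)))
        V, Gbig, Z = marginal_covariance(design, vc, a_matrix(ped))
        Vi = np.linalg.inv(V)
        X, y = design.X, design.y
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = Gbig @ Z.T @ Vi @ (y - X @ beta)
        assert np.abs(sol.sol[:design.p] - beta).max() < 1e-8
        assert np.abs(sol.sol[design.p:] - u).max() < 1e-8


class TestEstimateBreedingValues:
    def test_equal_phenotypes_give_zero_ebv(self):
        ped, data = small_dataset()
        data = data.copy()
        data["y"] = 200.0
        ebv = estimate_breeding_values(data, ModelSpec(model="social"), VC,
                                       a_inverse(ped), ped)
        assert np.abs(ebv["dbv"]).max() < 1e-10
        assert np.abs(ebv["sbv"]).max() < 1e-10

    def test_covers_all_pedigree_animals(self):
        ped, data = small_dataset()
        ebv = estimate_breeding_values(data, ModelSpec(model="social"), VC,
                                       a_inverse(ped), ped)
        assert set(ebv["animal"]) == set(ped.ids)
        assert ebv["n_pen"].isna().sum() == 4  # the four ancestors

    def test_hinv_without_genotyped_equals_pedigree_blup(self):
        ped, data = small_dataset()
        Ainv = a_inverse(ped)
        Hinv = h_inverse(Ainv, np.empty((0, 0)), np.array([], dtype=int))
        spec = ModelSpec(model="social")
        e1 = estimate_breeding_values(data, spec, VC, Ainv, ped)
        e2 = estimate_breeding_values(data, spec, VC, Hinv, ped)
        assert np.abs(e1["dbv"] - e2["dbv"]).max() < 1e-10

    def test_social_fit_on_classical_data_tracks_classical(self,
                                                           liability_world):
        """With no social variance in the data the social model's direct
        EBVs nearly coincide with the classical model's."""
        from igeblup.syndata import (simulate_phenotypes,
                                     simulate_true_breeding_values)
        w = liability_world
        cfg = w.config.with_(true_varcomp=social_components(
            14.21, 1e-6, 68.84, 8.60, 15.79, 284.3, r_uds=0.0))
        effects = simulate_true_breeding_values(w.pedigree, cfg.true_varcomp,
                                                seed=cfg.seed)
        data = simulate_phenotypes(effects, w.pens, cfg, w.pedigree)
        data["y"] = data["score"]
        Ainv = a_inverse(w.pedigree)
        vc_s = social_components(14.21, 0.05, 68.84, 8.60, 15.79, 284.3, 0.0)
        vc_c = VarianceComponents(14.21, None, None, 68.84, 8.60, 15.79,
                                  284.3, model="classical")
        dbv_s = estimate_breeding_values(
            data, ModelSpec(model="social"), vc_s, Ainv, w.pedigree)["dbv"]
        dbv_c = estimate_breeding_values(
            data, ModelSpec(model="classical"), vc_c, Ainv, w.pedigree)["dbv"]
        phenotyped = np.isin(w.pedigree.ids, data["animal"])
        corr = np.corrcoef(dbv_s[phenotyped], dbv_c[phenotyped])[0, 1]
        assert corr > 0.99
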