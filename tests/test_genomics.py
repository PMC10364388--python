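import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from igeblup.genomics import (
    GenotypeError, GenotypeMatrix, QCThresholds, blend,
    build_genomic_matrices, center_dosages, g_matrix, h_inverse,
    hwe_chi2_pvalues, impute_missing, qc_genotypes,
)
from igeblup.pedigree import a22, a_inverse, a_matrix
from .conftest import make_pedigree, random_pedigree


def _geno(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_map = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": range(1, m + 1),
    })
    return GenotypeMatrix(ids=np.arange(1, n + 1), dosages=dosages,
                          snp_map=snp_map)


class TestQC:
    def test_low_maf_removed_threshold_kept(self):
        n = 50
        rare = np.zeros(n); rare[:4] = 1          # freq 0.04 -> removed
        exact = np.zeros(n); exact[:5] = 1        # freq 0.05 -> kept (strict <)
        common = np.ones(n)                       # freq 0.5 -> kept
        common[::2] = 0
        geno = _geno(np.column_stack([rare, exact, common]))
        qc, report = qc_genotypes(geno)
        assert list(qc.snp_map["snp"]) == ["s1", "s2"]
        assert report.loc[report.criterion == "maf", "n_snps"].iloc[0] == 1

    def test_low_call_rate_removed(self):
        n = 100
        good = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        bad = good.copy(); bad[:6] = np.nan       # 94% call rate
        qc, _ = qc_genotypes(_geno(np.column_stack([good, bad])))
        assert list(qc.snp_map["snp"]) == ["s0"]

    def test_hwe_outlier_removed(self):
        # (AA, AB, BB) = (50, 0, 50): chi-square = n = 100, p << 1e-7
        col = np.array([0.0] * 50 + [2.0] * 50)
        ok = np.tile([0.0, 1.0, 1.0, 2.0], 25)
        geno = _geno(np.column_stack([col, ok]))
        p = hwe_chi2_pvalues(geno.dosages)
        assert p[0] == pytest.approx(chi2.sf(100.0, df=1))
        qc, report = qc_genotypes(geno)
        assert list(qc.snp_map["snp"]) == ["s1"]
        assert report.loc[report.criterion == "hwe", "n_snps"].iloc[0] == 1

    def test_sex_chromosome_removed(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], (1, 25)).reshape(25, 4).T
        geno = _geno(np.tile([0.0, 1.0, 2.0, 1.0], (3, 25)).T.reshape(100, 3),
                     chrom=[1, 2, 19])
        qc, _ = qc_genotypes(geno, QCThresholds(sex_chromosomes=(19,)))
        assert 19 not in qc.snp_map["chrom"].values

    def test_joint_counts_union_of_criteria(self):
        """Criteria are evaluated on the raw matrix, not sequentially."""
        n = 100
        rng = np.random.default_rng(0)
        ok = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        rare = np.zeros(n); rare[:2] = 1
        sparse_col = ok[:, 0].copy(); sparse_col[:10] = np.nan
        geno = _geno(np.column_stack([ok, rare, sparse_col]))
        qc, report = qc_genotypes(geno)
        counts = report.set_index("criterion")["n_snps"]
        assert counts["total_removed"] == counts["maf"] + counts["call_rate"]
        assert counts["kept"] == 5

    def test_all_removed_raises(self):
        with pytest.raises(GenotypeError):
            qc_genotypes(_geno(np.zeros((20, 2))))


class TestImpute:
    def test_identity_without_missing(self):
        geno = _geno(np.tile([0.0, 1.0, 2.0, 1.0], (3, 25)).T.reshape(100, 3))
        lines = pd.Series("L1", index=geno.ids)
        assert np.array_equal(impute_missing(geno, lines).dosages,
                              geno.dosages)

    def test_line_frequency_fill(self):
        d = np.array([[0.0, 2.0], [1.0, 0.0], [0.0, np.nan], [1.0, 1.0]])
        lines = pd.Series(["A", "A", "B", "B"], index=[1, 2, 3, 4])
        out = impute_missing(_geno(d), lines)
        # line B freq at SNP 2 from animal 4 only: 1/2 -> dosage 1.0
        assert out.dosages[2, 1] == pytest.approx(1.0)

    def test_quarter_frequency_gives_half_dosage(self):
        d = np.array([[0.0], [1.0], [1.0], [0.0], [np.nan]])
        lines = pd.Series("A", index=range(1, 6))
        out = impute_missing(_geno(d), lines)
        assert out.dosages[4, 0] == pytest.approx(0.5)

    def test_line_means_preserved(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, size=(40, 6)).astype(float)
        mask = rng.random(d.shape) < 0.1
        dm = d.copy(); dm[mask] = np.nan
        lines = pd.Series(np.repeat(["A", "B"], 20), index=range(1, 41))
        out = impute_missing(_geno(dm), lines)
        for ln in ("A", "B"):
            rows = (lines == ln).to_numpy()
            with np.errstate(invalid="ignore"):
                observed = np.nanmean(dm[rows], axis=0)
            imputed = out.dosages[rows].mean(axis=0)
            ok = ~np.isnan(observed)
            assert np.allclose(imputed[ok], observed[ok], atol=1e-12)

    def test_empty_line_falls_back_pooled(self):
        d = np.array([[2.0], [2.0], [np.nan]])
        lines = pd.Series(["A", "A", "B"], index=[1, 2, 3])
        with pytest.warns(UserWarning, match="pooled"):
            out = impute_missing(_geno(d), lines)
        assert out.dosages[2, 0] == pytest.approx(2.0)


class TestGMatrix:
    def test_hand_example_two_animals_one_snp(self):
        G = g_matrix(_geno([[0.0], [2.0]]))
        assert np.allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicated_animal_rows_identical(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(6, 30)).astype(float)
        d[5] = d[0]
        G = g_matrix(_geno(d))
        assert np.allclose(G[5], G[0])
        assert np.allclose(G[:, 5], G[:, 0])

    def test_monomorphic_panel_raises(self):
        with pytest.raises(GenotypeError, match="monomorphic"):
            g_matrix(_geno(np.full((4, 3), 2.0)))

    def test_mean_diagonal_tracks_inbreeding(self, tiny_world):
        """On gene-dropped data, mean diag(G) ~ 1 + mean F of the
        genotyped animals (allele frequencies from the same set)."""
        from igeblup.genomics import impute_missing as imp
        from igeblup.pedigree import inbreeding
        geno = tiny_world.genotypes
        lines = tiny_world.pedigree.table.set_index("animal")["line"]
        qc, _ = qc_genotypes(geno)
        full = imp(qc, lines)
        G = g_matrix(full)
        ped = tiny_world.pedigree
        fbar = inbreeding(ped)[ped.positions_of(geno.ids)].mean()
        assert np.mean(np.diag(G)) == pytest.approx(1.0 + fbar, abs=0.12)


class TestBlendAndHInverse:
    def test_blend_identities(self):
        A22 = np.array([[1.0, 0.2], [0.2, 1.0]])
        G = np.array([[1.4, 0.1], [0.1, 0.9]])
        assert np.allclose(blend(A22, A22), A22)
        assert np.allclose(blend(G, A22, weight=0.0), G)

    def test_blend_fixes_singularity(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.4, size=(4, 40)).astype(float)
        d[3] = d[0]  # duplicated animal -> singular G
        G = g_matrix(_geno(d))
        assert np.linalg.matrix_rank(G) < 4
        Gb = blend(G, np.eye(4), weight=0.05)
        assert np.isfinite(np.linalg.cond(Gb))
        assert np.linalg.eigvalsh(Gb).min() > 0

    def test_empty_genotyped_set_returns_ainv(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        Ainv = a_inverse(ped)
        Hinv = h_inverse(Ainv, np.empty((0, 0)), np.array([], dtype=int))
        assert np.allclose(Hinv.toarray(), Ainv.toarray())

    def test_gblend_equal_a22_returns_ainv(self):
        rng = np.random.default_rng(9)
        ped = random_pedigree(rng, 30)
        genotyped = [10, 20, 30]
        A22, A22i = a22(ped, genotyped)
        Ainv = a_inverse(ped)
        Hinv = h_inverse(Ainv, np.linalg.inv(A22) - A22i,
                         ped.positions_of(genotyped))
        assert np.abs(Hinv.toarray() - Ainv.toarray()).max() < 1e-10

    def test_dense_joint_h_oracle(self):
        """H^-1 equals the inverse of H built by the conditional
        construction on the genotyped block."""
        rng = np.random.default_rng(10)
        ped = random_pedigree(rng, 60)
        genotyped = list(range(41, 61))
        gpos = ped.positions_of(genotyped)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 50),
                         size=(20, 50)).astype(float)
        gm = build_genomic_matrices(_geno(d), *a22(ped, genotyped))
        A = a_matrix(ped)
        npos = np.setdiff1d(np.arange(60), gpos)
        A11, A12 = A[np.ix_(npos, npos)], A[np.ix_(npos, gpos)]
        A22m, Gb = gm.A22, gm.G_blend
        A22i = np.linalg.inv(A22m)
        H = np.zeros_like(A)
        H[np.ix_(npos, npos)] = A11 + A12 @ A22i @ (Gb - A22m) @ A22i @ A12.T
        H[np.ix_(npos, gpos)] = A12 @ A22i @ Gb
        H[np.ix_(gpos, npos)] = Gb @ A22i @ A12.T
        H[np.ix_(gpos, gpos)] = Gb
        Hinv = h_inverse(a_inverse(ped), gm.hinv_correction, gpos)
        assert np.abs(Hinv.toarray() - np.linalg.inv(H)).max() < 1e-8

    def test_center_dosages_scale(self):
        d = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 2.0], [1.0, 0.0]])
        M, p, scale = center_dosages(_geno(d))
        assert np.allclose(p, [0.5, 0.5])
        assert scale == pytest.approx(1.0)
        assert np.allclose(M.mean(axis=0), 0.0)
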