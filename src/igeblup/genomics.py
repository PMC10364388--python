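"""Genotype QC, genomic relationship matrices and single-step H inverse.

The genomic relationship follows VanRaden's first method,
``G = MM' / (2 * sum_j p_j (1 - p_j))`` with dosages centred by twice
the allele frequency observed in the genotyped set.  ``G`` is blended
with a small share of the pedigree relationships among genotyped
animals (``A22``) before inversion, and enters the mixed-model
equations through

    H^-1 = A^-1 + [0 0; 0 G_blend^-1 - A22^-1]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """SNP dosages (rows = animals, columns = SNPs) with a physical map.

    ``dosages`` are in {0, 1, 2} with ``NaN`` for missing calls before
    imputation; real-valued dosages are allowed after imputation.
    """

    ids: np.ndarray
    dosages: np.ndarray
    snp_map: pd.DataFrame  # columns snp, chrom, pos
    freqs: np.ndarray | None = None  # per-SNP allele frequency after QC

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.ids), len(self.snp_map)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snp_map)} SNPs")
        m = self.snp_map
        key = m[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"])):
            raise GenotypeError("SNP map must be sorted by (chrom, pos)")
        if m.groupby("chrom")["pos"].apply(
                lambda s: (s.diff().dropna() <= 0).any()).any():
            raise GenotypeError("positions must strictly increase within chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def observed_freqs(self) -> np.ndarray:
        """Allele frequency per SNP from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)


@dataclass
class QCThresholds:
    """Exclusion rules; strict inequalities, so a SNP exactly at a
    threshold is kept."""

    maf: float = 0.05
    call_rate: float = 0.95
    hwe_p: float = 1e-7
    sex_chromosomes: tuple = ()


def hwe_chi2_pvalues(dosages: np.ndarray) -> np.ndarray:
    """One-degree-of-freedom Hardy-Weinberg chi-square test per SNP."""
    n0 = np.nansum(dosages == 0, axis=0).astype(float)
    n1 = np.nansum(dosages == 1, axis=0).astype(float)
    n2 = np.nansum(dosages == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.stack([n0, n1, n2])
        stat = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0
                        ).sum(axis=0)
    stat = np.where(n > 0, stat, 0.0)
    return chi2.sf(stat, df=1)


def qc_genotypes(
    raw: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Joint SNP filtering on MAF, call rate, HWE and sex chromosomes.

    All criteria are evaluated on the raw matrix, so the outcome does
    not depend on the order of application.  Animals are never removed.
    Returns the filtered matrix and a per-criterion report.
    """
    th = thresholds or QCThresholds()
    freq = raw.observed_freqs()
    maf = np.minimum(freq, 1 - freq)
    call = raw.call_rate()
    hwe = hwe_chi2_pvalues(raw.dosages)
    on_sex = raw.snp_map["chrom"].isin(th.sex_chromosomes).to_numpy()
    fail_maf = maf < th.maf
    fail_call = call < th.call_rate
    fail_hwe = hwe < th.hwe_p
    drop = fail_maf | fail_call | fail_hwe | on_sex
    report = pd.DataFrame({
        "criterion": ["maf", "call_rate", "hwe", "sex_chromosome", "total_removed",
                      "kept"],
        "n_snps": [int(fail_maf.sum()), int(fail_call.sum()), int(fail_hwe.sum()),
                   int(on_sex.sum()), int(drop.sum()), int((~drop).sum())],
    })
    if drop.all():
        raise GenotypeError("quality control removed every SNP")
    keep = ~drop
    return (
        GenotypeMatrix(
            ids=raw.ids.copy(),
            dosages=raw.dosages[:, keep].copy(),
            snp_map=raw.snp_map.loc[keep].reset_index(drop=True),
        ),
        report,
    )


def impute_missing(qc: GenotypeMatrix, lines: pd.Series | dict) -> GenotypeMatrix:
    """Replace missing dosages by twice the within-line allele frequency.

    ``lines`` maps animal id to line label.  A line with no observed
    call at a SNP falls back to the pooled frequency with a warning.
    Deterministic; real-valued dosages result.
    """
    lines = pd.Series(lines)
    labels = np.asarray([lines[a] for a in qc.ids])
    out = qc.dosages.copy()
    pooled = qc.observed_freqs()
    fallback = 0
    for ln in pd.unique(labels):
        rows = labels == ln
        block = out[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            line_freq = np.nanmean(block, axis=0) / 2.0
        empty = np.isnan(line_freq)
        fallback += int((empty & miss.any(axis=0)).sum())
        line_freq[empty] = pooled[empty]
        fill = np.broadcast_to(2.0 * line_freq, block.shape)
        block[miss] = fill[miss]
        out[rows] = block
    if fallback:
        warnings.warn(
            f"{fallback} SNP/line cells had no observed call; pooled "
            "frequency used", stacklevel=2)
    if np.isnan(out).any():
        raise GenotypeError("missing dosages remain after imputation")
    return GenotypeMatrix(ids=qc.ids.copy(), dosages=out,
                          snp_map=qc.snp_map.copy())


def center_dosages(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Centred dosage matrix M, allele frequencies and VanRaden scale.

    Frequencies are computed from the genotyped set itself; the scale is
    ``2 * sum_j p_j (1 - p_j)``, the denominator of G and the ratio
    between total genetic variance and per-SNP variance.
    """
    p = geno.dosages.mean(axis=0) / 2.0
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise GenotypeError("all SNPs monomorphic: VanRaden denominator is zero")
    M = geno.dosages - 2.0 * p
    return M, p, scale


def g_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix from imputed, QC'd dosages."""
    M, _, scale = center_dosages(geno)
    return (M @ M.T) / scale


def blend(G: np.ndarray, A22: np.ndarray, weight: float = 0.05) -> np.ndarray:
    """``(1 - weight) * G + weight * A22``; guards against singular G."""
    if G.shape != A22.shape:
        raise GenotypeError(f"G {G.shape} and A22 {A22.shape} are not conformable")
    return (1.0 - weight) * G + weight * A22


@dataclass
class GenomicMatrices:
    """G, its blended version and the H-inverse correction block."""

    G: np.ndarray
    G_blend: np.ndarray
    A22: np.ndarray
    A22_inv: np.ndarray
    hinv_correction: np.ndarray = field(repr=False)
    blend_weight: float = 0.05


def build_genomic_matrices(
    geno: GenotypeMatrix, A22: np.ndarray, A22_inv: np.ndarray,
    weight: float = 0.05,
) -> GenomicMatrices:
    G = g_matrix(geno)
    Gb = blend(G, A22, weight)
    try:
        Gb_inv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as err:
        raise GenotypeError(
            f"blended G not invertible ({err}); increase the blending weight"
        ) from err
    return GenomicMatrices(
        G=G, G_blend=Gb, A22=A22, A22_inv=A22_inv,
        hinv_correction=Gb_inv - A22_inv, blend_weight=weight,
    )


def h_inverse(
    Ainv: sp.spmatrix, correction: np.ndarray, genotyped_pos: np.ndarray,
    n: int | None = None,
) -> sp.csr_matrix:
    """Single-step ``H^-1``: pedigree inverse plus the genomic correction.

    ``correction`` is ``G_blend^-1 - A22^-1`` in the order of
    ``genotyped_pos`` (row/column positions of genotyped animals within
    the pedigree ordering).  Sparse outside the genotyped block.
    """
    n = n or Ainv.shape[0]
    genotyped_pos = np.asarray(genotyped_pos, dtype=np.int64)
    if len(genotyped_pos) == 0:
        return sp.csr_matrix(Ainv)
    if correction.shape != (len(genotyped_pos), len(genotyped_pos)):
        raise GenotypeError("correction block does not match genotyped set")
    rows = np.repeat(genotyped_pos, len(genotyped_pos))
    cols = np.tile(genotyped_pos, len(genotyped_pos))
    corr = sp.coo_matrix((correction.ravel(), (rows, cols)), shape=(n, n))
    return (Ainv.tocsr() + corr.tocsr()).tocsr()
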