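"""Single-step GWAS by backsolving SNP effects from genomic EBVs.

Genotyped animals' (G)EBVs ``u`` are converted to SNP effects through

    a = (sigma2_a / sigma2_u) M' G_blend^-1 u,

the VanRaden/Strandén-Garrick backsolving identity, where ``M`` holds
centred dosages.  By default ``sigma2_a = sigma2_u / (2 sum p_j(1-p_j))``
so the leading ratio is the VanRaden scaling constant.  Standard errors
propagate the covariance of the GEBVs (``Var(u) = G_blend*sigma2_u -
PEV``) through the same linear map, p-values are two-sided normal, and
significance is Bonferroni-corrected (0.05/m).  Variance explained is
summarised over windows of 20 adjacent SNPs within a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


class GwasError(ValueError):
    pass


@dataclass
class GwasResult:
    snps: pd.DataFrame            # snp, chrom, pos, effect, sd, pvalue
    windows: pd.DataFrame         # chrom, start/end indices + positions, pct_var
    threshold: float              # Bonferroni-corrected p-value cutoff
    component: str                # "direct" or "social"
    model: str
    window_size: int = 20
    meta: dict = field(default_factory=dict)


def backsolve_snp_effects(
    u_hat: np.ndarray,
    G_blend: np.ndarray,
    M: np.ndarray,
    sigma2_u: float,
    sigma2_a: float | None = None,
    vanraden_scale: float | None = None,
) -> np.ndarray:
    """SNP effects from genotyped-animal (G)EBVs.

    ``M`` must be the centred dosage matrix in the same animal order as
    ``G_blend`` and ``u_hat``.  If ``sigma2_a`` is omitted it defaults
    to ``sigma2_u / vanraden_scale`` with ``vanraden_scale =
    2 sum p_j (1 - p_j)``.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if M.shape[0] != len(u_hat) or G_blend.shape != (len(u_hat), len(u_hat)):
        raise GwasError(
            f"misaligned inputs: M {M.shape}, G {G_blend.shape}, "
            f"u {u_hat.shape}")
    if sigma2_a is None:
        if vanraden_scale is None:
            raise GwasError("provide sigma2_a or vanraden_scale")
        sigma2_a = sigma2_u / vanraden_scale
    w = np.linalg.solve(G_blend, u_hat)
    return (sigma2_a / sigma2_u) * (M.T @ w)


def snp_standard_errors(
    var_u_hat: np.ndarray,
    G_blend: np.ndarray,
    M: np.ndarray,
    sigma2_u: float,
    sigma2_a: float | None = None,
    vanraden_scale: float | None = None,
) -> np.ndarray:
    """sd(a_i) via the same linear map applied to ``Var(u)``.

    ``var_u_hat`` is the covariance of the GEBVs among genotyped
    animals, typically ``G_blend*sigma2_u - PEV`` with the PEV block
    taken from the MME coefficient-matrix inverse.
    """
    if sigma2_a is None:
        if vanraden_scale is None:
            raise GwasError("provide sigma2_a or vanraden_scale")
        sigma2_a = sigma2_u / vanraden_scale
    B = np.linalg.solve(G_blend, M)          # G^-1 M, n x m
    quad = np.einsum("ij,ij->j", B, var_u_hat @ B)
    c = sigma2_a / sigma2_u
    var_a = c**2 * quad
    bad = var_a <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} SNPs with non-positive effect "
                      "variance; p-values reported missing", stacklevel=2)
    sd = np.sqrt(np.where(bad, np.nan, var_a))
    return sd


def snp_pvalues(a_hat: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values ``2(1 - Phi(|a/sd|))``."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(np.asarray(a_hat) / np.asarray(sd))
    return 2.0 * norm.sf(z)


def gebv_covariance(
    c_inv_block: np.ndarray, G_blend: np.ndarray, sigma2_u: float,
    ignore_pev: bool = False,
) -> np.ndarray:
    """``Var(u) = G_blend sigma2_u - PEV`` for the genotyped animals.

    ``c_inv_block`` is the prediction-error (co)variance block of the
    MME inverse restricted to the genotyped animals' equations of one
    genetic component.  ``ignore_pev=True`` gives the naive
    ``G_blend*sigma2_u`` alternative for sensitivity analysis.
    """
    if ignore_pev:
        return G_blend * sigma2_u
    return G_blend * sigma2_u - c_inv_block


def window_variance(
    a_hat: np.ndarray,
    M: np.ndarray,
    snp_map: pd.DataFrame,
    sigma2_u: float,
    window: int = 20,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Percentage of genetic variance explained per SNP window.

    For each window the genomic term ``M_w a_w`` is formed over the
    genotyped animals; its variance divided by ``sigma2_u`` (x100) is
    the window's share.  Sliding windows move one SNP at a time within
    a chromosome (truncated end windows dropped); ``mode='disjoint'``
    tiles the chromosome instead.
    """
    if mode not in ("sliding", "disjoint"):
        raise GwasError(f"unknown window mode {mode!r}")
    rows = []
    for chrom, sub in snp_map.reset_index(drop=True).groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < window:
            warnings.warn(f"chromosome {chrom} has fewer than {window} SNPs; "
                          "skipped", stacklevel=2)
            continue
        starts = (range(0, len(idx) - window + 1)
                  if mode == "sliding"
                  else range(0, len(idx) - window + 1, window))
        for s in starts:
            cols = idx[s:s + window]
            term = M[:, cols] @ a_hat[cols]
            pct = 100.0 * float(np.var(term, ddof=1)) / sigma2_u
            rows.append({
                "chrom": chrom,
                "start_snp": snp_map["snp"].iloc[cols[0]],
                "end_snp": snp_map["snp"].iloc[cols[-1]],
                "start_pos": int(snp_map["pos"].iloc[cols[0]]),
                "end_pos": int(snp_map["pos"].iloc[cols[-1]]),
                "pct_var": pct,
            })
    return pd.DataFrame(rows)


def significance_threshold(m: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-SNP significance level ``alpha/m``."""
    if m < 1:
        raise GwasError("at least one SNP is required")
    return alpha / m


def run_gwas(
    u_hat: np.ndarray,
    G_blend: np.ndarray,
    M: np.ndarray,
    snp_map: pd.DataFrame,
    sigma2_u: float,
    var_u_hat: np.ndarray,
    vanraden_scale: float,
    component: str = "direct",
    model: str = "social",
    window: int = 20,
    alpha: float = 0.05,
) -> GwasResult:
    """Full backsolving GWAS for one genetic component."""
    a_hat = backsolve_snp_effects(u_hat, G_blend, M, sigma2_u,
                                  vanraden_scale=vanraden_scale)
    sd = snp_standard_errors(var_u_hat, G_blend, M, sigma2_u,
                             vanraden_scale=vanraden_scale)
    pvals = snp_pvalues(a_hat, sd)
    snps = snp_map.copy()
    snps["effect"] = a_hat
    snps["sd"] = sd
    snps["pvalue"] = pvals
    windows = window_variance(a_hat, M, snp_map, sigma2_u, window=window)
    return GwasResult(
        snps=snps, windows=windows,
        threshold=significance_threshold(len(snp_map), alpha),
        component=component, model=model, window_size=window,
    )


def manhattan_table(result: GwasResult) -> pd.DataFrame:
    """Plot-ready table: cumulative coordinate, -log10(p), threshold."""
    snps = result.snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    offset = 0
    coords = np.empty(len(snps))
    for chrom, sub in snps.groupby("chrom", sort=True):
        coords[sub.index] = offset + sub["pos"].to_numpy()
        offset += int(sub["pos"].max()) + 1
    out = snps.copy()
    out["genome_pos"] = coords
    with np.errstate(divide="ignore", invalid="ignore"):
        out["neg_log10_p"] = -np.log10(out["pvalue"])
    out.attrs["threshold_line"] = -np.log10(result.threshold)
    return out


def manhattan_plot(result: GwasResult, path: str) -> None:
    """Save a Manhattan plot (chromosomes on x, -log10 p on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = manhattan_table(result)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for k, (chrom, sub) in enumerate(tab.groupby("chrom", sort=True)):
        ax.scatter(sub["genome_pos"], sub["neg_log10_p"], s=4,
                   color=["#3b5b92", "#8aa2c8"][k % 2])
    ax.axhline(tab.attrs["threshold_line"], color="red", lw=0.8)
    ax.set_xlabel("chromosome position")
    ax.set_ylabel("-log10(p)")
    ax.set_title(f"{result.component} SNP effects ({result.model} model)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
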