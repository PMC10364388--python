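"""Derived genetic parameters for socially affected traits.

For a trait recorded on groups of ``N`` pen mates the heritable
variance available to selection is the variance of total breeding
values ``TBV = u_D + (N - 1) u_S``:

    sigma2_TBV = sigma2_uD + 2 (Nbar-1) sigma_uDS + (Nbar-1)^2 sigma2_uS

and the phenotypic variance under average pen-mate relationship ``r``:

    sigma2_P_DS = sigma2_uD
                  + (Nbar-1) r [2 sigma_uDS + (Nbar-2) sigma2_uS]
                  + (Nbar-1) sigma2_uS
                  + sigma2_gr + sigma2_cl + sigma2_cg + sigma2_e

``T2 = sigma2_TBV / sigma2_P_DS`` generalises the classical
heritability ``h2 = sigma2_uD / sigma2_P_D`` and collapses to it when
the social variance and covariance vanish.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import VarianceComponents

DEFAULT_NBAR = 10.7  # population mean pen-group size used when N is unknown


class ParameterError(ValueError):
    pass


@dataclass
class DerivedParams:
    h2: float | None
    t2: float | None
    sigma2_tbv: float | None
    sigma2_p_d: float | None
    sigma2_p_ds: float | None
    r_uds: float | None
    n_bar: float | None
    r: float | None


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """Classical heritability and the direct phenotypic variance."""
    sigma2_p = (vc.sigma2_ud + vc.sigma2_gr + vc.sigma2_cl + vc.sigma2_cg
                + vc.sigma2_e)
    if sigma2_p <= 0:
        raise ParameterError("phenotypic variance must be positive")
    return vc.sigma2_ud / sigma2_p, sigma2_p


def sigma_tbv(vc: VarianceComponents, n_bar: float) -> float:
    """Total heritable variance at mean pen-group size ``n_bar``."""
    if not vc.is_social:
        raise ParameterError("sigma2_TBV requires social-model components")
    if n_bar < 1:
        raise ParameterError("n_bar must be at least 1")
    k = n_bar - 1.0
    return vc.sigma2_ud + 2.0 * k * vc.sigma_uds + k**2 * vc.sigma2_us


def sigma_p_ds(vc: VarianceComponents, n_bar: float, r: float) -> float:
    """Phenotypic variance under the social model."""
    if not vc.is_social:
        raise ParameterError("sigma2_P_DS requires social-model components")
    if n_bar < 2:
        raise ParameterError("n_bar must be at least 2")
    if not 0 <= r <= 2:
        raise ParameterError("pen-mate relationship r must be in [0, 2]")
    k = n_bar - 1.0
    out = (vc.sigma2_ud
           + k * r * (2.0 * vc.sigma_uds + (n_bar - 2.0) * vc.sigma2_us)
           + k * vc.sigma2_us
           + vc.sigma2_gr + vc.sigma2_cl + vc.sigma2_cg + vc.sigma2_e)
    if out <= 0:
        raise ParameterError(f"non-positive phenotypic variance {out:.4g}")
    return out


def t_squared(vc: VarianceComponents, n_bar: float, r: float) -> float:
    """Total heritable variance relative to the phenotypic variance."""
    return sigma_tbv(vc, n_bar) / sigma_p_ds(vc, n_bar, r)


def genetic_correlation(vc: VarianceComponents) -> float:
    """Correlation between direct and social genetic effects."""
    if not vc.is_social:
        raise ParameterError("correlation requires social-model components")
    denom = math.sqrt(vc.sigma2_ud * vc.sigma2_us)
    if denom == 0:
        warnings.warn("zero genetic variance: r_uDS undefined", stacklevel=2)
        return math.nan
    r = vc.sigma_uds / denom
    if abs(r) > 1.0 + 1e-8:
        raise ParameterError(f"r_uDS={r:.6g} outside [-1, 1]")
    return float(np.clip(r, -1.0, 1.0))


def derived_params(
    vc: VarianceComponents, n_bar: float | None = None, r: float | None = None,
) -> DerivedParams:
    """All derived parameters the fitted model admits."""
    if vc.is_social:
        return DerivedParams(
            h2=None,
            t2=t_squared(vc, n_bar, r),
            sigma2_tbv=sigma_tbv(vc, n_bar),
            sigma2_p_d=None,
            sigma2_p_ds=sigma_p_ds(vc, n_bar, r),
            r_uds=genetic_correlation(vc),
            n_bar=n_bar, r=r,
        )
    h2, sp_d = heritability(vc)
    return DerivedParams(h2=h2, t2=None, sigma2_tbv=None, sigma2_p_d=sp_d,
                         sigma2_p_ds=None, r_uds=None, n_bar=n_bar, r=r)


def total_breeding_values(
    ebv: pd.DataFrame, n_bar: float = DEFAULT_NBAR,
) -> pd.DataFrame:
    """Add ``tbv = dbv + (N - 1) sbv`` to a social-model EBV table.

    ``N`` is the animal's own pen size (``n_pen`` column); animals
    without a pen (sires, other ancestors) fall back to the population
    mean ``n_bar``.
    """
    if "sbv" not in ebv.columns:
        raise ParameterError("TBV requires social breeding values")
    out = ebv.copy()
    n = out["n_pen"].fillna(n_bar) if "n_pen" in out.columns else n_bar
    out["tbv"] = out["dbv"] + out["sbv"] * (n - 1.0)
    return out
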