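"""Forward validation of breeding values by the LR (linear regression) method.

Breeding values are estimated twice: with the complete data and with a
partial data set truncated at a cutoff date (phenotypes after the
cutoff masked; pedigree and genotypes retained).  Over a validation
group the method reports

    accuracy   = sqrt( cov(EBV_p, EBV_c) / ((1 - Fbar) sigma2_u) )
    bias       = mean(EBV_p) - mean(EBV_c)
    dispersion = cov(EBV_c, EBV_p) / var(EBV_p)

with ``sigma2_u`` the genetic variance matching the EBV kind (direct,
social, or total) and ``Fbar`` the mean pedigree inbreeding of the
validation animals.  Covariances use the n-1 denominator throughout.
Standard errors come from bootstrapping the validation animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LRStatistics:
    kind: str
    accuracy: float
    bias: float
    dispersion: float
    n: int
    f_bar: float
    sigma2_u: float


def split_partial(data: pd.DataFrame, cutoff: str) -> pd.DataFrame:
    """Phenotype records scored on or before ``cutoff`` (ISO date).

    Only phenotypes are masked; callers keep using the full pedigree
    and genotypes with the reduced table.
    """
    dates = pd.to_datetime(data["date"])
    cut = pd.Timestamp(cutoff)
    keep = dates <= cut
    if keep.all():
        warnings.warn("cutoff after every record: partial equals complete",
                      stacklevel=2)
    if not keep.any():
        warnings.warn("cutoff before every record: partial set is empty",
                      stacklevel=2)
    return data[keep].reset_index(drop=True)


def select_validation_sires(
    ped_table: pd.DataFrame, data: pd.DataFrame, cutoff: str,
    min_progeny: int = 10,
) -> list:
    """Young sires: >= ``min_progeny`` phenotyped progeny after the
    cutoff and none before it."""
    sire_of = ped_table.set_index("animal")["sire"]
    dates = pd.to_datetime(data["date"])
    cut = pd.Timestamp(cutoff)
    sires = data["animal"].map(sire_of)
    after = sires[dates > cut].value_counts()
    before = sires[dates <= cut].value_counts()
    chosen = [
        int(s) for s, k in after.items()
        if s != 0 and k >= min_progeny and before.get(s, 0) == 0
    ]
    if not chosen:
        warnings.warn("no sire qualifies as a validation sire", stacklevel=2)
    return sorted(chosen)


def select_validation_gilts(data: pd.DataFrame, cutoff: str) -> list:
    """Phenotyped gilts born (scored) after the cutoff."""
    dates = pd.to_datetime(data["date"])
    return sorted(data.loc[dates > pd.Timestamp(cutoff), "animal"].tolist())


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1])


def lr_statistics(
    ebv_partial: pd.Series,
    ebv_complete: pd.Series,
    validation_ids,
    f_bar: float,
    sigma2_u: float,
    kind: str = "dbv",
) -> LRStatistics:
    """LR accuracy, bias and dispersion over a validation group.

    ``ebv_partial`` / ``ebv_complete`` are indexed by animal id and must
    cover every validation animal.  A negative partial-complete
    covariance leaves the accuracy undefined (NaN with a warning), as
    does a zero partial variance for the dispersion.
    """
    ids = list(validation_ids)
    p = ebv_partial.loc[ids].to_numpy(dtype=float)
    c = ebv_complete.loc[ids].to_numpy(dtype=float)
    cov_pc = _cov(p, c)
    denom = (1.0 - f_bar) * sigma2_u
    if cov_pc < 0 or denom <= 0:
        warnings.warn(
            f"accuracy undefined (cov={cov_pc:.4g}, denom={denom:.4g})",
            stacklevel=2)
        acc = math.nan
    else:
        acc = math.sqrt(cov_pc / denom)
    var_p = float(np.var(p, ddof=1))
    if var_p == 0:
        warnings.warn("zero variance of partial EBV: dispersion undefined",
                      stacklevel=2)
        disp = math.nan
    else:
        disp = cov_pc / var_p
    return LRStatistics(kind=kind, accuracy=acc, bias=float(p.mean() - c.mean()),
                        dispersion=disp, n=len(ids), f_bar=f_bar,
                        sigma2_u=sigma2_u)


def bootstrap_se(
    statistic, validation_ids, n_boot: int = 1000, seed: int = 0,
) -> float:
    """Bootstrap standard error of ``statistic(ids)`` over resampled
    validation animals; degenerate resamples are skipped and counted."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(list(validation_ids))
    values = []
    skipped = 0
    for _ in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                v = statistic(sample)
            except (ValueError, ZeroDivisionError):
                skipped += 1
                continue
        if v is None or (isinstance(v, float) and math.isnan(v)):
            skipped += 1
            continue
        values.append(v)
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap resamples skipped",
                      stacklevel=2)
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1))


def tbv_with_unknown_n(
    ebv: pd.DataFrame, n_bar: float,
) -> tuple[pd.Series, pd.Series, float]:
    """TBV with each animal's known pen size vs a constant pen size.

    Returns the two TBV vectors (indexed by animal) and their
    correlation; quantifies how much forward prediction loses when the
    future pen size is unknown.
    """
    from .genpar import total_breeding_values

    known = total_breeding_values(ebv, n_bar=n_bar).set_index("animal")["tbv"]
    const_tab = ebv.copy()
    const_tab["n_pen"] = np.nan
    const = total_breeding_values(const_tab, n_bar=n_bar).set_index("animal")["tbv"]
    if known.std(ddof=1) == 0 or const.std(ddof=1) == 0:
        corr = 1.0 if np.allclose(known, const) else math.nan
    else:
        corr = float(np.corrcoef(known, const)[0, 1])
    return known, const, corr
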