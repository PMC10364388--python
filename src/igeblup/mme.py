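"""Design matrices and Henderson mixed-model equations.

Two animal models are supported for the 100/200-coded score ``y``:

* classical:  y = Xb + Z_D u_D + Z1 gr + Z2 cl + Z3 cg + e
* social:     y = Xb + Z_D u_D + Z_S u_S + Z1 gr + Z2 cl + Z3 cg + e

``Z_S`` links each record to the social effects of its pen mates (one
per mate, so row sums equal pen size minus one).  Genetic effects exist
for every pedigree animal; the relationship inverse may be the pedigree
``A⁻¹`` or the single-step ``H⁻¹``.  Fixed effects are line and scorer
(reference level dropped) and age at scoring centred at its mean.

Equation order is fixed effects, all direct effects, all social effects
(social model), then pen, litter and contemporary group; the genetic
block carries ``inv(G_2x2) (x) K⁻¹``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.linalg as sla
from scipy.linalg.lapack import dpotri

from .components import CLASSICAL, SOCIAL, VarianceComponents
from .pedigree import Pedigree

PEDIGREE_REL = "pedigree"
SSGBLUP = "ssgblup"


class MMEError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which model to fit and through which relationship structure."""

    model: str = SOCIAL
    relationship: str = PEDIGREE_REL
    blend_weight: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in (CLASSICAL, SOCIAL):
            raise MMEError(f"unknown model {self.model!r}")
        if self.relationship not in (PEDIGREE_REL, SSGBLUP):
            raise MMEError(f"unknown relationship source {self.relationship!r}")

    @property
    def is_social(self) -> bool:
        return self.model == SOCIAL


@dataclass
class RandomEffectTerm:
    name: str
    Z: sp.csr_matrix = field(repr=False)
    levels: np.ndarray
    kind: str  # "genetic" or "iid"

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class Design:
    """Assembled design matrices plus cached cross-products."""

    X: np.ndarray
    x_names: list[str]
    y: np.ndarray
    genetic: list[RandomEffectTerm]  # direct (and social) share animal levels
    iid: list[RandomEffectTerm]
    animal_ids: np.ndarray | None = None
    record_ids: np.ndarray | None = None
    age_mean: float | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_genetic_levels(self) -> int:
        return self.genetic[0].n_levels if self.genetic else 0

    def terms(self) -> list[RandomEffectTerm]:
        return list(self.genetic) + list(self.iid)

    def slices(self) -> dict[str, slice]:
        out = {"fixed": slice(0, self.p)}
        start = self.p
        for t in self.terms():
            out[t.name] = slice(start, start + t.n_levels)
            start += t.n_levels
        return out

    @property
    def n_equations(self) -> int:
        return self.p + sum(t.n_levels for t in self.terms())

    def t_matrix(self) -> sp.csr_matrix:
        """Full design ``T = [X | Z...]`` as one sparse matrix."""
        if "T" not in self._cache:
            blocks = [sp.csr_matrix(self.X)] + [t.Z for t in self.terms()]
            self._cache["T"] = sp.hstack(blocks, format="csr")
        return self._cache["T"]

    def cross_products(self):
        """(T'T, T'y, y'y) cached across REML iterations."""
        if "TtT" not in self._cache:
            T = self.t_matrix()
            self._cache["TtT"] = (T.T @ T).tocsr()
            self._cache["Tty"] = T.T @ self.y
            self._cache["yty"] = float(self.y @ self.y)
        return self._cache["TtT"], self._cache["Tty"], self._cache["yty"]


def _dummies(codes: np.ndarray, n_levels: int, drop_first: bool) -> np.ndarray:
    cols = range(1, n_levels) if drop_first else range(n_levels)
    return np.column_stack([(codes == k).astype(float) for k in cols]) \
        if n_levels > (1 if drop_first else 0) else np.empty((len(codes), 0))


def _incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def build_design(
    data: pd.DataFrame, spec: ModelSpec, ped: Pedigree,
) -> Design:
    """Build X, Z_D, (Z_S), Z1, Z2, Z3 from a phenotype table.

    ``data`` needs columns ``animal, y, pen, litter, cg, scorer, line,
    age_days``; every phenotyped animal must be in the pedigree and
    belong to exactly one pen.
    """
    required = {"animal", "y", "pen", "litter", "cg", "scorer", "line", "age_days"}
    missing = required - set(data.columns)
    if missing:
        raise MMEError(f"phenotype table lacks columns {sorted(missing)}")
    if data["animal"].duplicated().any():
        raise MMEError("duplicated phenotype records")
    try:
        pos = ped.positions_of(data["animal"].to_numpy())
    except KeyError as err:
        raise MMEError(f"phenotyped animal missing from pedigree: {err}") from err

    n = len(data)
    n_anim = len(ped)
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    for col in ("line", "scorer"):
        codes, levels = pd.factorize(data[col], sort=True)
        parts.append(_dummies(codes, len(levels), drop_first=True))
        names.extend(f"{col}[{lv}]" for lv in levels[1:])
    age_mean = float(data["age_days"].mean())
    parts.append((data["age_days"].to_numpy() - age_mean)[:, None])
    names.append("age_days")
    X = np.hstack(parts)

    Z_D = _incidence(pos, n_anim)
    genetic = [RandomEffectTerm("direct", Z_D, ped.ids, "genetic")]
    if spec.is_social:
        pen_codes, pen_levels = pd.factorize(data["pen"])
        rows, cols = [], []
        rec_idx = np.arange(n)
        for p in range(len(pen_levels)):
            members = rec_idx[pen_codes == p]
            k = len(members)
            rows.append(np.repeat(members, k))
            cols.append(np.tile(pos[members], k))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        Z_all = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n_anim))
        Z_S = (Z_all - Z_D).tocsr()
        Z_S.eliminate_zeros()
        genetic.append(RandomEffectTerm("social", Z_S, ped.ids, "genetic"))

    iid = []
    for name, col in (("pen", "pen"), ("litter", "litter"), ("cg", "cg")):
        codes, levels = pd.factorize(data[col])
        iid.append(RandomEffectTerm(
            name, _incidence(codes, len(levels)), np.asarray(levels), "iid"))

    return Design(
        X=X, x_names=names, y=data["y"].to_numpy(dtype=float),
        genetic=genetic, iid=iid, animal_ids=ped.ids.copy(),
        record_ids=data["animal"].to_numpy(), age_mean=age_mean,
    )


@dataclass
class MMESystem:
    """Dense symmetric Henderson system ``C s = rhs``."""

    C: np.ndarray = field(repr=False)
    rhs: np.ndarray = field(repr=False)
    slices: dict
    sigma2_e: float
    design: Design = field(repr=False)
    varcomp: VarianceComponents = field(repr=False)

    @property
    def n_equations(self) -> int:
        return len(self.rhs)


def genetic_precision_block(
    varcomp: VarianceComponents, relinv: sp.spmatrix
) -> sp.csr_matrix:
    """``inv(G_2x2) (x) K⁻¹`` (or ``K⁻¹/sigma2_ud`` classical)."""
    g = varcomp.genetic_matrix()
    try:
        ginv = np.linalg.inv(g)
    except np.linalg.LinAlgError as err:
        raise MMEError(
            "direct-social genetic matrix is singular; bend it to the "
            f"nearest positive-definite matrix first ({err})") from err
    if g.shape == (1, 1):
        return (relinv * ginv[0, 0]).tocsr()
    return sp.kron(ginv, relinv, format="csr")


def assemble_mme(
    design: Design, varcomp: VarianceComponents, relinv: sp.spmatrix,
) -> MMESystem:
    """Henderson MME with the residual absorbed as ``1/sigma2_e``."""
    if varcomp.sigma2_e <= 0:
        raise MMEError("residual variance must be strictly positive")
    if varcomp.is_social != (len(design.genetic) == 2):
        raise MMEError("variance components do not match the design's model")
    TtT, Tty, _ = design.cross_products()
    se = varcomp.sigma2_e
    C = (TtT / se).toarray()
    slices = design.slices()
    gen = genetic_precision_block(varcomp, relinv)
    g0 = slices["direct"].start
    g1 = (slices["social"].stop if varcomp.is_social else slices["direct"].stop)
    C[g0:g1, g0:g1] += gen.toarray()
    for term, s2 in zip(design.iid, (varcomp.sigma2_gr, varcomp.sigma2_cl,
                                     varcomp.sigma2_cg)):
        if s2 <= 0:
            raise MMEError(f"variance for {term.name} must be strictly positive")
        sl = slices[term.name]
        C[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += 1.0 / s2
    return MMESystem(C=C, rhs=Tty / se, slices=slices, sigma2_e=se,
                     design=design, varcomp=varcomp)


@dataclass
class MMESolution:
    sol: np.ndarray
    c_inv: np.ndarray | None = None
    slices: dict | None = None

    def effect(self, name: str) -> np.ndarray:
        return self.sol[self.slices[name]]


def _aliased_fixed_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in np.flatnonzero(diag <= tol)]

def solve_mme(system: MMESystem, compute_inverse: bool = False) -> MMESolution:
    """Solve by dense Cholesky; optionally return the full ``C⁻¹``.

    The inverse carries prediction-error (co)variances and the trace
    terms REML and the ssGWAS standard errors require.
    """
    try:
        c, low = sla.cho_factor(system.C, lower=True, check_finite=False)
        pivots = np.diag(c)
        if pivots.min() <= math.sqrt(np.finfo(float).eps) * pivots.max():
            raise np.linalg.LinAlgError("numerically singular pivot")
    except np.linalg.LinAlgError as err:
        aliased = _aliased_fixed_columns(system.design.X, system.design.x_names)
        raise MMEError(
            f"singular mixed-model equations ({err}); "
            f"aliased fixed-effect columns: {aliased or 'none detected'}"
        ) from err
    sol = sla.cho_solve((c, low), system.rhs, check_finite=False)
    c_inv = None
    if compute_inverse:
        c_inv, info = dpotri(c, lower=1)
        if info != 0:
            raise MMEError(f"inverse computation failed (dpotri info={info})")
        c_inv = np.tril(c_inv) + np.tril(c_inv, -1).T
    return MMESolution(sol=sol, c_inv=c_inv, slices=system.slices)


def estimate_breeding_values(
    data: pd.DataFrame,
    spec: ModelSpec,
    varcomp: VarianceComponents,
    relinv: sp.spmatrix,
    ped: Pedigree,
) -> pd.DataFrame:
    """BLUP breeding values for every pedigree animal.

    Returns a table with ``animal, dbv`` (plus ``sbv`` under the social
    model) and the pen size ``n_pen`` for penned animals (NaN for
    ancestors), tagged with the model and relationship source.
    """
    design = build_design(data, spec, ped)
    solution = solve_mme(assemble_mme(design, varcomp, relinv))
    out = pd.DataFrame({"animal": ped.ids, "dbv": solution.effect("direct")})
    if spec.is_social:
        out["sbv"] = solution.effect("social")
    pen_sizes = data.groupby("pen")["animal"].transform("size")
    n_pen = pd.Series(pen_sizes.to_numpy(), index=data["animal"].to_numpy())
    out["n_pen"] = out["animal"].map(n_pen)
    out.attrs["model"] = spec.model
    out.attrs["relationship"] = spec.relationship
    return out
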