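"""Pedigree relationship machinery.

Additive (numerator) relationship matrices and their inverses are the
backbone of every animal model fitted in this package.  The module keeps
two complementary representations:

* the dense tabular-method matrix ``A`` for desk-scale oracles and for
  subsets (``A22``), and
* the sparse Henderson inverse ``A⁻¹`` (with inbreeding accounted for)
  used inside mixed-model equations at any scale.

Unknown parents are encoded by the reserved id ``0`` and treated as
unrelated, non-inbred founders; unknown-parent groups are deliberately
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN_PARENT = 0

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "line", "birth_date", "genotyped"]


class PedigreeError(ValueError):
    """Raised for structural problems: cycles, duplicate or orphan ids."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree with positional parent indices.

    Attributes
    ----------
    table:
        One row per animal with columns ``animal, sire, dam, line,
        birth_date, genotyped``; parents always appear in earlier rows.
    sire_pos, dam_pos:
        Row position of each animal's sire/dam, ``-1`` for unknown.
    """

    table: pd.DataFrame
    sire_pos: np.ndarray = field(repr=False)
    dam_pos: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    @property
    def id_to_pos(self) -> dict[int, int]:
        return {a: i for i, a in enumerate(self.table["animal"])}

    def positions_of(self, ids) -> np.ndarray:
        lookup = self.id_to_pos
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]} not in pedigree") from None


def sort_and_validate(table: pd.DataFrame) -> Pedigree:
    """Topologically sort a raw pedigree table (parents before offspring).

    Raises :class:`PedigreeError` on duplicate ids, parents missing from
    the table, or ancestry cycles (the offending cycle is listed).
    """
    tab = table.copy()
    for col in ("animal", "sire", "dam"):
        tab[col] = tab[col].fillna(UNKNOWN_PARENT).astype(np.int64)
    ids = tab["animal"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise PedigreeError(f"duplicate animal ids: {list(dup[dup > 1].index[:5])}")
    if np.any(ids == UNKNOWN_PARENT):
        raise PedigreeError(f"animal id {UNKNOWN_PARENT} is reserved for unknown parents")
    known = set(ids)
    for col in ("sire", "dam"):
        orphans = set(tab[col]) - known - {UNKNOWN_PARENT}
        if orphans:
            raise PedigreeError(f"{col} ids absent from pedigree: {sorted(orphans)[:5]}")

    # Kahn's algorithm over the parent -> offspring DAG.
    pos = {a: i for i, a in enumerate(ids)}
    sire = tab["sire"].to_numpy()
    dam = tab["dam"].to_numpy()
    n_parents = np.zeros(len(ids), dtype=np.int64)
    children: list[list[int]] = [[] for _ in ids]
    for i in range(len(ids)):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN_PARENT:
                n_parents[i] += 1
                children[pos[p]].append(i)
    order: list[int] = list(np.flatnonzero(n_parents == 0))
    remaining = n_parents.copy()
    head = 0
    while head < len(order):
        i = order[head]
        head += 1
        for c in children[i]:
            remaining[c] -= 1
            if remaining[c] == 0:
                order.append(c)
    if len(order) < len(ids):
        cycle = [int(ids[i]) for i in np.flatnonzero(remaining > 0)]
        raise PedigreeError(f"pedigree contains a cycle among animals {cycle}")

    sorted_tab = tab.iloc[order].reset_index(drop=True)
    pos2 = {a: i for i, a in enumerate(sorted_tab["animal"])}
    sire_pos = np.array(
        [pos2.get(s, -1) for s in sorted_tab["sire"]], dtype=np.int64
    )
    dam_pos = np.array([pos2.get(d, -1) for d in sorted_tab["dam"]], dtype=np.int64)
    return Pedigree(sorted_tab, sire_pos, dam_pos)


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Memory is quadratic in pedigree size; intended for desk-scale
    pedigrees and for extracting submatrices such as ``A22``.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_pos, ped.dam_pos
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return A


def _kinship_table(ped: Pedigree):
    """Memoised coancestry phi(i, j) over row positions."""
    s, d = ped.sire_pos, ped.dam_pos
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + phi(s[i], d[i]))
        else:
            # i is the later-born animal, so recurse through its parents
            val = 0.5 * (phi(s[i], j) + phi(d[i], j))
        memo[key] = val
        return val

    return phi


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient per animal (pedigree order).

    ``F_i`` is the coancestry of the parents; founders and animals with an
    unknown parent get ``F = 0``.  Exactly equals ``diag(A) - 1``.
    """
    phi = _kinship_table(ped)
    s, d = ped.sire_pos, ped.dam_pos
    out = np.zeros(len(ped))
    for i in range(len(ped)):
        if s[i] >= 0 and d[i] >= 0:
            out[i] = phi(s[i], d[i])
    return out


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variances ``d_i`` relative to sigma2_u.

    These drive both Henderson's ``A⁻¹`` rules and ``log|A| = sum log d_i``.
    """
    if F is None:
        F = inbreeding(ped)
    s, d = ped.sire_pos, ped.dam_pos
    out = np.ones(len(ped))
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s >= 0) & (d < 0)
    out[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (d >= 0) & (s < 0)
    out[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return out


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse ``A⁻¹`` by Henderson's rules, inbreeding accounted for."""
    if F is None:
        F = inbreeding(ped)
    dvec = mendelian_variances(ped, F)
    s, d = ped.sire_pos, ped.dam_pos
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    n = len(ped)
    i = np.arange(n)
    b = 1.0 / dvec
    add(i, i, b)
    for p in (s, d):
        m = p >= 0
        add(i[m], p[m], -0.5 * b[m])
        add(p[m], i[m], -0.5 * b[m])
        add(p[m], p[m], 0.25 * b[m])
    both = (s >= 0) & (d >= 0)
    add(s[both], d[both], 0.25 * b[both])
    add(d[both], s[both], 0.25 * b[both])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return Ainv.tocsr()


def relationship_between(ped: Pedigree, ids_a, ids_b) -> np.ndarray:
    """Additive relationships a(i, j) = 2*phi(i, j) for two id lists.

    Works pair-by-pair through the memoised coancestry recursion, so it
    scales with the number of requested pairs rather than pedigree size.
    """
    phi = _kinship_table(ped)
    pa = ped.positions_of(ids_a)
    pb = ped.positions_of(ids_b)
    out = np.empty((len(pa), len(pb)))
    for i, x in enumerate(pa):
        for j, y in enumerate(pb):
            out[i, j] = 2.0 * phi(int(x), int(y))
    return out


def a22(ped: Pedigree, genotyped_ids) -> tuple[np.ndarray, np.ndarray]:
    """``A`` restricted to the genotyped animals, plus its dense inverse.

    The inverse is of the submatrix itself (not a submatrix of ``A⁻¹``),
    obtained by dense factorisation; the genotyped set is small by design.
    """
    genotyped_ids = list(genotyped_ids)
    A22 = relationship_between(ped, genotyped_ids, genotyped_ids)
    A22 = 0.5 * (A22 + A22.T)
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as err:
        raise PedigreeError(f"A22 is singular: {err}") from err
    return A22, A22_inv


@dataclass
class RelationshipSummary:
    """Pen-structure summaries entering the derived-parameter formulas."""

    n_bar: float  # mean pen-group size
    r: float  # mean additive relationship between pen mates
    f_bar: float  # mean inbreeding of the summarised animals
    n_pens: int
    n_pairs: int


def pen_mate_relationship(
    A: np.ndarray, ids, pens: pd.DataFrame, F: np.ndarray | None = None
) -> RelationshipSummary:
    """Mean relationship over all unordered pen-mate pairs from a dense ``A``.

    Parameters
    ----------
    A:
        Relationship matrix whose rows/columns follow ``ids``.
    pens:
        Assignment table with columns ``animal`` and ``pen``.  Pens with a
        single animal are excluded.
    """
    lookup = {a: i for i, a in enumerate(ids)}
    return _pen_summary(lambda i, j: A[lookup[i], lookup[j]], pens, F, lookup)


def pen_mate_relationship_from_pedigree(
    ped: Pedigree, pens: pd.DataFrame
) -> RelationshipSummary:
    """Same summary computed through the coancestry recursion (no dense A)."""
    phi = _kinship_table(ped)
    pos = ped.id_to_pos
    F = inbreeding(ped)
    return _pen_summary(
        lambda i, j: 2.0 * phi(pos[i], pos[j]), pens, F, pos
    )


def _pen_summary(rel, pens: pd.DataFrame, F, pos_lookup) -> RelationshipSummary:
    sizes = []
    total = 0.0
    n_pairs = 0
    f_sum = 0.0
    n_animals = 0
    for _, members in pens.groupby("pen")["animal"]:
        animals = members.to_list()
        if len(animals) < 2:
            continue
        sizes.append(len(animals))
        for k in range(len(animals)):
            for l in range(k + 1, len(animals)):
                total += rel(animals[k], animals[l])
                n_pairs += 1
        if F is not None:
            f_sum += sum(F[pos_lookup[a]] for a in animals)
            n_animals += len(animals)
    if not sizes:
        raise PedigreeError("no pen with at least two animals")
    return RelationshipSummary(
        n_bar=float(np.mean(sizes)),
        r=total / n_pairs,
        f_bar=(f_sum / n_animals) if n_animals else 0.0,
        n_pens=len(sizes),
        n_pairs=n_pairs,
    )
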