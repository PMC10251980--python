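"""Pedigree validation and numerator-relationship-matrix algebra.

The animal model treats each bird's additive genetic merit as a random
effect whose covariance is proportional to the numerator relationship
matrix ``A`` computed from the pedigree.  This module provides:

* :func:`validate_and_sort` — checks a raw record list (unique ids, known
  parents, acyclic) and returns a topologically ordered
  :class:`Pedigree` in which every parent precedes its offspring;
* :func:`relationship_matrix` — the dense ``A`` by the tabular
  (recursive) method;
* :func:`inbreeding_coefficients` — ``F_i = a_ii - 1``;
* :func:`a_inverse` — sparse ``A^{-1}`` built directly by the
  Henderson/Quaas rules with inbreeding, which is all the Gibbs sampler
  ever needs.

Unknown parents are coded 0 in files (the universal convention in animal
breeding data) and treated as draws from an unrelated base population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "PedigreeError",
    "DuplicateIdError",
    "UnknownParentError",
    "PedigreeCycleError",
    "validate_and_sort",
    "relationship_matrix",
    "inbreeding_coefficients",
    "a_inverse",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


class PedigreeError(ValueError):
    """Base class for structural pedigree problems."""


class DuplicateIdError(PedigreeError):
    """An animal id occurs more than once."""


class UnknownParentError(PedigreeError):
    """A sire or dam id is referenced but never defined as an animal."""


class PedigreeCycleError(PedigreeError):
    """An animal is (transitively) its own ancestor."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids
        Animal identifiers in topological order (parents first).
    sire_idx, dam_idx
        Positional index (into ``ids``) of each animal's sire/dam, or
        ``-1`` when the parent is unknown (base animal).
    sex
        Per-animal sex code, ``"M"``/``"F"`` (``"U"`` if unrecorded).
    """

    ids: np.ndarray
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    sex: np.ndarray
    _pos: dict = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_pos", {int(a): i for i, a in enumerate(self.ids)}
        )

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def position(self, animal_id) -> int:
        """Row index of an animal id (raises KeyError if absent)."""
        return self._pos[int(animal_id)]

    @property
    def is_base(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame with 0 coding unknown parents."""
        sire = np.where(self.sire_idx >= 0, self.ids[self.sire_idx], UNKNOWN)
        dam = np.where(self.dam_idx >= 0, self.ids[self.dam_idx], UNKNOWN)
        return pd.DataFrame(
            {"id": self.ids, "sire": sire, "dam": dam, "sex": self.sex}
        )


def validate_and_sort(records) -> Pedigree:
    """Validate raw pedigree records and sort parents-before-offspring.

    Parameters
    ----------
    records
        DataFrame with columns ``id, sire, dam`` (optional ``sex``), or
        any iterable of ``(id, sire, dam[, sex])`` tuples.  ``0`` (or
        negative/NaN) marks an unknown parent.

    Returns
    -------
    Pedigree
        Topologically sorted; the sort is stable (ties keep input order).

    Raises
    ------
    DuplicateIdError, UnknownParentError, PedigreeCycleError
    """
    df = _coerce_records(records)
    ids = df["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].unique()
        raise DuplicateIdError(f"duplicate animal ids: {dupes[:5].tolist()}")
    pos = {int(a): i for i, a in enumerate(ids)}

    n = len(ids)
    parents = np.full((n, 2), -1, dtype=np.int64)
    for j, col in enumerate(("sire", "dam")):
        for i, p in enumerate(df[col].to_numpy()):
            if p == UNKNOWN:
                continue
            if int(p) not in pos:
                raise UnknownParentError(
                    f"animal {ids[i]} references unknown {col} {p}"
                )
            parents[i, j] = pos[int(p)]

    order = _stable_toposort(parents, ids)

    remap = np.empty(n, dtype=np.int64)
    remap[order] = np.arange(n)
    sire_idx = np.where(parents[order, 0] >= 0, remap[parents[order, 0]], -1)
    dam_idx = np.where(parents[order, 1] >= 0, remap[parents[order, 1]], -1)
    return Pedigree(
        ids=ids[order],
        sire_idx=sire_idx.astype(np.int64),
        dam_idx=dam_idx.astype(np.int64),
        sex=df["sex"].to_numpy()[order],
    )


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, Pedigree):
        df = records.to_frame()
    elif isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [tuple(r) for r in records]
        width = max((len(r) for r in rows), default=4)
        cols = ["id", "sire", "dam", "sex"][:width]
        df = pd.DataFrame(rows, columns=cols)
    if "sex" not in df.columns:
        df["sex"] = "U"
    for col in ("id", "sire", "dam"):
        df[col] = (
            pd.to_numeric(df[col], errors="raise")
            .fillna(UNKNOWN)
            .astype(np.int64)
        )
    # negative codes also mean "unknown"
    df.loc[df["sire"] < 0, "sire"] = UNKNOWN
    df.loc[df["dam"] < 0, "dam"] = UNKNOWN
    return df.reset_index(drop=True)


def _stable_toposort(parents: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Kahn's algorithm keeping input order among ready animals."""
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in parents[i]:
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    import heapq

    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        stuck = ids[[i for i in range(n) if indeg[i] > 0]]
        raise PedigreeCycleError(
            f"pedigree contains a cycle involving ids {stuck[:5].tolist()}"
        )
    return np.asarray(order, dtype=np.int64)


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix ``A`` by the tabular method.

    ``a_ii = 1 + 0.5*a(sire,dam)``;
    ``a_ij = 0.5*(a(j,sire_i) + a(j,dam_i))`` for ``j < i``, with an
    unknown parent contributing zero.  Requires the parents-first order
    guaranteed by :func:`validate_and_sort`.
    """
    _check_sorted(pedigree)
    n = pedigree.n_animals
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        v = np.zeros(i)
        if s[i] >= 0:
            v += A[:i, s[i]]
        if d[i] >= 0:
            v += A[:i, d[i]]
        v *= 0.5
        A[i, :i] = v
        A[:i, i] = v
        A[i, i] = 1.0 + (0.5 * A[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient ``F = diag(A) - 1``.

    Base animals (both parents unknown) have ``F = 0`` by construction.
    """
    return np.diag(relationship_matrix(pedigree)) - 1.0


def mendelian_variance_scale(pedigree: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance multiplier ``d_i`` per animal.

    ``d_i`` scales the base additive (co)variance for the deviation of an
    animal's breeding value from its parent average: 0.5 - 0.25(F_s+F_d)
    with both parents known, 0.75 - 0.25 F_p with one, 1 with none.
    Shared between the gene-dropping simulator and the A-inverse rules.
    """
    if F is None:
        F = inbreeding_coefficients(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], np.nan)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], np.nan)
    out = np.ones(pedigree.n_animals)
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    only_s = (s >= 0) & (d < 0)
    out[only_s] = 0.75 - 0.25 * Fs[only_s]
    only_d = (s < 0) & (d >= 0)
    out[only_d] = 0.75 - 0.25 * Fd[only_d]
    return out


def a_inverse(pedigree: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse ``A^{-1}`` by the Henderson/Quaas rules with inbreeding.

    For each animal ``i`` with Mendelian variance ``d_i`` (see
    :func:`mendelian_variance_scale`) and ``alpha = 1/d_i``::

        A^{-1}[i,i]         += alpha
        A^{-1}[i,p], [p,i]  -= alpha/2   for each known parent p
        A^{-1}[p,p']        += alpha/4   for each known parent pair

    The product with the tabular ``A`` is the identity to ~1e-10 on
    pedigrees of the scale used here.
    """
    _check_sorted(pedigree)
    dscale = mendelian_variance_scale(pedigree, F)
    if np.any(dscale <= 0):
        raise PedigreeError("non-positive Mendelian variance; invalid pedigree")
    n = pedigree.n_animals
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        alpha = 1.0 / dscale[i]
        add(i, i, alpha)
        for p in (s[i], d[i]):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s[i], d[i]):
            for q in (s[i], d[i]):
                if p >= 0 and q >= 0:
                    add(p, q, alpha / 4.0)
    return sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def _check_sorted(pedigree: Pedigree) -> None:
    idx = np.arange(pedigree.n_animals)
    if np.any(pedigree.sire_idx >= idx) or np.any(pedigree.dam_idx >= idx):
        raise PedigreeError(
            "pedigree is not parents-first ordered; run validate_and_sort"
        )


def read_pedigree_csv(path) -> Pedigree:
    """Read the package CSV dialect (id,sire,dam,sex; '#' comments)."""
    df = pd.read_csv(path, comment="#")
    if "sex" not in df.columns and df.shape[1] == 3:
        df.columns = ["id", "sire", "dam"]
    return validate_and_sort(df)


def write_pedigree_csv(pedigree: Pedigree, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pedigree.to_frame().to_csv(fh, index=False)
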