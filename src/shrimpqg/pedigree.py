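"""Pedigrees and the additive (numerator) relationship matrix.

The animal models in this package need the expected additive genetic
relationship between every pair of animals.  For a pedigree of known
sire/dam links this is the numerator relationship matrix **A**: the
matrix of twice the kinship coefficients, with diagonal ``1 + F_i``
where ``F_i`` is the inbreeding coefficient of animal *i*.

Three core routines are provided:

``build_pedigree``
    Validate records, auto-insert missing parents as founders and
    topologically sort so every parent precedes its offspring.
``a_matrix``
    Dense A by the tabular method (recursive over the sorted pedigree).
``a_inverse``
    Sparse A^-1 built directly by Henderson's rules, with inbreeding
    from the Meuwissen & Luo algorithm (no dense inversion).

Unknown parents are treated as unrelated, non-inbred phantom founders;
no genetic-group effects are fitted.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "PedigreeCycleError",
    "DuplicateAnimalError",
    "build_pedigree",
    "a_matrix",
    "a_inverse",
    "inbreeding_coefficients",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "export_matrix_market",
]

#: Sentinel for an unknown parent in memory; `0`, empty and NA map to it on read.
UNKNOWN = None

_MISSING_CODES = {"", "0", "NA", "NONE", "UNKNOWN", "."}


class PedigreeError(ValueError):
    """Invalid pedigree structure."""


class PedigreeCycleError(PedigreeError):
    """An animal is its own ancestor."""


class DuplicateAnimalError(PedigreeError):
    """The same animal id occurs in more than one record."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its (possibly unknown) sire and dam."""

    animal: str
    sire: str | None = None
    dam: str | None = None


@dataclass
class Pedigree:
    """Topologically sorted pedigree with integer parent indices.

    ``sire_idx``/``dam_idx`` hold the position of each animal's parents in
    ``records`` (or -1 for unknown); every parent position precedes its
    offspring's.
    """

    records: list[PedigreeRecord]
    order: dict[str, int] = field(repr=False)
    sire_idx: np.ndarray = field(repr=False)
    dam_idx: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal for r in self.records]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    @property
    def sires(self) -> set[str]:
        return {r.sire for r in self.records if r.sire is not None}

    @property
    def dams(self) -> set[str]:
        return {r.dam for r in self.records if r.dam is not None}

    @property
    def n_progeny(self) -> int:
        """Animals with at least one known parent."""
        return len(self) - self.n_founders

    def summary(self) -> dict[str, int]:
        return {
            "n_animals": len(self),
            "n_founders": self.n_founders,
            "n_sires": len(self.sires),
            "n_dams": len(self.dams),
            "n_progeny": self.n_progeny,
        }


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix (or its inverse) with row ids."""

    ids: list[str]
    values: np.ndarray | sp.spmatrix

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    @property
    def inbreeding(self) -> np.ndarray:
        """F_i = A_ii - 1 (only meaningful for A itself, not its inverse)."""
        return np.asarray(self.toarray().diagonal()) - 1.0


def _norm_id(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s.upper() in _MISSING_CODES:
        return None
    return s


def build_pedigree(records: Iterable[PedigreeRecord | tuple]) -> Pedigree:
    """Validate and topologically sort pedigree records.

    Parents referenced but never listed as animals are inserted as
    founders.  Raises :class:`DuplicateAnimalError` for repeated animal
    ids, :class:`PedigreeError` for an animal that is its own parent or
    an id used both as sire and dam, and :class:`PedigreeCycleError`
    when an animal is its own ancestor.
    """
    parsed: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    sires_seen: set[str] = set()
    dams_seen: set[str] = set()
    for rec in records:
        if not isinstance(rec, PedigreeRecord):
            rec = PedigreeRecord(*rec)
        animal = _norm_id(rec.animal)
        sire = _norm_id(rec.sire)
        dam = _norm_id(rec.dam)
        if not animal:
            raise PedigreeError("empty animal id")
        if animal in parsed:
            raise DuplicateAnimalError(f"duplicate record for animal {animal!r}")
        if animal == sire or animal == dam:
            raise PedigreeCycleError(f"animal {animal!r} is its own parent")
        if sire is not None and sire == dam:
            raise PedigreeError(f"animal {animal!r} has identical sire and dam {sire!r}")
        parsed[animal] = (sire, dam)
        order_seen.append(animal)
        if sire is not None:
            sires_seen.add(sire)
        if dam is not None:
            dams_seen.add(dam)
    both = sires_seen & dams_seen
    if both:
        raise PedigreeError(
            f"id(s) used as both sire and dam: {sorted(both)[:5]}"
        )
    # phantom founders for parents without their own record
    for pid in list(sires_seen | dams_seen):
        if pid not in parsed:
            parsed[pid] = (None, None)
            order_seen.append(pid)

    # Kahn topological sort (parents before offspring), stable in input order
    children: dict[str, list[str]] = {a: [] for a in parsed}
    n_parents = {a: 0 for a in parsed}
    for animal, (sire, dam) in parsed.items():
        for p in (sire, dam):
            if p is not None:
                children[p].append(animal)
                n_parents[animal] += 1
    queue = deque(a for a in order_seen if n_parents[a] == 0)
    sorted_ids: list[str] = []
    while queue:
        a = queue.popleft()
        sorted_ids.append(a)
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                queue.append(c)
    if len(sorted_ids) != len(parsed):
        offender = next(a for a in order_seen if a not in set(sorted_ids))
        raise PedigreeCycleError(f"pedigree cycle involving animal {offender!r}")

    order = {a: i for i, a in enumerate(sorted_ids)}
    sire_idx = np.full(len(sorted_ids), -1, dtype=np.int64)
    dam_idx = np.full(len(sorted_ids), -1, dtype=np.int64)
    recs = []
    for i, a in enumerate(sorted_ids):
        sire, dam = parsed[a]
        recs.append(PedigreeRecord(a, sire, dam))
        if sire is not None:
            sire_idx[i] = order[sire]
        if dam is not None:
            dam_idx[i] = order[dam]
    return Pedigree(records=recs, order=order, sire_idx=sire_idx, dam_idx=dam_idx)


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 A_sd, A_ij = 0.5 (A_js + A_jd) for j preceding i;
    an unknown parent contributes zero.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += A[:i, si]
            if di >= 0:
                row += A[:i, di]
            row *= 0.5
            A[:i, i] = row
            A[i, :i] = row
    return RelationshipMatrix(ids=ped.ids, values=A)


def _mendelian_d(F: np.ndarray, si: int, di: int) -> float:
    """Mendelian-sampling variance share d_i given parental inbreeding."""
    if si >= 0 and di >= 0:
        return 0.5 - 0.25 * (F[si] + F[di])
    if si >= 0 or di >= 0:
        known = si if si >= 0 else di
        return 0.75 - 0.25 * F[known]
    return 1.0


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the row of L (Cholesky of A) over its ancestors is
    accumulated in decreasing pedigree order, giving
    ``A_ii = sum_j L_ij^2 d_j`` and ``F_i = A_ii - 1`` without forming
    the dense A.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            continue  # founder, F = 0
        L = np.zeros(i + 1)
        L[i] = 1.0
        Aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            Aii += lj * lj * _mendelian_d(F, s[j], d[j])
            if s[j] >= 0:
                L[s[j]] += 0.5 * lj
            if d[j] >= 0:
                L[d[j]] += 0.5 * lj
        F[i] = Aii - 1.0
    return F


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 directly from Henderson's rules with inbreeding.

    The Mendelian-sampling variance d_i uses parental inbreeding from
    :func:`inbreeding_coefficients`; `a_inverse(ped) @ a_matrix(ped)`
    equals the identity to numerical tolerance.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        w = 1.0 / _mendelian_d(F, si, di)
        add(i, i, w)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return RelationshipMatrix(ids=ped.ids, values=Ainv)


# ---------------------------------------------------------------------------
# I/O: `animal,sire,dam` CSV dialect; 0/empty = unknown parent.

def read_pedigree_csv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    recs = [
        PedigreeRecord(r.animal, r.sire, r.dam)
        for r in df.itertuples(index=False)
    ]
    return build_pedigree(recs)


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "animal": [r.animal for r in ped.records],
            "sire": [r.sire or "0" for r in ped.records],
            "dam": [r.dam or "0" for r in ped.records],
        }
    )
    df.to_csv(path, index=False)


def export_matrix_market(mat: RelationshipMatrix, path: str | Path) -> None:
    """Write A (or A^-1) as Matrix Market sparse triplets for inspection."""
    from scipy.io import mmwrite

    values = mat.values if sp.issparse(mat.values) else sp.coo_matrix(mat.values)
    mmwrite(str(path), values)
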