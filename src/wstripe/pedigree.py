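"""Pedigree containers and additive-relationship machinery.

A pedigree is the list of individual → (sire, dam) links, together with the
line / sex / hatch / generation metadata the downstream models use as fixed
effects.  From it we build the additive (numerator) relationship matrix A,
whose entry a_ij is twice the kinship between i and j and whose diagonal is
1 + F_i with F_i the inbreeding coefficient.  The Gibbs sampler never needs
dense A — only its sparse inverse, assembled by Henderson's rules with
Mendelian-sampling variances corrected for parental inbreeding
(d_i = 0.5 − 0.25·(F_s + F_d), the Meuwissen–Luo correction).

Unknown parents are treated as unrelated, non-inbred founders of the base
population; no genetic groups are fitted.  All matrices are indexed in
pedigree (topological) order; callers address individuals by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "KinshipCalculator",
    "load_pedigree",
    "write_pedigree",
    "additive_relationship",
    "a_inverse",
    "inbreeding_coefficients",
]

#: marker for an unknown parent in integer index arrays
UNKNOWN = -1

_REQUIRED_COLUMNS = ("id", "sire", "dam", "line", "sex", "hatch", "generation")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree: every parent precedes its offspring.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per individual with columns id, sire, dam, line, sex, hatch,
        generation, in topological order.  ``sire``/``dam`` are 0 for
        unknown parents.
    sire_idx, dam_idx : ndarray of int
        Row index of each individual's parents (-1 = unknown).
    """

    table: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    _row_of: dict = field(repr=False, default_factory=dict)
    _F: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        ids = self.table["id"].tolist()
        self._row_of = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n_sires(self) -> int:
        s = self.table["sire"]
        return int(s[s != 0].nunique())

    @property
    def n_dams(self) -> int:
        d = self.table["dam"]
        return int(d[d != 0].nunique())

    def rows_of(self, ids) -> np.ndarray:
        """Map ids to pedigree row indices (the only supported addressing)."""
        try:
            return np.asarray([self._row_of[i] for i in np.asarray(ids).tolist()])
        except KeyError as exc:  # pragma: no cover - message check only
            raise PedigreeError(f"id {exc.args[0]!r} not in pedigree") from None

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients F (Meuwissen–Luo)."""
        if self._F is None:
            self._F = inbreeding_coefficients(self.sire_idx, self.dam_idx)
        return self._F

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Validate, topologically sort, and wrap a raw pedigree frame."""
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree file lacks columns: {missing}")
        df = df.copy()
        for col in ("sire", "dam"):
            df[col] = df[col].replace({"": 0, np.nan: 0})
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        ids = set(df["id"])
        for col in ("sire", "dam"):
            known = df.loc[df[col] != 0, col]
            absent = set(known) - ids
            if absent:
                raise PedigreeError(
                    f"{col} id {sorted(absent, key=str)[0]!r} absent from pedigree file"
                )
        order = _toposort(df)
        df = df.iloc[order].reset_index(drop=True)
        row_of = {v: i for i, v in enumerate(df["id"])}
        sire_idx = np.array(
            [row_of[s] if s != 0 else UNKNOWN for s in df["sire"]], dtype=np.int64
        )
        dam_idx = np.array(
            [row_of[d] if d != 0 else UNKNOWN for d in df["dam"]], dtype=np.int64
        )
        ped = cls(table=df, sire_idx=sire_idx, dam_idx=dam_idx)
        _check_parent_sex(ped)
        return ped


def _toposort(df: pd.DataFrame) -> np.ndarray:
    """Kahn topological sort over parent→offspring edges; names a cycle member."""
    n = len(df)
    row_of = {v: i for i, v in enumerate(df["id"])}
    children: list[list[int]] = [[] for _ in range(n)]
    n_parents = np.zeros(n, dtype=np.int64)
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p != 0:
                children[row_of[p]].append(i)
                n_parents[i] += 1
    # min-heap on file position: smallest valid order, and the identity for
    # input that is already topologically sorted (stable round-trips)
    import heapq

    order: list[int] = []
    ready = [i for i in range(n) if n_parents[i] == 0]
    heapq.heapify(ready)
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        left = next(i for i in range(n) if n_parents[i] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle involving individual {df['id'].iloc[left]!r}"
        )
    return np.asarray(order)


def _check_parent_sex(ped: Pedigree) -> None:
    sex = ped.table["sex"].to_numpy()
    for i in range(len(ped)):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s != UNKNOWN and str(sex[s]).lower() not in ("m", "male", "1"):
            raise PedigreeError(
                f"sire {ped.table['id'].iloc[s]!r} of "
                f"{ped.table['id'].iloc[i]!r} is not male"
            )
        if d != UNKNOWN and str(sex[d]).lower() not in ("f", "female", "2"):
            raise PedigreeError(
                f"dam {ped.table['id'].iloc[d]!r} of "
                f"{ped.table['id'].iloc[i]!r} is not female"
            )


def load_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (comma default, tab accepted).

    Columns: ``id,sire,dam,line,sex,hatch,generation``; 0 or empty marks an
    unknown parent.  Returns a topologically sorted :class:`Pedigree`.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path, sep: str = ",") -> None:
    ped.table.to_csv(path, sep=sep, index=False)


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix A, dense, or its sparse inverse.

    ``matrix`` is a dense ndarray when ``is_inverse`` is False and a
    scipy CSR matrix when True.  ``F`` holds inbreeding coefficients in
    pedigree order (diag(A) = 1 + F).
    """

    matrix: object
    F: np.ndarray
    is_inverse: bool = False


def inbreeding_coefficients(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """F for every individual, parents assumed to precede offspring.

    F_i = 0.5 · a(sire_i, dam_i); kinships are resolved by memoized recursion
    on the pedigree (exact, matches the tabular method).
    """
    calc = KinshipCalculator(sire_idx, dam_idx)
    return calc.inbreeding_all()


class KinshipCalculator:
    """Memoized kinship/inbreeding on index-coded pedigrees.

    Used both by the relationship-matrix builders and by the breeding-scheme
    simulator (which needs parental F for Mendelian-sampling variances while
    the pedigree is still growing; call :meth:`extend` as rows are added).
    """

    def __init__(self, sire_idx, dam_idx) -> None:
        self.sire = list(np.asarray(sire_idx, dtype=np.int64))
        self.dam = list(np.asarray(dam_idx, dtype=np.int64))
        self._phi: dict[tuple[int, int], float] = {}
        self._F: dict[int, float] = {}

    def extend(self, sire_idx, dam_idx) -> None:
        self.sire.extend(int(s) for s in sire_idx)
        self.dam.extend(int(d) for d in dam_idx)

    def F(self, i: int) -> float:
        if i == UNKNOWN:
            return 0.0
        f = self._F.get(i)
        if f is None:
            s, d = self.sire[i], self.dam[i]
            f = 0.0 if (s == UNKNOWN or d == UNKNOWN) else self.relationship(s, d) / 2.0
            self._F[i] = f
        return f

    def kinship(self, i: int, j: int) -> float:
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + self.F(i))
        a, b = (i, j) if i < j else (j, i)  # b is the later-born
        key = (a, b)
        val = self._phi.get(key)
        if val is None:
            val = 0.5 * (self.kinship(a, self.sire[b]) + self.kinship(a, self.dam[b]))
            self._phi[key] = val
        return val

    def relationship(self, i: int, j: int) -> float:
        """Additive relationship a_ij = 2·kinship."""
        return 2.0 * self.kinship(i, j)

    def inbreeding_all(self) -> np.ndarray:
        import sys

        depth = sys.getrecursionlimit()
        need = 10 * (len(self.sire) + 10)
        if depth < need:
            sys.setrecursionlimit(need)
        return np.array([self.F(i) for i in range(len(self.sire))])


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular (recursive) method.

    a_ii = 1 + 0.5·a_{sd};  a_ij = 0.5·(a_{j,s_i} + a_{j,d_i}) for j < i,
    with unknown parents contributing zero.  Quadratic in pedigree size —
    intended for pedigrees up to a few thousand (oracles, desk checks).
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[:i, s[i]]
        if d[i] != UNKNOWN:
            row += 0.5 * A[:i, d[i]]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s[i], d[i]] if (s[i] != UNKNOWN and d[i] != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    F = np.diag(A) - 1.0
    return RelationshipMatrix(matrix=A, F=F, is_inverse=False)


def mendelian_sampling_variances(ped: Pedigree) -> np.ndarray:
    """d_i, the within-family (Mendelian-sampling) variance coefficients.

    both parents known: 0.5 − 0.25·(F_s + F_d); one known: 0.75 − 0.25·F_p;
    none: 1.  These scale the within-family genetic variance and are the
    diagonal D of the A = T D T' decomposition.
    """
    F = ped.inbreeding
    s, d = ped.sire_idx, ped.dam_idx
    out = np.ones(len(ped))
    both = (s != UNKNOWN) & (d != UNKNOWN)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s != UNKNOWN) & (d == UNKNOWN)
    out[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (s == UNKNOWN) & (d != UNKNOWN)
    out[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return out


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding-corrected d_i.

    For each individual i with Mendelian-sampling coefficient d_i and known
    parents P ⊆ {s, d}:  α = 1/d_i contributes α to (i,i), −α/2 to (i,p),
    and α/4 to (p,q) for p,q ∈ P.
    """
    n = len(ped)
    dvec = mendelian_sampling_variances(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        alpha = 1.0 / dvec[i]
        if not np.isfinite(alpha):
            raise PedigreeError(f"non-finite Mendelian variance at row {i}")
        parents = [p for p in (s[i], d[i]) if p != UNKNOWN]
        rows.append(i), cols.append(i), vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
            for q in parents:
                rows.append(p), cols.append(q), vals.append(alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(matrix=Ainv, F=ped.inbreeding, is_inverse=True)
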